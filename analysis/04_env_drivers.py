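#!/usr/bin/env python
"""Environmental drivers of the DDG peaks.

Builds per-campaign environmental records (annual means, Tempsd, area,
WLF), log-transforms and reduces them by PCA with the axis-naming rule,
checks the complete-data subset's representativeness by PERMANOVA, and
fits the stepwise additive mixed models for every D_max / R_max response.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lakeddg import io as lio
from lakeddg.ddg import all_measures, measures_frame
from lakeddg.env import build_env_records, log_transform, pca_drivers, representativeness_check
from lakeddg.gamm import fit_gamm
from lakeddg.partition import all_profiles

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()

    surveys = lio.read_surveys(args.data / "surveys.csv")
    metas = lio.read_lakes(args.data / "lakes.csv")
    wls = lio.read_waterlevel(args.data / "waterlevel.csv")
    monthly = lio.read_monthly(args.data / "monthly.csv")
    records, _ = lio.filter_records(surveys, metas)

    profiles = all_profiles(records)
    campaigns = [(p.lake_id, p.year) for p in profiles]
    env = build_env_records(monthly, metas, wls, campaigns)
    env.to_csv(args.out / "env_records.csv", index=False)
    complete = env.dropna().reset_index(drop=True)
    print(f"environmental records: {len(env)} campaigns, {len(complete)} complete")

    pca = pca_drivers(log_transform(complete.drop(columns=["lake_id", "year"])))
    pca.loadings.to_csv(args.out / "pca_loadings.csv")
    print(f"retained {pca.n_retained} axes (cumulative variance "
          f"{pca.explained[:pca.n_retained].sum():.0%}):")
    for k, names in enumerate(pca.axis_names):
        print(f"  PC{k+1} ({pca.explained[k]:.0%}): {' & '.join(names) or '(mixed)'}")

    mwide = measures_frame(all_measures(records)).pivot_table(
        index=["lake_id", "year"], columns="component", values=["d_max", "r_max"]
    )
    mwide.columns = [f"{a}_{b}" for a, b in mwide.columns]

    # representativeness of the complete-data campaigns
    keys = set(map(tuple, complete[["lake_id", "year"]].itertuples(index=False)))
    full = mwide.reset_index()
    in_sub = full.apply(lambda r: (r.lake_id, int(r.year)) in keys, axis=1)
    cols = [c for c in full.columns if c not in ("lake_id", "year")]
    if in_sub.all() or not in_sub.any():
        print("representativeness: trivial (complete tier covers everything)")
    else:
        f, p = representativeness_check(
            full.loc[in_sub, cols], full.loc[~in_sub, cols], n_perm=999, seed=args.seed
        )
        verdict = "representative" if p > 0.05 else "NOT representative"
        print(f"PERMANOVA: pseudo-F = {f:.2f}, p = {p:.3f} -> {verdict}")

    model_data = complete[["lake_id", "year"]].join(pca.scores).merge(
        full, on=["lake_id", "year"]
    )
    axes = list(pca.scores.columns)
    report = {}
    for resp in cols:
        res = fit_gamm(model_data, resp, axes)
        report[resp] = res.to_dict()
        kept = ", ".join(
            f"{t} (p={res.p_values[t]:.3g}, dc={res.drop_contribution[t]:.1f}%)"
            for t in res.retained
        )
        print(f"  {resp}: adjR2 = {res.adj_r2:.2f}; retained: {kept or 'none'}")
    (args.out / "gamm_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
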