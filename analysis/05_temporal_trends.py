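#!/usr/bin/env python
"""Temporal stability and per-lake trends of the DDG measures.

Computes invariability coefficients (IC = mean/sd over survey years) and
the per-lake plus pooled linear-trend table for total gamma richness and
all D_max / R_max measures, writing trend_table.csv, trend_matrix.csv and
invariability.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from lakeddg import io as lio
from lakeddg.ddg import all_measures, measures_frame
from lakeddg.partition import all_profiles, summary_frame
from lakeddg.trends import invariability, trend_frame, trend_matrix, trend_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    surveys = lio.read_surveys(args.data / "surveys.csv")
    metas = lio.read_lakes(args.data / "lakes.csv")
    records, _ = lio.filter_records(surveys, metas)

    profiles = all_profiles(records)
    mwide = measures_frame(all_measures(records)).pivot_table(
        index=["lake_id", "year"], columns="component", values=["d_max", "r_max"]
    )
    mwide.columns = [f"{a}_{b}" for a, b in mwide.columns]
    data = mwide.join(
        summary_frame(profiles).set_index(["lake_id", "year"])["total_gamma"]
    ).reset_index()
    cols = [c for c in data.columns if c not in ("lake_id", "year")]

    results, skipped = trend_table(data, cols)
    trend_frame(results).to_csv(args.out / "trend_table.csv", index=False)
    mat = trend_matrix(results)
    mat.to_csv(args.out / "trend_matrix.csv")

    inv_rows = []
    for lake in sorted(data["lake_id"].unique()):
        sub = data[data["lake_id"] == lake]
        for col in cols:
            # depth measures are negative; stability is assessed on magnitude
            vals = sub[col].dropna().abs()
            if len(vals) >= 3 and vals.mean() > 0:
                r = invariability(vals, lake, col)
                inv_rows.append(
                    {"lake_id": lake, "measure": col, "ic": r.ic, "stable": r.infinitely_stable}
                )
    inv = pd.DataFrame(inv_rows)
    inv.to_csv(args.out / "invariability.csv", index=False)

    print("trend matrix (sign + significance mark, lakes x measures):")
    print(mat.to_string())
    if skipped:
        print(f"skipped (too few years): {skipped}")
    pooled = trend_frame(results).query("lake_id == 'ALL'")
    flags = pooled[pooled["p"] < 0.1]
    print(f"\npooled trends flagged at p < .1: {len(flags)}/{len(pooled)}")
    finite = inv[~inv["stable"]]
    n_stable = int(inv["stable"].sum())
    print(f"mean IC per measure (excluding {n_stable} perfectly stable series):")
    print(finite.groupby("measure")["ic"].mean().round(2).to_string())


if __name__ == "__main__":
    main()
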