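"""Shared fixtures: compact builders for survey tables and lake metadata."""

from __future__ import annotations

import pandas as pd
import pytest

from lakeddg.io import LakeMeta, SURVEY_COLUMNS


def make_records(rows, lake_id="L1", year=2010):
    """Build a survey frame from (transect, depth_label, taxon) tuples.

    Longer tuples may override (rank, growth_form, kohler_freq).
    """
    out = []
    for row in rows:
        transect, depth, taxon = row[:3]
        rank = row[3] if len(row) > 3 else "species"
        growth = row[4] if len(row) > 4 else "submerged"
        kohler = row[5] if len(row) > 5 else 1
        out.append((lake_id, year, transect, depth, taxon, rank, growth, kohler))
    return pd.DataFrame(out, columns=SURVEY_COLUMNS)


def make_meta(lake_id="L1", **kw):
    defaults = dict(
        area_ha=500.0,
        max_depth_m=40.0,
        mixing_regime="dimictic",
        natural=True,
        natural_water_level=True,
    )
    defaults.update(kw)
    return LakeMeta(lake_id=lake_id, **defaults)


@pytest.fixture
def toy_campaign():
    """Two transects sharing one of three species at the surface class."""
    return make_records(
        [
            ("T1", "0-1", "A"),
            ("T1", "0-1", "B"),
            ("T2", "0-1", "B"),
            ("T2", "0-1", "C"),
        ]
    )
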