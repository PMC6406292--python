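"""Bundled reference tables.

``load_cohort_margins`` returns the published per-stratum counts of a large
Sydney cohort of adults aged 45+ (stratum size N and outcome counts for
overweight and obesity, with the printed percentages): the marginal fixture
the synthetic generator is proportioned from, and the regression target for
the reference-exclusion prevalence tabulation.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_cohort_margins", "margins_to_records"]


def load_cohort_margins() -> pd.DataFrame:
    """Per-stratum counts and printed prevalences of the source cohort.

    Columns: variable, stratum, N, n_overweight, n_obese, pct_overweight,
    pct_obese.  The 'cohort' row holds the whole-sample totals.
    """
    with resources.files("walkbym").joinpath("data/sydney_cohort_margins.csv").open() as fh:
        return pd.read_csv(fh)


def margins_to_records(margins: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Expand one variable's margin rows into a pseudo-cohort of individual
    records (area_id is a dummy), suitable for ``prevalence_table``."""
    rows = margins.loc[margins["variable"] == variable]
    if rows.empty:
        raise ValueError(f"no margin rows for variable {variable!r}")
    strata: list[np.ndarray] = []
    cats: list[np.ndarray] = []
    for _, r in rows.iterrows():
        n_ow, n_ob, n_tot = int(r["n_overweight"]), int(r["n_obese"]), int(r["N"])
        n_ref = n_tot - n_ow - n_ob
        if n_ref < 0:
            raise ValueError(f"stratum {r['stratum']!r}: counts exceed N")
        strata.append(np.repeat(r["stratum"], n_tot))
        cats.append(np.concatenate([
            np.repeat("underweight_normal", n_ref),
            np.repeat("overweight", n_ow),
            np.repeat("obese", n_ob),
        ]))
    return pd.DataFrame({
        "area_id": np.repeat("all", sum(len(s) for s in strata)),
        "bmi_category": np.concatenate(cats),
        variable: np.concatenate(strata),
    })
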