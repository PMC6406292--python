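"""Walkability index construction.

The index combines three built-environment components per area — residential
dwelling density, density of 3+-way intersections, and land-use-mix entropy —
by scoring each into deciles (1 = lowest, 10 = highest), summing to a total in
3..30, and cutting totals into quartiles labelled low / low-medium /
medium-high / high.

Tie rule (used for deciles, quartiles and the quintile maps downstream):
values are given average ranks; a value whose average rank falls exactly on a
bin cut-point is assigned the lower bin (bins are the half-open rank intervals
((b-1)n/B, bn/B]).  This is deterministic and invariant under strictly
increasing transforms of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "QUARTILE_LABELS",
    "land_use_entropy",
    "rank_bins",
    "decile_scores",
    "total_and_quartile",
    "score_components",
]

QUARTILE_LABELS = ("low", "low-medium", "medium-high", "high")


def land_use_entropy(proportions, tol: float = 1e-8) -> float:
    """Normalised Shannon entropy of land-use proportions.

    -sum(p_k ln p_k) / ln K with 0 ln 0 := 0; 0 for a single land use, 1 for a
    uniform mix over the K use classes.
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need a 1-d vector of at least 2 land-use proportions")
    if np.any(p < -tol) or not np.all(np.isfinite(p)):
        raise ValueError("proportions must be finite and non-negative")
    if abs(p.sum() - 1.0) > max(tol, 1e-6):
        raise ValueError(f"proportions sum to {p.sum():.6g}, not 1")
    p = np.clip(p, 0.0, None)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def rank_bins(values, n_bins: int) -> np.ndarray:
    """Average-rank binning into ``n_bins`` classes 1..n_bins, lowest first.

    bin = ceil(B * r / n) for average rank r; exact cut-points go to the lower
    bin because the rank intervals are half-open on the left.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    r = rankdata(v, method="average")
    b = np.ceil(n_bins * r / v.size).astype(int)
    return np.clip(b, 1, n_bins)


def decile_scores(values) -> np.ndarray:
    """Score per-area component values into deciles 1 (lowest) .. 10 (highest)."""
    return rank_bins(values, 10)


@dataclass(frozen=True)
class WalkabilityScore:
    """Per-area index: three decile scores, their total (3..30), quartile label."""

    decile_scores: tuple[int, int, int]
    total: int
    quartile: str

    def __post_init__(self) -> None:
        if self.total != sum(self.decile_scores):
            raise ValueError("total must equal the sum of the decile scores")
        if not 3 <= self.total <= 30:
            raise ValueError("total must lie in 3..30")
        if self.quartile not in QUARTILE_LABELS:
            raise ValueError(f"unknown quartile label {self.quartile!r}")


def total_and_quartile(d1, d2, d3) -> list[WalkabilityScore]:
    """Sum three per-area decile score vectors and classify the totals into
    empirical quartiles across areas (low .. high walkability)."""
    a, b, c = (np.asarray(x, dtype=int) for x in (d1, d2, d3))
    if not (a.shape == b.shape == c.shape) or a.ndim != 1:
        raise ValueError("decile score vectors must be 1-d and of equal length")
    for v in (a, b, c):
        if v.size and (v.min() < 1 or v.max() > 10):
            raise ValueError("decile scores must lie in 1..10")
    totals = a + b + c
    quart = rank_bins(totals, 4)
    return [
        WalkabilityScore((int(a[i]), int(b[i]), int(c[i])), int(totals[i]),
                         QUARTILE_LABELS[quart[i] - 1])
        for i in range(totals.size)
    ]


def score_components(components: pd.DataFrame) -> pd.DataFrame:
    """Score an area table of raw components into the full index.

    ``components`` needs columns area_id, residential_density,
    intersection_density, land_use_mix.  Returns area_id, the three decile
    scores, total and quartile label.
    """
    required = ["area_id", "residential_density", "intersection_density", "land_use_mix"]
    missing = [c for c in required if c not in components.columns]
    if missing:
        raise ValueError(f"missing component columns: {missing}")
    lum = components["land_use_mix"].to_numpy(dtype=float)
    if np.any((lum < 0) | (lum > 1)):
        raise ValueError("land_use_mix entropy must lie in [0, 1]")
    d1 = decile_scores(components["residential_density"])
    d2 = decile_scores(components["intersection_density"])
    d3 = decile_scores(lum)
    scores = total_and_quartile(d1, d2, d3)
    return pd.DataFrame(
        {
            "area_id": components["area_id"].to_numpy(),
            "residential_density_decile": d1,
            "intersection_density_decile": d2,
            "land_use_mix_decile": d3,
            "total": [s.total for s in scores],
            "quartile": [s.quartile for s in scores],
        }
    )
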