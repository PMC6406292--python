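"""Posterior decomposition into mappable prevalence-ratio surfaces and the
six-model suite.

Per area the fitted random effects decompose excess prevalence into a Total
surface exp(s+u), a Spatial surface exp(s) and an Unstructured surface exp(u)
(posterior medians), classed into quintiles for mapping.  The spatial fraction
rho = Vs/(Vs+Vu) — computed per draw from the empirical variances of {s_j} and
{u_j} across areas — indexes how much residual between-area variation is
spatially structured.

The model suite fits, per outcome: (1) null model with unadjusted offsets,
(2) null with adjusted offsets, (3) + walkability, (4) + disadvantage,
(5) + both, (6) + both + their interaction; models are compared by DIC on
identical data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .areal_graph import AdjacencyGraph
from .bym import BYMPosterior, BYMSpec, ChainSettings, TEST_PRESET, run_chains
from .walkability import rank_bins

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_SPECS",
    "RiskMaps",
    "ModelSuiteResult",
    "spatial_fraction",
    "decompose_risk",
    "classify_quintiles",
    "run_model_suite",
    "export_maps",
]

# Models 1-6 of the suite; 3-6 all use adjusted offsets.
MODEL_SPECS: dict[int, BYMSpec] = {
    1: BYMSpec(offset_kind="unadjusted"),
    2: BYMSpec(offset_kind="adjusted"),
    3: BYMSpec(offset_kind="adjusted", covariates=("walkability",)),
    4: BYMSpec(offset_kind="adjusted", covariates=("disadvantage",)),
    5: BYMSpec(offset_kind="adjusted", covariates=("walkability", "disadvantage")),
    6: BYMSpec(offset_kind="adjusted", covariates=("walkability", "disadvantage"),
               interaction=True),
}


def spatial_fraction(posterior: BYMPosterior) -> float:
    """Posterior median of rho = Vs/(Vs+Vu) over kept draws, where Vs and Vu
    are the across-area empirical variances of s and u in each draw.  A draw
    with both variances zero contributes 0.5 by convention (flagged)."""
    s = posterior.pooled("s")
    u = posterior.pooled("u")
    vs = s.var(axis=1)
    vu = u.var(axis=1)
    total = vs + vu
    rho = np.full(total.shape, 0.5)
    nz = total > 0
    rho[nz] = vs[nz] / total[nz]
    if np.any(~nz):
        logger.warning("spatial_fraction: %d draw(s) with zero total variance "
                       "contribute rho = 0.5 by convention", int((~nz).sum()))
    return float(np.median(rho))


@dataclass(frozen=True)
class RiskMaps:
    """Per-area posterior-median prevalence-ratio surfaces with quintile
    classes (1 = lowest ratio .. 5 = highest)."""

    area_ids: tuple[str, ...]
    total_pr: np.ndarray
    spatial_pr: np.ndarray
    unstructured_pr: np.ndarray
    total_class: np.ndarray
    spatial_class: np.ndarray
    unstructured_class: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "area_id": list(self.area_ids),
            "total_pr": self.total_pr,
            "spatial_pr": self.spatial_pr,
            "unstructured_pr": self.unstructured_pr,
            "total_quintile": self.total_class,
            "spatial_quintile": self.spatial_class,
            "unstructured_quintile": self.unstructured_class,
        })


def classify_quintiles(surface) -> np.ndarray:
    """Rank-based quintile classes 1..5 (same tie rule as the walkability
    deciles)."""
    surface = np.asarray(surface, dtype=float)
    if surface.size < 5:
        raise ValueError("need at least 5 areas for quintile classes")
    return rank_bins(surface, 5)


def decompose_risk(posterior: BYMPosterior) -> RiskMaps:
    """Per-area posterior medians of exp(s+u), exp(s) and exp(u); the median
    of the Total surface is taken over per-draw products, not the product of
    medians."""
    s = posterior.pooled("s")
    u = posterior.pooled("u")
    total = np.median(np.exp(s + u), axis=0)
    spatial = np.median(np.exp(s), axis=0)
    unstructured = np.median(np.exp(u), axis=0)
    return RiskMaps(
        area_ids=posterior.area_ids,
        total_pr=total, spatial_pr=spatial, unstructured_pr=unstructured,
        total_class=classify_quintiles(total),
        spatial_class=classify_quintiles(spatial),
        unstructured_class=classify_quintiles(unstructured),
    )


@dataclass
class ModelSuiteResult:
    """All six fitted models for one outcome, with DIC comparison."""

    outcome: str
    posteriors: dict[int, BYMPosterior]
    dic: dict[int, float]
    p_d: dict[int, float]
    spatial_fractions: dict[int, float]
    pr_range: dict[int, tuple[float, float]]  # min/max smoothed total PR
    best_model: int

    def dic_delta(self) -> dict[int, float]:
        best = self.dic[self.best_model]
        return {m: d - best for m, d in self.dic.items()}

    def summary_json(self) -> dict:
        out = {"outcome": self.outcome, "best_model": self.best_model, "models": {}}
        for m, post in self.posteriors.items():
            out["models"][str(m)] = {
                "offset_kind": post.spec.offset_kind,
                "covariates": list(post.spec.covariates),
                "interaction": post.spec.interaction,
                "dic": self.dic[m],
                "pD": self.p_d[m],
                "spatial_fraction": self.spatial_fractions[m],
                "pr_range": list(self.pr_range[m]),
                "prevalence_ratios": {
                    row["parameter"]: [row["median"], row["lo95"], row["hi95"]]
                    for _, row in post.summary().iterrows()
                    if row["parameter"].startswith("exp(")
                },
                "gelman_rubin": post.gelman,
                "warnings": post.warnings,
            }
        return out


def run_model_suite(
    outcome: str,
    area_table: pd.DataFrame,
    graph: AdjacencyGraph,
    settings: ChainSettings = TEST_PRESET,
    models: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
) -> ModelSuiteResult:
    """Fit the requested models of the suite with a shared seed policy
    (model m uses sub-seed m of ``settings.seed``) and select the minimum-DIC
    model."""
    for col in ("o", "e_unadj", "e_adj", "walkability", "disadvantage"):
        if col not in area_table.columns:
            raise ValueError(f"area_table lacks required column {col!r}")
    posteriors: dict[int, BYMPosterior] = {}
    dic_by: dict[int, float] = {}
    pd_by: dict[int, float] = {}
    rho_by: dict[int, float] = {}
    rng_seeds = {m: int(np.random.SeedSequence([settings.seed, m]).generate_state(1)[0]
                        % (2**31)) for m in models}
    pr_range: dict[int, tuple[float, float]] = {}
    for m in models:
        spec = MODEL_SPECS[m]
        post = run_chains(spec, area_table, graph,
                          settings=ChainSettings(settings.chains, settings.kept,
                                                 settings.thin, settings.burn_in,
                                                 rng_seeds[m]))
        posteriors[m] = post
        dic_by[m] = post.dic
        pd_by[m] = post.p_d
        rho_by[m] = spatial_fraction(post)
        maps = decompose_risk(post)
        pr_range[m] = (float(maps.total_pr.min()), float(maps.total_pr.max()))
        for w in post.warnings:
            logger.warning("model %d: %s", m, w)
    best = min(dic_by, key=dic_by.get)
    return ModelSuiteResult(outcome, posteriors, dic_by, pd_by, rho_by, pr_range, best)


def export_maps(maps: RiskMaps, csv_path, polygons: dict | None = None,
                geojson_path=None) -> None:
    """Write the surfaces as CSV, and as GeoJSON feature properties when a
    FeatureCollection with matching ids is given."""
    maps.to_frame().to_csv(csv_path, index=False)
    if polygons is None:
        return
    if geojson_path is None:
        raise ValueError("geojson_path required when polygons are given")
    by_id = {}
    for feat in polygons.get("features", []):
        props = feat.get("properties") or {}
        fid = str(props.get("id", feat.get("id")))
        by_id[fid] = feat
    missing = [a for a in maps.area_ids if a not in by_id]
    if missing:
        raise ValueError(f"no polygon for area(s): {missing[:5]}")
    frame = maps.to_frame().set_index("area_id")
    features = []
    for aid in maps.area_ids:
        feat = by_id[aid]
        props = dict(feat.get("properties") or {})
        props["id"] = aid
        for col in frame.columns:
            val = frame.loc[aid, col]
            props[col] = float(val) if "pr" in col else int(val)
        features.append({"type": "Feature", "geometry": feat["geometry"],
                         "properties": props})
    with open(geojson_path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
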