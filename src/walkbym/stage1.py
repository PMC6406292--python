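"""Stage 1: individual-level logistic models and expected-count offsets.

The two-stage design controls for individual-level composition before the
areal model ever sees the data.  Individual log odds of each dichotomous
outcome are modelled as l_ij = alpha + x_i beta; predicted probabilities
(inverse logit) are summed within areas to give expected counts e_j, which
enter the spatial Poisson model as offsets.  A null (intercept-only) model
yields "unadjusted" offsets — every area expects the pooled prevalence — and
the full covariate model yields "adjusted" offsets reflecting each area's
respondent mix.

Denominator convention (reference exclusion): the prevalence of one elevated
BMI category is computed against the underweight/normal reference only, with
the other elevated category excluded from the denominator.  Both the
tabulations and the stage-1 fits use these subsets; this is the only
convention under which the published stratum percentages are internally
consistent with their printed counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .areal_graph import AdjacencyGraph, exclusion_filter

logger = logging.getLogger(__name__)

__all__ = [
    "OUTCOMES",
    "PerfectSeparationError",
    "code_bmi_category",
    "analysis_subset",
    "prevalence_table",
    "prevalence_percent",
    "inclusion_rate",
    "LogisticFit",
    "fit_logistic",
    "predicted_probability",
    "predicted_probabilities",
    "expected_counts",
    "fit_report",
]

OUTCOMES = ("overweight", "obese")
_REFERENCE = "underweight_normal"


class PerfectSeparationError(RuntimeError):
    """The outcome is constant within some covariate level; the MLE diverges."""


# -- outcome coding --------------------------------------------------------

def code_bmi_category(
    weight_kg: float,
    height_m: float,
    weight_bounds: tuple[float, float] = (30.0, 250.0),
    height_bounds: tuple[float, float] = (1.0, 2.5),
) -> str | None:
    """Classify BMI = weight / height^2 with WHO cut-points.

    [25.0, 30.0) is overweight and >= 30.0 is obese (half-open intervals,
    lower bounds closed).  Values outside the plausibility bounds return None
    (missing) and are logged; non-positive inputs are an error.
    """
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    if not (weight_bounds[0] <= weight_kg <= weight_bounds[1]
            and height_bounds[0] <= height_m <= height_bounds[1]):
        logger.info("implausible anthropometry (%.1f kg, %.2f m) coded missing",
                    weight_kg, height_m)
        return None
    bmi = weight_kg / height_m**2
    if bmi >= 30.0:
        return "obese"
    if bmi >= 25.0:
        return "overweight"
    return _REFERENCE


def _check_outcome(outcome: str) -> None:
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")


def analysis_subset(records: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Reference-exclusion subset and binary outcome vector.

    The overweight analysis keeps reference + overweight individuals; the
    obese analysis keeps reference + obese.  The returned vector is 1 for the
    analysed outcome, 0 for the reference.
    """
    _check_outcome(outcome)
    cats = records["bmi_category"]
    subset = records.loc[cats.isin([_REFERENCE, outcome])].copy()
    y = (subset["bmi_category"] == outcome).to_numpy(dtype=int)
    return subset, y


def prevalence_percent(n_outcome: int, stratum_total: int, n_other: int) -> float:
    """Stratum prevalence under reference exclusion, in percent to 1 decimal:
    100 * n_outcome / (stratum_total - n_other); 0.0 for an empty denominator."""
    denom = stratum_total - n_other
    if denom <= 0 or n_outcome == 0:
        return 0.0
    return round(100.0 * n_outcome / denom, 1)


def prevalence_table(records: pd.DataFrame, outcome: str, stratifier: str) -> pd.DataFrame:
    """Tabulate stratum size N, outcome count n and reference-exclusion
    prevalence % of ``outcome`` by the levels of ``stratifier``.

    ``stratifier`` may be any individual covariate column or an area-level
    covariate column previously merged onto the records.
    """
    _check_outcome(outcome)
    if stratifier not in records.columns:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    other = [o for o in OUTCOMES if o != outcome][0]
    grp = records.groupby(stratifier, sort=False, observed=True)["bmi_category"]
    N = grp.size()
    n = grp.apply(lambda c: int((c == outcome).sum()))
    n_other = grp.apply(lambda c: int((c == other).sum()))
    pct = [prevalence_percent(int(n[s]), int(N[s]), int(n_other[s])) for s in N.index]
    return pd.DataFrame({"stratum": N.index.to_numpy(), "N": N.to_numpy(),
                         "n": n.to_numpy(), "percent": pct})


def inclusion_rate(included: int, total: int) -> float:
    """Share of eligible units retained, in percent to 1 decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * included / total, 1)


# -- logistic fits ---------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """A fitted individual-level logistic model.

    ``coefficients`` maps ``"covariate=level"`` to its log odds ratio; the
    reference (first-listed) level of every covariate is exactly 0 and is not
    stored.  ``schema`` records the level order used for dummy coding.
    """

    intercept: float
    coefficients: dict[str, float]
    schema: dict[str, tuple[str, ...]]
    fitted_on: str
    iterations: int
    score_norm: float
    converged: bool
    standard_errors: dict[str, float] | None = None

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        """Per-record log odds; unseen covariate levels are an error."""
        l = np.full(len(records), self.intercept)
        for cov, levels in self.schema.items():
            vals = records[cov]
            unseen = set(vals.unique()) - set(levels)
            if unseen:
                raise ValueError(
                    f"covariate {cov!r} has level(s) {sorted(unseen)} unseen by the fit")
            for level in levels[1:]:
                l += np.where(vals == level, self.coefficients[f"{cov}={level}"], 0.0)
        return l


def _build_design(records: pd.DataFrame, schema: Mapping[str, Sequence[str]]
                  ) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(records))]
    names = ["intercept"]
    for cov, levels in schema.items():
        observed = set(records[cov].unique())
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(f"covariate {cov!r} has undeclared level(s) {sorted(unknown)}")
        for level in levels[1:]:
            cols.append((records[cov] == level).to_numpy(dtype=float))
            names.append(f"{cov}={level}")
    return np.column_stack(cols), names


def _separation_check(records: pd.DataFrame, y: np.ndarray,
                      schema: Mapping[str, Sequence[str]]) -> None:
    for cov in schema:
        rate = pd.Series(y).groupby(records[cov].to_numpy()).mean()
        bad = rate[(rate == 0.0) | (rate == 1.0)]
        if len(bad):
            raise PerfectSeparationError(
                f"perfect separation: outcome is constant within level(s) "
                f"{list(bad.index)} of covariate {cov!r}")


def fit_logistic(
    records: pd.DataFrame,
    y: np.ndarray,
    schema: Mapping[str, Sequence[str]] | None,
    fitted_on: str = "",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression on dummy-coded covariate levels.

    ``schema`` maps each covariate to its level order (first level =
    reference); pass None or {} for the null model, whose intercept is the
    exact closed form logit(pooled prevalence).  Fitting is iteratively
    reweighted least squares (via the binomial GLM machinery); convergence
    requires the maximum absolute score below ``tol``.
    """
    y = np.asarray(y)
    p_bar = float(np.mean(y))
    if p_bar in (0.0, 1.0):
        raise ValueError("outcome is constant; the logistic MLE does not exist")
    if not schema:
        return LogisticFit(float(np.log(p_bar / (1 - p_bar))), {}, {},
                           fitted_on or "null", 0, 0.0, True)

    schema = {cov: tuple(levels) for cov, levels in schema.items()}
    _separation_check(records, y, schema)
    X, names = _build_design(records, schema)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
    score = model.score(res.params)
    score_norm = float(np.max(np.abs(score)))
    converged = bool(res.converged) and score_norm < max(tol * len(y), 1e-6)
    if not converged:
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} IRLS iterations "
            f"(max |score| = {score_norm:.3g})")
    se = np.sqrt(np.diag(res.cov_params()))
    coef = {name: float(b) for name, b in zip(names[1:], res.params[1:])}
    ses = {name: float(s) for name, s in zip(names, se)}
    return LogisticFit(float(res.params[0]), coef, schema, fitted_on or "adjusted",
                       int(getattr(res, "fit_history", {}).get("iteration", max_iter)),
                       score_norm, True, ses)


def predicted_probability(fit: LogisticFit, record: Mapping[str, str]) -> float:
    """Inverse-logit of one record's log odds (numerically stable)."""
    df = pd.DataFrame([dict(record)])
    return float(predicted_probabilities(fit, df)[0])


def predicted_probabilities(fit: LogisticFit, records: pd.DataFrame) -> np.ndarray:
    # clamp inside the open interval so extreme log odds cannot round to 0 or 1
    return np.clip(expit(fit.linear_predictor(records)), 1e-12, 1.0 - 1e-12)


# -- offsets ---------------------------------------------------------------

def expected_counts(
    null_fit: LogisticFit,
    adjusted_fit: LogisticFit,
    records: pd.DataFrame,
    y: np.ndarray,
    graph: AdjacencyGraph,
    area_covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, AdjacencyGraph]:
    """Aggregate the analysis subset to the per-area table used by the
    spatial model.

    Returns (table, filtered graph): per area, n (subset respondents),
    o (observed outcome count), e_unadj (null-model expected count) and e_adj
    (covariate-model expected count); areas with zero subset respondents or
    zero neighbours are dropped by the exclusion filter and logged.  With an
    intercept in each fit, sum(e) = sum(o) for both offset kinds.
    """
    if not set(records["area_id"].unique()) <= set(graph.area_ids):
        stray = sorted(set(records["area_id"].unique()) - set(graph.area_ids))
        raise ValueError(f"records reference areas absent from the graph: {stray[:5]}")
    p_null = predicted_probabilities(null_fit, records)
    p_adj = predicted_probabilities(adjusted_fit, records)
    agg = pd.DataFrame({
        "area_id": records["area_id"].to_numpy(),
        "o": np.asarray(y, dtype=float),
        "e_unadj": p_null,
        "e_adj": p_adj,
        "n": 1.0,
    }).groupby("area_id", sort=False).sum().reset_index()

    counts = dict(zip(agg["area_id"], agg["n"].astype(int)))
    fgraph, excluded = exclusion_filter(graph, counts)
    if excluded:
        logger.info("expected_counts: excluded %d area(s): %s", len(excluded), excluded)
    table = (agg.set_index("area_id").reindex(list(fgraph.area_ids)).reset_index())
    table["n"] = table["n"].astype(int)
    table["o"] = table["o"].astype(int)
    if area_covariates is not None:
        table = table.merge(area_covariates, on="area_id", how="left", validate="1:1")
    return table[["area_id", "n", "o", "e_unadj", "e_adj"]
                 + [c for c in table.columns
                    if c not in ("area_id", "n", "o", "e_unadj", "e_adj")]], fgraph


def fit_report(fit: LogisticFit) -> dict:
    """Coefficients as odds ratios with Wald 95% confidence intervals."""
    rows = []
    for name, b in fit.coefficients.items():
        se = (fit.standard_errors or {}).get(name)
        ci = (float(np.exp(b - 1.959963984540054 * se)),
              float(np.exp(b + 1.959963984540054 * se))) if se is not None else None
        rows.append({"term": name, "log_or": b, "or": float(np.exp(b)),
                     "ci95": ci})
    return {
        "fitted_on": fit.fitted_on,
        "intercept": fit.intercept,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "score_norm": fit.score_norm,
        "terms": rows,
    }
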