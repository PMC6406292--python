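"""Besag-York-Mollié (BYM) spatial Poisson regression by Metropolis-within-Gibbs.

Model, per area j with observed count o_j and expected-count offset e_j:

    o_j ~ Poisson(theta_j e_j),
    log(theta_j) = alpha + x_j' beta + s_j + u_j,

with s an intrinsic CAR (ICAR) field over the contiguity graph — each s_j is
conditionally normal around the mean of its k_j neighbours with variance
sigma_s^2 / k_j — and u_j i.i.d. N(0, sigma_u^2).  exp(alpha) is the study-area
prevalence ratio and exp(beta) are prevalence ratios versus reference levels.

Sampling scheme
---------------
* s: single-site random-walk Metropolis, vectorised over colour classes of the
  contiguity graph (areas in an independent set have mutually independent full
  conditionals, so they update simultaneously).  After every sweep s is
  re-centred to per-component mean zero, the subtracted (size-weighted) mean
  being absorbed into alpha — the ICAR prior is flat along that direction and
  the shift leaves every theta_j unchanged on connected graphs.
* u, alpha, beta: random-walk Metropolis (u vectorised across areas).
* precisions tau_s = 1/sigma_s^2, tau_u = 1/sigma_u^2: exact Gibbs draws from
  their gamma full conditionals under Gamma(a, b) hyperpriors.
* proposal scales adapt in batches during burn-in only (targeting ~0.44
  acceptance), preserving detailed balance afterwards.

Priors default to N(0, 1000) on alpha and each beta and Gamma(0.5, 0.0005) on
both precisions (a long-standing disease-mapping convention); all are
configurable, and either precision may be held fixed (used by the brute-force
oracle comparisons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .areal_graph import AdjacencyGraph, component_labels
from .synthetic_cohort import DISADVANTAGE_LEVELS, WALKABILITY_LEVELS

logger = logging.getLogger(__name__)

__all__ = [
    "BYMSpec",
    "ChainSettings",
    "PAPER_PRESET",
    "TEST_PRESET",
    "BYMData",
    "SamplerState",
    "BYMPosterior",
    "log_likelihood",
    "icar_log_density",
    "build_design",
    "gibbs_step_s",
    "gibbs_step_u",
    "gibbs_step_fixed",
    "gibbs_step_precisions",
    "run_chains",
    "gelman_rubin",
    "autocorrelation",
    "dic",
]

AREA_LEVELS: dict[str, tuple[str, ...]] = {
    "walkability": WALKABILITY_LEVELS,
    "disadvantage": DISADVANTAGE_LEVELS,
}


@dataclass(frozen=True)
class BYMSpec:
    """One model of the six-model suite: offset kind, area covariate terms,
    optional interaction, and priors."""

    offset_kind: str = "unadjusted"  # or "adjusted"
    covariates: tuple[str, ...] = ()
    interaction: bool = False
    intercept_prior_var: float = 1000.0
    coef_prior_var: float = 1000.0
    precision_prior: tuple[float, float] = (0.5, 0.0005)  # gamma shape, rate
    fixed_tau_s: float | None = None
    fixed_tau_u: float | None = None

    def __post_init__(self) -> None:
        if self.offset_kind not in ("unadjusted", "adjusted"):
            raise ValueError("offset_kind must be 'unadjusted' or 'adjusted'")
        unknown = set(self.covariates) - set(AREA_LEVELS)
        if unknown:
            raise ValueError(f"unknown area covariates {sorted(unknown)}")
        if self.interaction and set(self.covariates) != set(AREA_LEVELS):
            raise ValueError("interaction requires both main-effect terms")
        if self.intercept_prior_var <= 0 or self.coef_prior_var <= 0:
            raise ValueError("prior variances must be positive")
        if min(self.precision_prior) <= 0:
            raise ValueError("precision hyperprior parameters must be positive")


@dataclass(frozen=True)
class ChainSettings:
    """MCMC protocol: ``chains`` independent chains, keeping every ``thin``-th
    post-burn-in state until ``kept`` draws per chain.  Burn-in defaults to
    one ninth of the sampling phase, i.e. 10% of total iterations."""

    chains: int = 2
    kept: int = 500
    thin: int = 10
    burn_in: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.kept < 1 or self.thin < 1:
            raise ValueError("chains, kept and thin must be positive")

    @property
    def burn(self) -> int:
        return self.burn_in if self.burn_in is not None else (self.kept * self.thin) // 9


PAPER_PRESET = ChainSettings(chains=2, kept=5000, thin=250)
TEST_PRESET = ChainSettings(chains=2, kept=500, thin=10)


# -- densities -------------------------------------------------------------

def log_likelihood(o, e, linpred) -> float:
    """Full Poisson log likelihood sum_j [o_j (linpred_j + ln e_j)
    - e_j exp(linpred_j) - ln o_j!]."""
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    lp = np.asarray(linpred, dtype=float)
    if np.any(o < 0):
        raise ValueError("counts must be non-negative")
    if np.any(e <= 0):
        raise ValueError("offsets must be positive")
    return float(np.sum(o * (lp + np.log(e)) - e * np.exp(lp) - gammaln(o + 1.0)))


def icar_log_density(s, tau_s: float, graph: AdjacencyGraph) -> float:
    """Unnormalised ICAR log density -(tau_s/2) sum_{i~j, i<j} (s_i - s_j)^2."""
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    s = np.asarray(s, dtype=float)
    ea = graph.edge_array()
    if ea.shape[0] == 0:
        return 0.0
    d = s[ea[:, 0]] - s[ea[:, 1]]
    return float(-(tau_s / 2.0) * (d @ d))


# -- design matrix ---------------------------------------------------------

def build_design(area_table, spec: BYMSpec) -> tuple[np.ndarray, list[str]]:
    """0/1 dummy design for the spec's area covariates (reference = first
    level; interaction = full cross of non-reference dummies)."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    order = [c for c in ("walkability", "disadvantage") if c in spec.covariates]
    for cov in order:
        levels = AREA_LEVELS[cov]
        vals = area_table[cov].to_numpy()
        unknown = set(vals) - set(levels)
        if unknown:
            raise ValueError(f"{cov}: unknown level(s) {sorted(unknown)}")
        for level in levels[1:]:
            cols.append((vals == level).astype(float))
            names.append(f"{cov}={level}")
    if spec.interaction:
        wvals = area_table["walkability"].to_numpy()
        dvals = area_table["disadvantage"].to_numpy()
        for wl in WALKABILITY_LEVELS[1:]:
            for dl in DISADVANTAGE_LEVELS[1:]:
                cols.append(((wvals == wl) & (dvals == dl)).astype(float))
                names.append(f"walkability={wl}:disadvantage={dl}")
    if cols:
        return np.column_stack(cols), names
    return np.zeros((len(area_table), 0)), names


# -- sampler machinery -----------------------------------------------------

class BYMData:
    """Immutable per-fit data: counts, offsets, design, graph structure and
    the colour classes used for vectorised s updates."""

    def __init__(self, o, e, X: np.ndarray, coef_names: Sequence[str],
                 graph: AdjacencyGraph):
        self.o = np.asarray(o, dtype=float)
        self.e = np.asarray(e, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.coef_names = list(coef_names)
        self.graph = graph
        n = graph.n_areas
        if not (self.o.shape == self.e.shape == (n,)) or self.X.shape[0] != n:
            raise ValueError("o, e and X must align with the graph's areas")
        if np.any(self.o < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.e <= 0):
            raise ValueError("offsets must be positive")
        self.k = graph.k.astype(float)
        if np.any(self.k < 1):
            bad = [graph.area_ids[i] for i in np.where(self.k < 1)[0]]
            raise ValueError(
                f"areas with no neighbours cannot enter the ICAR prior: {bad}; "
                f"apply the exclusion filter first")
        self.edges = graph.edge_array()
        coloring = nx.greedy_color(graph.to_networkx(), strategy="largest_first")
        n_colors = max(coloring.values()) + 1
        self.color_classes = [
            np.array(sorted(j for j, c in coloring.items() if c == col), dtype=int)
            for col in range(n_colors)
        ]
        self.comp_labels = component_labels(graph)
        self.n_components = int(self.comp_labels.max()) + 1
        # adjacency in CSR-ish form for neighbour sums
        import scipy.sparse as sp
        rows = np.concatenate([self.edges[:, 0], self.edges[:, 1]]) if len(self.edges) else np.array([], dtype=int)
        cols = np.concatenate([self.edges[:, 1], self.edges[:, 0]]) if len(self.edges) else np.array([], dtype=int)
        self.adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        self.n = n
        self.p = self.X.shape[1]
        self.beta_masks = [np.where(self.X[:, p] != 0)[0] for p in range(self.p)]


@dataclass
class SamplerState:
    """Mutable chain state.  ``scale_*`` are random-walk proposal scales
    (adapted during burn-in only)."""

    alpha: float
    beta: np.ndarray
    s: np.ndarray
    u: np.ndarray
    tau_s: float
    tau_u: float
    scale_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale_u: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale_alpha: float = 0.1
    scale_beta: np.ndarray = field(default=None)  # type: ignore[assignment]

    def linpred(self, data: BYMData) -> np.ndarray:
        return self.alpha + data.X @ self.beta + self.s + self.u


def _init_state(data: BYMData, rng: np.random.Generator) -> SamplerState:
    alpha0 = float(np.log(max(data.o.sum(), 0.5) / data.e.sum()))
    s0 = 0.1 * rng.standard_normal(data.n)
    for c in range(data.n_components):
        mask = data.comp_labels == c
        s0[mask] -= s0[mask].mean()
    return SamplerState(
        alpha=alpha0,
        beta=np.zeros(data.p),
        s=s0,
        u=0.05 * rng.standard_normal(data.n),
        tau_s=100.0,
        tau_u=100.0,
        scale_s=np.full(data.n, 0.2),
        scale_u=np.full(data.n, 0.2),
        scale_alpha=0.05,
        scale_beta=np.full(data.p, 0.1),
    )


def gibbs_step_s(state: SamplerState, data: BYMData, rng: np.random.Generator,
                 recenter: bool = True) -> np.ndarray:
    """One Metropolis sweep over all s_j (by colour class), followed by
    per-component re-centring with the subtracted mean absorbed into alpha.
    Returns the per-area acceptance indicator."""
    accepted = np.zeros(data.n)
    fixed = state.alpha + data.X @ state.beta
    for cls in data.color_classes:
        cur = state.s[cls]
        prop = cur + state.scale_s[cls] * rng.standard_normal(cls.size)
        nsum = (data.adj @ state.s)[cls]
        eta_cur = fixed[cls] + cur + state.u[cls]
        eta_prop = fixed[cls] + prop + state.u[cls]
        d_lik = data.o[cls] * (prop - cur) - data.e[cls] * (np.exp(eta_prop) - np.exp(eta_cur))
        d_pri = -(state.tau_s / 2.0) * (data.k[cls] * (prop**2 - cur**2)
                                        - 2.0 * (prop - cur) * nsum)
        acc = np.log(rng.random(cls.size)) < d_lik + d_pri
        state.s[cls] = np.where(acc, prop, cur)
        accepted[cls] = acc
    if recenter:
        shift = 0.0
        for c in range(data.n_components):
            mask = data.comp_labels == c
            m = state.s[mask].mean()
            state.s[mask] -= m
            shift += m * mask.sum() / data.n
        state.alpha += shift
    return accepted


def gibbs_step_u(state: SamplerState, data: BYMData, rng: np.random.Generator) -> np.ndarray:
    """Vectorised Metropolis update of every u_j against its Poisson term and
    N(0, 1/tau_u) prior.  Returns the per-area acceptance indicator."""
    fixed = state.alpha + data.X @ state.beta + state.s
    cur = state.u
    prop = cur + state.scale_u * rng.standard_normal(data.n)
    d_lik = data.o * (prop - cur) - data.e * (np.exp(fixed + prop) - np.exp(fixed + cur))
    d_pri = -(state.tau_u / 2.0) * (prop**2 - cur**2)
    acc = np.log(rng.random(data.n)) < d_lik + d_pri
    state.u = np.where(acc, prop, cur)
    return acc.astype(float)


def gibbs_step_fixed(state: SamplerState, data: BYMData, spec: BYMSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Random-walk Metropolis updates of alpha and each beta (wide normal
    priors).  Returns acceptance indicators, alpha first."""
    acc = np.zeros(1 + data.p)
    w = data.e * np.exp(state.linpred(data))  # e_j exp(eta_j)

    delta = state.scale_alpha * rng.standard_normal()
    d_lik = delta * data.o.sum() - (np.exp(delta) - 1.0) * w.sum()
    d_pri = -((state.alpha + delta) ** 2 - state.alpha**2) / (2.0 * spec.intercept_prior_var)
    if np.log(rng.random()) < d_lik + d_pri:
        state.alpha += delta
        w *= np.exp(delta)
        acc[0] = 1.0

    for p in range(data.p):
        mask = data.beta_masks[p]
        delta = state.scale_beta[p] * rng.standard_normal()
        d_lik = delta * data.o[mask].sum() - (np.exp(delta) - 1.0) * w[mask].sum()
        b = state.beta[p]
        d_pri = -((b + delta) ** 2 - b**2) / (2.0 * spec.coef_prior_var)
        if np.log(rng.random()) < d_lik + d_pri:
            state.beta[p] = b + delta
            w[mask] *= np.exp(delta)
            acc[1 + p] = 1.0
    return acc


def gibbs_step_precisions(state: SamplerState, data: BYMData, spec: BYMSpec,
                          rng: np.random.Generator) -> None:
    """Exact Gibbs draws: tau_s ~ Gamma(a + (n-C)/2, b + pairwise_sum/2) with
    C connected components; tau_u ~ Gamma(a + n/2, b + sum(u^2)/2)."""
    a, b = spec.precision_prior
    if spec.fixed_tau_s is not None:
        state.tau_s = spec.fixed_tau_s
    else:
        if len(data.edges):
            d = state.s[data.edges[:, 0]] - state.s[data.edges[:, 1]]
            pair = float(d @ d)
        else:
            pair = 0.0
        shape = a + (data.n - data.n_components) / 2.0
        state.tau_s = rng.gamma(shape, 1.0 / (b + pair / 2.0))
    if spec.fixed_tau_u is not None:
        state.tau_u = spec.fixed_tau_u
    else:
        shape = a + data.n / 2.0
        state.tau_u = rng.gamma(shape, 1.0 / (b + float(state.u @ state.u) / 2.0))


# -- diagnostics -----------------------------------------------------------

def gelman_rubin(chains) -> float:
    """Potential scale reduction factor over >= 2 equal-length chains.

    Returns 1.0 for identical chains (B = 0 guard) and inf for the degenerate
    case of zero within-chain variance with separated chains."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, length = arr.shape
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    means = arr.mean(axis=1)
    B = length * float(np.var(means, ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_plus = (length - 1) / length * W + B / length
    return float(max(1.0, np.sqrt(var_plus / W)))


def autocorrelation(series, max_lag: int) -> np.ndarray:
    """Sample ACF at lags 1..max_lag, normalised by the lag-0 variance.
    A (numerically) constant series is degenerate and yields NaNs."""
    x = np.asarray(series, dtype=float)
    if x.size <= max_lag:
        raise ValueError("series must be longer than max_lag")
    xc = x - x.mean()
    c0 = float(xc @ xc) / x.size
    if c0 <= 1e-300:
        logger.warning("autocorrelation: constant series, ACF undefined")
        return np.full(max_lag, np.nan)
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        out[lag - 1] = float(xc[:-lag] @ xc[lag:]) / x.size / c0
    return out


def dic(linpred_draws: np.ndarray, o, e) -> tuple[float, float]:
    """Deviance Information Criterion from per-draw linear predictors.

    D = -2 log-likelihood; pD = mean(D) - D(posterior mean linear predictor,
    per area) — the "focused" version, stable in the presence of random
    effects; DIC = mean(D) + pD.
    """
    lp = np.atleast_2d(np.asarray(linpred_draws, dtype=float))
    devs = np.array([-2.0 * log_likelihood(o, e, lp[k]) for k in range(lp.shape[0])])
    d_bar = float(devs.mean())
    d_hat = -2.0 * log_likelihood(o, e, lp.mean(axis=0))
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d


# -- the posterior container ----------------------------------------------

@dataclass
class BYMPosterior:
    """Post-thinning draws (per chain) and derived summaries for one model."""

    area_ids: tuple[str, ...]
    coef_names: list[str]
    alpha: np.ndarray          # (chains, kept)
    beta: np.ndarray           # (chains, kept, p)
    s: np.ndarray              # (chains, kept, n)
    u: np.ndarray              # (chains, kept, n)
    sigma2_s: np.ndarray       # (chains, kept)
    sigma2_u: np.ndarray       # (chains, kept)
    dic: float
    p_d: float
    gelman: dict[str, float]
    acceptance: dict[str, float]
    warnings: list[str]
    settings: ChainSettings
    spec: BYMSpec

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled over chains: alpha/sigma2_s/sigma2_u -> (K,),
        beta -> (K, p), s/u -> (K, n)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def linpred_draws(self) -> np.ndarray:
        """(K, n) pooled per-draw linear predictors alpha + X beta + s + u."""
        lp = (self.pooled("alpha")[:, None]
              + self.pooled("s") + self.pooled("u"))
        if self.beta.shape[-1]:
            lp = lp + self.pooled("beta") @ self._X.T
        return lp

    def summary(self) -> "pd.DataFrame":
        import pandas as pd
        rows = []
        def add(name, draws):
            lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
            rows.append({"parameter": name, "median": med, "lo95": lo, "hi95": hi})
        add("alpha", self.pooled("alpha"))
        add("exp(alpha)", np.exp(self.pooled("alpha")))
        for p, name in enumerate(self.coef_names):
            add(name, self.pooled("beta")[:, p])
            add(f"exp({name})", np.exp(self.pooled("beta")[:, p]))
        add("sigma2_s", self.pooled("sigma2_s"))
        add("sigma2_u", self.pooled("sigma2_u"))
        return pd.DataFrame(rows)

    def credible_interval(self, name: str) -> tuple[float, float]:
        """Pooled 95% credible interval for alpha, sigma2_s/u or a named
        coefficient."""
        if name in ("alpha", "sigma2_s", "sigma2_u"):
            draws = self.pooled(name)
        elif name in self.coef_names:
            draws = self.pooled("beta")[:, self.coef_names.index(name)]
        else:
            raise KeyError(name)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return float(lo), float(hi)


# -- the driver ------------------------------------------------------------

def run_chains(
    spec: BYMSpec,
    area_table,
    graph: AdjacencyGraph,
    settings: ChainSettings = TEST_PRESET,
    monitor_warn: float = 1.1,
    adapt_batch: int = 50,
) -> BYMPosterior:
    """Fit one BYM model: ``settings.chains`` independent chains with distinct
    sub-seeds, each keeping every ``thin``-th post-burn-in state.

    ``area_table`` must align with ``graph.area_ids`` and carry o, the offset
    column for ``spec.offset_kind`` and any area covariates the spec names.
    A Gelman-Rubin statistic above ``monitor_warn`` is recorded as a warning
    in the result, never raised.
    """
    if list(area_table["area_id"]) != list(graph.area_ids):
        raise ValueError("area_table rows must match graph.area_ids in order")
    offset_col = "e_unadj" if spec.offset_kind == "unadjusted" else "e_adj"
    X, coef_names = build_design(area_table, spec)
    data = BYMData(area_table["o"].to_numpy(), area_table[offset_col].to_numpy(),
                   X, coef_names, graph)

    burn = settings.burn
    n_iter = burn + settings.kept * settings.thin
    chains_out = {k: [] for k in ("alpha", "beta", "s", "u", "sigma2_s", "sigma2_u")}
    acc_totals = {"s": 0.0, "u": 0.0, "fixed": 0.0}
    acc_count = 0

    for sub in np.random.SeedSequence(settings.seed).spawn(settings.chains):
        rng = np.random.default_rng(sub)
        state = _init_state(data, rng)
        if spec.fixed_tau_s is not None:
            # start on the prior's scale so adaptation need not travel far
            state.tau_s = spec.fixed_tau_s
            state.s[:] = 0.0
            state.scale_s[:] = np.clip(
                2.4 / np.sqrt(spec.fixed_tau_s * max(data.k.mean(), 1.0)), 1e-7, 1.0)
        if spec.fixed_tau_u is not None:
            state.tau_u = spec.fixed_tau_u
            state.u[:] = 0.0
            state.scale_u[:] = np.clip(2.4 / np.sqrt(spec.fixed_tau_u), 1e-7, 1.0)
        keep = {k: [] for k in chains_out}
        acc_s = np.zeros(data.n)
        acc_u = np.zeros(data.n)
        acc_f = np.zeros(1 + data.p)
        batch = 0
        for it in range(n_iter):
            a_s = gibbs_step_s(state, data, rng)
            a_u = gibbs_step_u(state, data, rng)
            a_f = gibbs_step_fixed(state, data, spec, rng)
            gibbs_step_precisions(state, data, spec, rng)
            acc_s += a_s
            acc_u += a_u
            acc_f += a_f
            if it < burn:
                if (it + 1) % adapt_batch == 0:
                    batch += 1
                    d = min(0.25, batch**-0.5)
                    state.scale_s *= np.exp(np.where(acc_s / adapt_batch > 0.44, d, -d))
                    state.scale_u *= np.exp(np.where(acc_u / adapt_batch > 0.44, d, -d))
                    state.scale_alpha *= np.exp(d if acc_f[0] / adapt_batch > 0.44 else -d)
                    if data.p:
                        state.scale_beta *= np.exp(
                            np.where(acc_f[1:] / adapt_batch > 0.44, d, -d))
                    acc_s[:] = 0.0
                    acc_u[:] = 0.0
                    acc_f[:] = 0.0
                if it == burn - 1:
                    acc_s[:] = 0.0
                    acc_u[:] = 0.0
                    acc_f[:] = 0.0
            elif (it - burn + 1) % settings.thin == 0:
                keep["alpha"].append(state.alpha)
                keep["beta"].append(state.beta.copy())
                keep["s"].append(state.s.copy())
                keep["u"].append(state.u.copy())
                keep["sigma2_s"].append(1.0 / state.tau_s)
                keep["sigma2_u"].append(1.0 / state.tau_u)
        for k in chains_out:
            chains_out[k].append(np.array(keep[k]))
        post_iters = n_iter - burn
        acc_totals["s"] += float(acc_s.mean()) / post_iters
        acc_totals["u"] += float(acc_u.mean()) / post_iters
        acc_totals["fixed"] += float(acc_f.mean()) / post_iters
        acc_count += 1

    alpha = np.stack(chains_out["alpha"])
    beta = np.stack(chains_out["beta"])
    s = np.stack(chains_out["s"])
    u = np.stack(chains_out["u"])
    sigma2_s = np.stack(chains_out["sigma2_s"])
    sigma2_u = np.stack(chains_out["sigma2_u"])

    gelman: dict[str, float] = {}
    warnings_list: list[str] = []
    if settings.chains >= 2 and settings.kept >= 10:
        monitored = {"alpha": alpha, "sigma2_s": sigma2_s, "sigma2_u": sigma2_u}
        for p, name in enumerate(coef_names):
            monitored[name] = beta[:, :, p]
        for name, arr in monitored.items():
            r = gelman_rubin(arr)
            gelman[name] = r
            if r > monitor_warn:
                warnings_list.append(
                    f"Gelman-Rubin {r:.3f} > {monitor_warn} for {name}")
    for w in warnings_list:
        logger.warning(w)

    lp = (alpha.reshape(-1)[:, None] + s.reshape(-1, data.n) + u.reshape(-1, data.n))
    if data.p:
        lp = lp + beta.reshape(-1, data.p) @ data.X.T
    dic_val, p_d = dic(lp, data.o, data.e)

    post = BYMPosterior(
        area_ids=graph.area_ids, coef_names=coef_names,
        alpha=alpha, beta=beta, s=s, u=u,
        sigma2_s=sigma2_s, sigma2_u=sigma2_u,
        dic=dic_val, p_d=p_d, gelman=gelman,
        acceptance={k: v / max(acc_count, 1) for k, v in acc_totals.items()},
        warnings=warnings_list, settings=settings, spec=spec,
    )
    post._X = data.X  # for linpred_draws
    return post
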