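"""Convenience composition of the two-stage pipeline on synthetic scenarios."""

from __future__ import annotations

import pandas as pd

from .areal_graph import AdjacencyGraph
from .stage1 import analysis_subset, expected_counts, fit_logistic
from .synthetic_cohort import SimulationScenario, generate_cohort

__all__ = ["simulate_offsets"]


def simulate_offsets(
    scenario: SimulationScenario, outcome: str
) -> tuple[pd.DataFrame, AdjacencyGraph, pd.DataFrame]:
    """Generate a cohort and run stage 1 for one outcome.

    Returns (area table with both offset kinds and area covariates, filtered
    graph, truth table)."""
    cohort, truth = generate_cohort(scenario)
    subset, y = analysis_subset(cohort, outcome)
    null_fit = fit_logistic(subset, y, None, fitted_on=f"{outcome}:null")
    schema = {c: tuple(levels) for c, levels in scenario.covariate_freqs.items()}
    adj_fit = fit_logistic(subset, y, schema, fitted_on=f"{outcome}:adjusted")
    table, graph = expected_counts(
        null_fit, adj_fit, subset, y, scenario.graph,
        truth[["area_id", "walkability", "disadvantage"]])
    return table, graph, truth
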