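"""Calibration sweeps on synthetic experiments with known ground truth.

These drive both the test suite and the reproduction script: false-discovery
and power calibration of the interaction scoring, maturation-category
recovery, and the type-I error of the rank-based group comparison.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .maturation import binarize_profiles, categorize_maturation
from .pla import compare_groups
from .quant_io import filter_contaminants, median_center
from .scoring import ScoringParams, score_experiment
from .simulate import SimulationConfig, simulate_experiment


def default_calibration_config(seed: int = 0) -> SimulationConfig:
    """The study-scale calibration setting: 500 background preys and 80 true
    interactors (30 constant / 30 Ca2+-only / 20 hyper-only) at a mean log2
    enrichment of 3."""
    return SimulationConfig(seed=seed)


def score_simulated(config: SimulationConfig, params: ScoringParams | None = None):
    """Simulate one experiment and run preprocess + scoring; returns
    (scores, design, truth)."""
    matrix, design, truth = simulate_experiment(config)
    matrix = median_center(filter_contaminants(matrix))
    scores = score_experiment(matrix, design, params or ScoringParams())
    return scores, design, truth


def fdr_power_sweep(
    n_seeds: int = 20,
    base_config: SimulationConfig | None = None,
    params: ScoringParams | None = None,
    seed0: int = 0,
) -> dict:
    """Empirical false-discovery proportion and power of the BFDR <= 0.05 rule.

    A significant (bait, condition, prey) call is false unless the triple is
    truly enriched; power is the fraction of truly enriched triples called.
    Pooled over ``n_seeds`` independent experiments.
    """
    base_config = base_config or default_calibration_config()
    n_false = n_calls = n_recovered = n_true = 0
    for i in range(n_seeds):
        config = replace(base_config, seed=seed0 + i)
        scores, _, truth = score_simulated(config, params)
        true_pairs = truth.true_pairs()
        called = {
            (r.bait, r.condition, r.prey)
            for r in scores[scores["significant"]].itertuples(index=False)
        }
        n_calls += len(called)
        n_false += len(called - true_pairs)
        n_recovered += len(called & true_pairs)
        n_true += len(true_pairs)
    return {
        "fdp": n_false / n_calls if n_calls else 0.0,
        "power": n_recovered / n_true if n_true else float("nan"),
        "n_calls": n_calls,
        "n_true": n_true,
        "n_seeds": n_seeds,
    }


def maturation_recovery(
    config: SimulationConfig | None = None,
    params: ScoringParams | None = None,
    threshold: float = 0.05,
) -> dict:
    """Fraction of truly interacting preys assigned their true maturation
    category after scoring + profiling (unprofiled true preys count as
    misses)."""
    config = config or default_calibration_config()
    scores, design, truth = score_simulated(config, params)
    profiles = binarize_profiles(scores, threshold, design.baits, design.conditions)
    calls = categorize_maturation(profiles).set_index("prey")["category"]
    true_rows = truth.data[
        truth.data["category"].isin(["constant", "calcium_dependent", "hyper_adhesive"])
    ]
    n_correct = sum(
        calls.get(row.prey) == row.category for row in true_rows.itertuples(index=False)
    )
    n_true = len(true_rows)
    return {
        "recovery": n_correct / n_true if n_true else float("nan"),
        "n_correct": n_correct,
        "n_true": n_true,
    }


def kruskal_type1_rate(
    n_sims: int = 1000, n_per_group: int = 50, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Rejection rate of the omnibus rank test when both groups share one
    distribution — should sit near alpha."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        result = compare_groups({"a": a, "b": b})
        if result["kruskal_p"] < alpha:
            rejections += 1
    return {"rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}
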