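"""Repeatable simulation experiments: pattern recovery and type-I control.

The pattern-recovery experiment repeats the attention-gated scenario at its
default size (27 subjects, 38 trials per cell) but restricts computation to
the occipital channels and the theta-band decomposition the tested measure
needs.  The type-I experiment simulates measure-level null datasets at 12
subjects and 20 trials per cell; pushing thousands of null datasets through
the full signal chain would add nothing to what it tests (the gated
statistical procedure).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import paper_like_design
from .simulate import generate_dataset, generate_null_measure_table
from .stats import GatedReport, run_gated_analysis
from .timefreq import TFMeasure, build_tf_measure_table

OCCIPITAL = ("O1", "OZ", "O2")

THETA_ITC_MEASURE = TFMeasure("visual_theta_itc_200_300", "itc", "theta",
                              (0.200, 0.300), OCCIPITAL)


@dataclass
class RecoveryOutcome:
    report: GatedReport

    @property
    def interaction_significant(self) -> bool:
        return self.report.interaction.p < self.report.alpha

    @property
    def attended_only_pattern(self) -> bool:
        """Interaction + TP simple effect in attended but not unattended."""
        if not (self.interaction_significant
                and self.report.branch == "simple_effects"):
            return False
        simple = self.report.simple_effects
        return (simple["attended"].effects["tp"].p < self.report.alpha
                and simple["unattended"].effects["tp"].p
                >= self.report.alpha)


def theta_itc_gated_run(seed: int, n_subjects: int = 27,
                        n_trials_per_cell: int = 38,
                        alpha: float = 0.05) -> RecoveryOutcome:
    """One scaled run of the attention-gated scenario on theta ITC.

    Generates the visual scenario, extracts the 200-300 ms theta band-window
    ITC per subject and cell, and applies the gated testing scheme.
    """
    spec = paper_like_design("visual", n_subjects=n_subjects,
                             n_trials_per_cell=n_trials_per_cell,
                             channels=OCCIPITAL)
    epochs = generate_dataset(spec, seed=seed)
    table = build_tf_measure_table(epochs, [THETA_ITC_MEASURE])
    return RecoveryOutcome(run_gated_analysis(table, alpha=alpha))


def pattern_recovery_rate(n_runs: int = 100, seed: int = 0,
                          n_subjects: int = 27, n_trials_per_cell: int = 38
                          ) -> float:
    """Fraction of seeded runs recovering the attended-only TP pattern."""
    hits = 0
    for k in range(n_runs):
        outcome = theta_itc_gated_run(seed * 100_003 + k, n_subjects,
                                      n_trials_per_cell)
        if outcome.attended_only_pattern:
            hits += 1
    return hits / n_runs


def null_pairwise_rate(n_sim: int = 2000, seed: int = 0,
                       n_subjects: int = 12, n_trials_per_cell: int = 20,
                       alpha: float = 0.05) -> float:
    """Type-I rate of the gated procedure's final pairwise claims.

    Under the global null (no programmed effects anywhere), the fraction of
    simulated datasets in which the procedure ends up declaring at least one
    Bonferroni-adjusted pairwise contrast significant.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        table = generate_null_measure_table(n_subjects, n_trials_per_cell,
                                            rng)
        report = run_gated_analysis(table, alpha=alpha)
        if report.significant_pairwise():
            hits += 1
    return hits / n_sim
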