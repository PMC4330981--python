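"""Synthetic fixtures: trial summaries with known truth, fuzzed parameter sets.

The trial generator emulates the evidence base behind the indirect
comparison: a handful of randomized trials per treatment class, each
comparing an active arm against symptomatic/placebo control on the RTSS
scale, with a known true standardized mean difference. Individual patient
scores are simulated as normal (the SMD framework's working model; no
truncation at zero, a deliberate simplification) and summarised to empirical
means/SDs, so sampling noise propagates into the per-trial summaries exactly
as it would in real trial reports.

The config fuzzer produces random valid model configurations for property
tests of the cohort engine (conservation, monotonicity) across the parameter
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    ALLERGOID,
    FIVE_GRASS,
    SYMPTOMATIC,
    ClinicalParams,
    ModelConfig,
    default_config,
)
from .itc import TrialSummary

__all__ = ["TrialGeneratorSpec", "generate_trials", "generate_parameter_sets"]


@dataclass(frozen=True)
class TrialGeneratorSpec:
    """Ground truth and design of a synthetic meta-analytic evidence base.

    Defaults mirror the published evidence structure: 4 tablet trials and 5
    allergoid trials, each anchored on symptomatic control (mean 4.47 RTSS),
    with true SMDs matching the published pooled symptom scores at a working
    SD of 2 points.
    """

    true_smd: dict[str, float] = field(
        default_factory=lambda: {FIVE_GRASS: -0.605, ALLERGOID: -0.415}
    )
    control_mean: float = 4.47
    control_sd: float = 2.0
    n_per_arm: int = 100
    n_trials: dict[str, int] = field(
        default_factory=lambda: {FIVE_GRASS: 4, ALLERGOID: 5}
    )
    seed: int = 42

    def __post_init__(self) -> None:
        if self.control_sd <= 0:
            raise ValueError("control_sd must be positive")
        if self.n_per_arm < 10:
            raise ValueError("n_per_arm must be >= 10")


def generate_trials(
    spec: TrialGeneratorSpec, rng: np.random.Generator | None = None
) -> list[TrialSummary]:
    """Simulate per-trial summary statistics with expected SMD equal to truth."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    trials = []
    for klass, k in spec.n_trials.items():
        active_mean = spec.control_mean + spec.true_smd[klass] * spec.control_sd
        for i in range(k):
            active = rng.normal(active_mean, spec.control_sd, size=spec.n_per_arm)
            control = rng.normal(spec.control_mean, spec.control_sd, size=spec.n_per_arm)
            trials.append(
                TrialSummary(
                    trial_id=f"{klass}_trial_{i + 1}",
                    treatment_class=klass,
                    mean_active=float(active.mean()),
                    sd_active=float(active.std(ddof=1)),
                    n_active=spec.n_per_arm,
                    mean_control=float(control.mean()),
                    sd_control=float(control.std(ddof=1)),
                    n_control=spec.n_per_arm,
                )
            )
    return trials


def generate_parameter_sets(
    config: ModelConfig | None = None, n: int = 200, seed: int = 7
) -> list[ModelConfig]:
    """Random valid configs for fuzzing engine invariants.

    Probabilities are drawn across their full supports (discontinuation up to
    0.95, relative risk up to 2 so both effect directions are exercised);
    costs and the season length are scaled around the base case.
    """
    base = default_config() if config is None else config
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        cfg = base.copy_deep()
        for arm_key in (FIVE_GRASS, ALLERGOID):
            cfg.arms[arm_key].disc_y1 = float(rng.uniform(0, 0.95))
            cfg.arms[arm_key].disc_y2 = float(rng.uniform(0, 0.95))
            cfg.arms[arm_key].rtss = float(rng.uniform(0, cfg.arms[SYMPTOMATIC].rtss))
        p_death = float(rng.uniform(0, 0.01))
        cfg.clinical = ClinicalParams(
            p_asthma_symptomatic=float(rng.uniform(0, 0.05)),
            rr_asthma_ait=float(rng.uniform(0, 2.0)),
            p_death_all=p_death,
            p_death_asthma=float(p_death * rng.uniform(1.0, 3.0)),
            mean_age_entry=cfg.clinical.mean_age_entry,
        )
        cfg.utility.season_months = float(rng.uniform(0.5, 12.0))
        scale = float(rng.uniform(0.5, 2.0))
        cfg.costs.c_specialist_visit = base.costs.c_specialist_visit * scale
        cfg.costs.c_injection = base.costs.c_injection * scale
        cfg.costs.c_asthma_annual = base.costs.c_asthma_annual * scale
        out.append(cfg)
    return out
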