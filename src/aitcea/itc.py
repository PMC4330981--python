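"""Anchored indirect treatment comparison on standardized mean differences.

Each randomized trial contributes a standardized mean difference (SMD) of the
active arm vs its own symptomatic/placebo control (negative = symptom
improvement). Per treatment class, SMDs are pooled with a fixed-effect
inverse-variance model; the two classes are then contrasted indirectly through
the common comparator (Bucher anchor: difference of pooled SMDs, variances
add). A pooled SMD can be mapped back to the RTSS scale against a reference
control mean and standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "TrialSummary",
    "ITCEstimate",
    "smd",
    "pool_fixed_effect",
    "indirect_contrast",
    "to_rtss_scale",
    "read_trials_csv",
    "forest_table",
]

Z975 = 1.959963984540054


@dataclass(frozen=True)
class TrialSummary:
    """Two-arm summary statistics of one randomized trial."""

    trial_id: str
    treatment_class: str  # e.g. "five_grass", "allergoid"
    mean_active: float
    sd_active: float
    n_active: int
    mean_control: float
    sd_control: float
    n_control: int

    def __post_init__(self) -> None:
        if self.n_active < 2 or self.n_control < 2:
            raise ValueError("each arm needs at least 2 patients")
        if self.sd_active <= 0 or self.sd_control <= 0:
            raise ValueError("arm standard deviations must be positive")


@dataclass(frozen=True)
class ITCEstimate:
    """A pooled SMD with its standard error, anchored on a common comparator."""

    smd: float
    se: float
    contrast: str  # e.g. "five_grass vs control"
    n_studies: int = 1

    @property
    def variance(self) -> float:
        return self.se**2

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.smd - Z975 * self.se, self.smd + Z975 * self.se)


def smd(trial: TrialSummary, hedges: bool = False) -> tuple[float, float]:
    """Cohen's d (optionally Hedges-corrected) and its variance for one trial.

    ``d = (mean_active - mean_control) / pooled SD``;
    ``var = (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))``.
    """
    n1, n2 = trial.n_active, trial.n_control
    pooled_var = ((n1 - 1) * trial.sd_active**2 + (n2 - 1) * trial.sd_control**2) / (
        n1 + n2 - 2
    )
    if pooled_var <= 0:
        raise ValueError("zero pooled standard deviation")
    d = (trial.mean_active - trial.mean_control) / math.sqrt(pooled_var)
    if hedges:
        j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
        d *= j
    var = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
    return d, var


def pool_fixed_effect(
    estimates: list[tuple[float, float]], contrast: str = "pooled"
) -> ITCEstimate:
    """Fixed-effect inverse-variance pooling of per-trial (smd, variance) pairs."""
    if not estimates:
        raise ValueError("cannot pool an empty list of estimates")
    weights = [1.0 / v for _, v in estimates]
    wsum = sum(weights)
    pooled = sum(w * g for (g, _), w in zip(estimates, weights)) / wsum
    return ITCEstimate(
        smd=pooled, se=wsum**-0.5, contrast=contrast, n_studies=len(estimates)
    )


def pool_trials(
    trials: list[TrialSummary], treatment_class: str, hedges: bool = False
) -> ITCEstimate:
    """Pool all trials of one treatment class against their controls."""
    subset = [t for t in trials if t.treatment_class == treatment_class]
    if not subset:
        raise ValueError(f"no trials of class {treatment_class!r}")
    return pool_fixed_effect(
        [smd(t, hedges=hedges) for t in subset], contrast=f"{treatment_class} vs control"
    )


def indirect_contrast(a_vs_control: ITCEstimate, b_vs_control: ITCEstimate) -> ITCEstimate:
    """Anchored (Bucher) contrast of two treatments through a common comparator."""
    anchor_a = a_vs_control.contrast.split(" vs ")[-1]
    anchor_b = b_vs_control.contrast.split(" vs ")[-1]
    if anchor_a != anchor_b:
        raise ValueError(
            f"mismatched anchors: {a_vs_control.contrast!r} vs {b_vs_control.contrast!r}"
        )
    name_a = a_vs_control.contrast.split(" vs ")[0]
    name_b = b_vs_control.contrast.split(" vs ")[0]
    return ITCEstimate(
        smd=a_vs_control.smd - b_vs_control.smd,
        se=math.sqrt(a_vs_control.variance + b_vs_control.variance),
        contrast=f"{name_a} vs {name_b}",
        n_studies=a_vs_control.n_studies + b_vs_control.n_studies,
    )


def to_rtss_scale(pooled: ITCEstimate, reference_sd: float, control_mean: float) -> float:
    """Back-transform a pooled SMD to the RTSS scale: ``control + smd * sd``."""
    if reference_sd <= 0:
        raise ValueError("reference_sd must be positive")
    return control_mean + pooled.smd * reference_sd


def read_trials_csv(path: str | Path) -> list[TrialSummary]:
    """Read trial summaries from a CSV with one row per trial.

    Expected columns: trial_id, treatment_class, mean_active, sd_active,
    n_active, mean_control, sd_control, n_control.
    """
    df = pd.read_csv(path)
    return [
        TrialSummary(
            trial_id=str(r.trial_id),
            treatment_class=str(r.treatment_class),
            mean_active=float(r.mean_active),
            sd_active=float(r.sd_active),
            n_active=int(r.n_active),
            mean_control=float(r.mean_control),
            sd_control=float(r.sd_control),
            n_control=int(r.n_control),
        )
        for r in df.itertuples()
    ]


def forest_table(trials: list[TrialSummary], pooled: ITCEstimate) -> str:
    """Plain-text forest table: one line per trial plus the pooled row."""
    lines = [f"{'trial':<20}{'smd':>9}{'se':>9}{'95% CI':>22}"]
    for t in trials:
        g, v = smd(t)
        se = math.sqrt(v)
        lines.append(
            f"{t.trial_id:<20}{g:>9.3f}{se:>9.3f}"
            f"   [{g - Z975 * se:>7.3f}, {g + Z975 * se:>7.3f}]"
        )
    lo, hi = pooled.ci95
    lines.append(
        f"{'pooled (' + pooled.contrast + ')':<20}{pooled.smd:>9.3f}{pooled.se:>9.3f}"
        f"   [{lo:>7.3f}, {hi:>7.3f}]"
    )
    return "\n".join(lines)
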