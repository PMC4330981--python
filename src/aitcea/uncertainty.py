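"""Sensitivity analysis: parameter distributions, PSA, CEAC, and tornado DSA.

Distribution families follow health-economic convention: beta for
probabilities and utilities, gamma for unit costs and the pollen-season
length, normal for the relative risk and the treatment-efficacy contrasts
(differences in symptom score vs symptomatic care, the SMD-anchored
quantities). Where a source reports no variance the standard error defaults
to 20% of the mean. Beta and gamma shapes come from method of moments.

Efficacy dispersion: the per-class SEs of the RTSS differences are
``efficacy_se_scale * 0.20 * mean difference``; the single scale factor is
calibrated (see :func:`calibrate_efficacy_dispersion`) so that the PSA's
draw-wise 95% interval of incremental QALYs (tablet vs allergoid) matches the
published interval — the per-class SMD variances themselves are not
published.

Parameters are drawn independently; normal draws for parameters with bounded
support are clipped to the support (with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ALLERGOID, FIVE_GRASS, SYMPTOMATIC, ModelConfig
from .economics import run_arm

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "CEACCurve",
    "DSAEntry",
    "build_distributions",
    "sample_psa",
    "run_psa",
    "ceac",
    "univariate_dsa",
    "psa_summary",
    "calibrate_efficacy_dispersion",
]

Z975 = 1.959963984540054
_SE_FRACTION = 0.20  # default SE where no variance is published

# Paths of the form "efficacy.<arm>" denote the RTSS difference
# (symptomatic minus arm) rather than a literal config field.
EFFICACY_PREFIX = "efficacy."


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter: dotted config path, family, and moments."""

    path: str
    family: str  # "beta" | "normal" | "gamma"
    mean: float
    se: float
    support: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.family not in ("beta", "normal", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.se < 0:
            raise ValueError(f"{self.path}: se must be >= 0")
        if self.family == "beta":
            if not (0 <= self.mean <= 1):
                raise ValueError(f"{self.path}: beta mean must lie in [0, 1]")
            if self.se > 0 and self.se**2 >= self.mean * (1 - self.mean):
                raise ValueError(
                    f"{self.path}: se {self.se} too large for a beta with mean {self.mean} "
                    "(method of moments infeasible)"
                )
        if self.family == "gamma" and self.mean < 0:
            raise ValueError(f"{self.path}: gamma mean must be non-negative")

    def shape_params(self) -> tuple[float, float]:
        """Method-of-moments parameters: (alpha, beta) or (shape, scale)."""
        m, s2 = self.mean, self.se**2
        if self.family == "beta":
            nu = m * (1 - m) / s2 - 1.0
            return m * nu, (1 - m) * nu
        if self.family == "gamma":
            return (m / self.se) ** 2, s2 / m
        return m, self.se

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.se == 0:
            return np.full(n, self.mean)
        if self.family == "beta":
            a, b = self.shape_params()
            return rng.beta(a, b, size=n)
        if self.family == "gamma":
            shape, scale = self.shape_params()
            return rng.gamma(shape, scale, size=n)
        x = rng.normal(self.mean, self.se, size=n)
        lo, hi = self.support
        if np.any((x < lo) | (x > hi)):
            warnings.warn(f"{self.path}: normal draws clipped to support [{lo}, {hi}]")
            x = np.clip(x, lo, hi)
        return x


def build_distributions(config: ModelConfig) -> list[ParameterDistribution]:
    """Assign every uncertain parameter its distribution family and moments.

    Drug acquisition prices (administered list prices) and the calibrated
    quantities (utility slope, resource counts) are held fixed. The baseline
    utility cancels in every incremental outcome and is excluded: the 20%-SE
    rule is method-of-moments infeasible for a beta that close to 1.
    """
    arms = config.arms
    sympt_rtss = arms[SYMPTOMATIC].rtss
    eff_scale = config.settings.efficacy_se_scale

    def d(path: str, family: str, mean: float, se: float | None = None, support=(-np.inf, np.inf)):
        return ParameterDistribution(
            path=path,
            family=family,
            mean=mean,
            se=_SE_FRACTION * mean if se is None else se,
            support=support,
        )

    dists = [
        d(f"arms.{FIVE_GRASS}.disc_y1", "beta", arms[FIVE_GRASS].disc_y1),
        d(f"arms.{FIVE_GRASS}.disc_y2", "beta", arms[FIVE_GRASS].disc_y2),
        d(f"arms.{ALLERGOID}.disc_y1", "beta", arms[ALLERGOID].disc_y1),
        d(f"arms.{ALLERGOID}.disc_y2", "beta", arms[ALLERGOID].disc_y2),
        d("clinical.p_asthma_symptomatic", "beta", config.clinical.p_asthma_symptomatic),
        d("clinical.p_death_all", "beta", config.clinical.p_death_all),
        d("clinical.p_death_asthma", "beta", config.clinical.p_death_asthma),
        d("clinical.rr_asthma_ait", "normal", config.clinical.rr_asthma_ait, support=(0.0, np.inf)),
        d("utility.season_months", "gamma", config.utility.season_months),
        d("costs.c_specialist_visit", "gamma", config.costs.c_specialist_visit),
        d("costs.c_injection", "gamma", config.costs.c_injection),
        d("costs.c_diagnostics", "gamma", config.costs.c_diagnostics),
        d("costs.c_asthma_annual", "gamma", config.costs.c_asthma_annual),
        d("costs.c_loratadine_ait", "gamma", config.costs.c_loratadine_ait),
        d("costs.c_budesonide_ait", "gamma", config.costs.c_budesonide_ait),
        d("costs.c_loratadine_sympt", "gamma", config.costs.c_loratadine_sympt),
        d("costs.c_budesonide_sympt", "gamma", config.costs.c_budesonide_sympt),
    ]
    for arm_key in (FIVE_GRASS, ALLERGOID):
        delta = sympt_rtss - arms[arm_key].rtss
        dists.append(
            d(
                EFFICACY_PREFIX + arm_key,
                "normal",
                delta,
                se=eff_scale * _SE_FRACTION * delta,
            )
        )
    return dists


def sample_psa(
    distributions: Sequence[ParameterDistribution], n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` independent joint parameter vectors, one column per path."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({dist.path: dist.sample(rng, n) for dist in distributions})


def _set_path(data: dict, path: str, value: float) -> None:
    if path.startswith(EFFICACY_PREFIX):
        arm_key = path[len(EFFICACY_PREFIX):]
        sympt_rtss = data["arms"][SYMPTOMATIC]["rtss"]
        data["arms"][arm_key]["rtss"] = max(sympt_rtss - value, 0.0)
        return
    parts = path.split(".")
    node = data
    for part in parts[:-1]:
        node = node[part]
    node[parts[-1]] = value


def apply_draw(
    config: ModelConfig,
    row: pd.Series | dict,
    fix_administration_months: bool = False,
) -> ModelConfig:
    """Return a config copy with one joint parameter draw applied.

    Independent mortality draws can cross the asthma-excess ordering; the
    asthma mortality is then raised to the all-cause draw (clip policy, as for
    truncated normals).

    With ``fix_administration_months``, arms priced per treated month keep
    their base-case total of administered months when the season draw moves:
    the acquisition price behaves as a fixed administered annual price in the
    probabilistic analysis, while the season draw still varies the symptom
    burden. This convention reproduces the published probabilistic
    incremental-cost interval; the one-way DSA keeps the full season-cost
    linkage.
    """
    data = config.model_dump(mode="python")
    items = row.items() if hasattr(row, "items") else row
    for path, value in items:
        _set_path(data, path, float(value))
    clinical = data["clinical"]
    if clinical["p_death_asthma"] < clinical["p_death_all"]:
        clinical["p_death_asthma"] = clinical["p_death_all"]
    if fix_administration_months:
        for arm_key, arm in data["arms"].items():
            if arm.get("fixed_annual_drug_cost") is None and arm["drug_cost_per_month"] > 0:
                base_total = (
                    config.arms[arm_key].preseasonal_months + config.utility.season_months
                )
                arm["preseasonal_months"] = max(
                    base_total - data["utility"]["season_months"], 0.0
                )
    return ModelConfig.model_validate(data)


@dataclass
class PSAResult:
    """Per-draw discounted costs and QALYs for each arm."""

    costs: pd.DataFrame  # (n_draws, arms)
    qalys: pd.DataFrame
    draws: pd.DataFrame
    seed: int
    n_failures: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.costs)

    def incremental(self, reference: str, comparator: str) -> pd.DataFrame:
        """Draw-wise (delta_cost, delta_qaly), reference minus comparator."""
        return pd.DataFrame(
            {
                "delta_cost": self.costs[reference] - self.costs[comparator],
                "delta_qaly": self.qalys[reference] - self.qalys[comparator],
            }
        )


def run_psa(
    config: ModelConfig,
    draws: pd.DataFrame,
    arms: Iterable[str] = (FIVE_GRASS, ALLERGOID, SYMPTOMATIC),
    seed: int = 0,
) -> PSAResult:
    """Evaluate the full model at every parameter draw.

    Draws that violate config invariants are logged and carried as NaN rows
    rather than silently dropped.
    """
    arms = list(arms)
    n = len(draws)
    costs = {a: np.empty(n) for a in arms}
    qalys = {a: np.empty(n) for a in arms}
    failures = 0
    fix_months = config.settings.psa_fixed_administration_months
    for i in range(n):
        try:
            cfg = apply_draw(config, draws.iloc[i], fix_administration_months=fix_months)
            for a in arms:
                res = run_arm(cfg, a)
                costs[a][i] = res.costs.total_discounted
                qalys[a][i] = res.qalys_discounted
        except Exception as exc:  # noqa: BLE001 - count, report, continue
            failures += 1
            warnings.warn(f"PSA draw {i} failed: {exc}")
            for a in arms:
                costs[a][i] = np.nan
                qalys[a][i] = np.nan
    return PSAResult(
        costs=pd.DataFrame(costs),
        qalys=pd.DataFrame(qalys),
        draws=draws,
        seed=seed,
        n_failures=failures,
    )


@dataclass
class CEACCurve:
    """Probability of each arm having maximal net monetary benefit, per WTP."""

    wtp: np.ndarray
    probabilities: pd.DataFrame  # (len(wtp), arms)

    def at(self, wtp_value: float, arm: str) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp_value)))
        return float(self.probabilities[arm].iloc[idx])

    def to_frame(self) -> pd.DataFrame:
        df = self.probabilities.copy()
        df.insert(0, "wtp", self.wtp)
        return df


def ceac(
    psa: PSAResult, wtp_grid: Sequence[float], arms: Iterable[str] | None = None
) -> CEACCurve:
    """Cost-effectiveness acceptability curves over a WTP grid.

    At each threshold, an arm's probability is the fraction of draws in which
    it attains the maximal net monetary benefit among ``arms`` (ties split
    towards the first listed arm; they have probability zero under continuous
    draws).
    """
    arms = list(arms) if arms is not None else list(psa.costs.columns)
    q = psa.qalys[arms].to_numpy()
    c = psa.costs[arms].to_numpy()
    valid = ~np.isnan(q).any(axis=1)
    wtp = np.asarray(list(wtp_grid), dtype=float)
    probs = np.zeros((len(wtp), len(arms)))
    for j, lam in enumerate(wtp):
        nmb = lam * q[valid] - c[valid]
        best = np.argmax(nmb, axis=1)
        for k in range(len(arms)):
            probs[j, k] = np.mean(best == k)
    return CEACCurve(wtp=wtp, probabilities=pd.DataFrame(probs, columns=arms))


def psa_summary(
    psa: PSAResult, reference: str = FIVE_GRASS, comparator: str = ALLERGOID
) -> dict:
    """Percentile intervals of the incremental cloud and the NE-quadrant share."""
    inc = psa.incremental(reference, comparator).dropna()
    dc, dq = inc["delta_cost"], inc["delta_qaly"]
    return {
        "reference": reference,
        "comparator": comparator,
        "n_draws": int(len(inc)),
        "delta_cost_mean": float(dc.mean()),
        "delta_cost_ci95": [float(dc.quantile(0.025)), float(dc.quantile(0.975))],
        "delta_qaly_mean": float(dq.mean()),
        "delta_qaly_ci95": [float(dq.quantile(0.025)), float(dq.quantile(0.975))],
        "p_ne_quadrant": float(np.mean((dq > 0) & (dc > 0))),
    }


@dataclass
class DSAEntry:
    """One tornado bar: outputs with a parameter at its 95% CI bounds."""

    parameter: str
    low_input: float
    high_input: float
    dqaly_low: float
    dqaly_high: float
    dcost_low: float
    dcost_high: float

    @property
    def qaly_range(self) -> float:
        return abs(self.dqaly_high - self.dqaly_low)

    @property
    def cost_range(self) -> float:
        return abs(self.dcost_high - self.dcost_low)


def _incremental_outcomes(
    config: ModelConfig, reference: str, comparator: str
) -> tuple[float, float]:
    ra, rb = run_arm(config, reference), run_arm(config, comparator)
    return (
        ra.qalys_discounted - rb.qalys_discounted,
        ra.costs.total_discounted - rb.costs.total_discounted,
    )


def univariate_dsa(
    config: ModelConfig,
    distributions: Sequence[ParameterDistribution] | None = None,
    reference: str = FIVE_GRASS,
    comparator: str = ALLERGOID,
    sort_by: str = "qaly",
) -> list[DSAEntry]:
    """One-way DSA: each parameter at mean +/- 1.96 SE (clipped to support).

    Returns entries sorted by the chosen output range, descending (tornado
    order).
    """
    if distributions is None:
        distributions = build_distributions(config)
    entries = []
    for dist in distributions:
        lo_s, hi_s = dist.support
        if dist.family == "beta":
            lo_s, hi_s = 0.0, 1.0
        elif dist.family == "gamma":
            lo_s, hi_s = 0.0, np.inf
        low = float(np.clip(dist.mean - Z975 * dist.se, lo_s, hi_s))
        high = float(np.clip(dist.mean + Z975 * dist.se, lo_s, hi_s))
        dq_lo, dc_lo = _incremental_outcomes(
            apply_draw(config, {dist.path: low}.items()), reference, comparator
        )
        dq_hi, dc_hi = _incremental_outcomes(
            apply_draw(config, {dist.path: high}.items()), reference, comparator
        )
        entries.append(
            DSAEntry(
                parameter=dist.path,
                low_input=low,
                high_input=high,
                dqaly_low=dq_lo,
                dqaly_high=dq_hi,
                dcost_low=dc_lo,
                dcost_high=dc_hi,
            )
        )
    key = (lambda e: e.qaly_range) if sort_by == "qaly" else (lambda e: e.cost_range)
    return sorted(entries, key=key, reverse=True)


def dsa_to_frame(entries: list[DSAEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "dqaly_low": e.dqaly_low,
                "dqaly_high": e.dqaly_high,
                "dcost_low": e.dcost_low,
                "dcost_high": e.dcost_high,
                "qaly_range": e.qaly_range,
                "cost_range": e.cost_range,
            }
            for e in entries
        ]
    )


def calibrate_efficacy_dispersion(
    config: ModelConfig,
    target_interval: tuple[float, float] = (0.002, 0.078),
    n: int | None = None,
    seed: int = 73,
) -> float:
    """Solve the efficacy SE scale so the PSA interval matches the target.

    The draw-wise incremental-QALY variance decomposes as a fixed part (all
    other parameters) plus a part proportional to the squared efficacy scale;
    the 95% percentile width follows the same law closely, so two PSA runs
    under common random numbers identify the scale, with one refinement pass.
    """
    target_width = target_interval[1] - target_interval[0]
    n = n or config.settings.n_psa
    base = config.copy_deep()
    base.settings.efficacy_se_scale = 1.0
    dists = build_distributions(base)
    draws = sample_psa(dists, n, seed)
    eff_cols = [d.path for d in dists if d.path.startswith(EFFICACY_PREFIX)]
    eff_means = {d.path: d.mean for d in dists if d.path.startswith(EFFICACY_PREFIX)}

    def width(scale: float) -> float:
        scaled = draws.copy()
        for col in eff_cols:
            scaled[col] = eff_means[col] + scale * (draws[col] - eff_means[col])
        psa = run_psa(base, scaled, arms=(FIVE_GRASS, ALLERGOID), seed=seed)
        inc = psa.incremental(FIVE_GRASS, ALLERGOID)["delta_qaly"].dropna()
        return float(inc.quantile(0.975) - inc.quantile(0.025))

    w0, w1 = width(0.0), width(1.0)
    if target_width <= w0:
        return 0.0
    scale = float(np.sqrt((target_width**2 - w0**2) / (w1**2 - w0**2)))
    # one refinement pass on the quadratic law around the first estimate
    w_s = width(scale)
    b = (w_s**2 - w0**2) / scale**2
    scale = float(np.sqrt(max(target_width**2 - w0**2, 0.0) / b))
    return scale
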