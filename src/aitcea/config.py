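"""Model parameters: typed configuration, validation, and structured-text I/O.

Every base-case number used by the cost-utility model lives here as a typed,
validated default: transition probabilities (treatment discontinuation, asthma
onset, mortality), symptom scores on the rhinoconjunctivitis total symptom
score (RTSS, 0-18) scale, German payer unit costs in 2013 EUR, utility
parameters, and the economic settings (9-year horizon, annual cycles, 3%
discounting).

Calibrated quantities (the RTSS-to-utility slope, per-arm visit and injection
counts, the societal productivity saving, the baseline utility, and the PSA
efficacy-dispersion scale) are not published inputs; their defaults are the
values recovered by :mod:`aitcea.calibration` from the published cost and QALY
components, and can be re-derived at any time with the ``calibrate`` command.

Config files are YAML (JSON, being a YAML subset, also parses). Unknown keys
are rejected. A JSON Schema for the format is bundled as
``aitcea/data/schema.json``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "ArmSpec",
    "ClinicalParams",
    "UtilityParams",
    "CostParams",
    "EconSettings",
    "ModelConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "default_config",
    "annual_drug_cost",
    "write_schema",
]

FIVE_GRASS = "five_grass"
ALLERGOID = "allergoid"
SYMPTOMATIC = "symptomatic"
ARM_KEYS = (FIVE_GRASS, ALLERGOID, SYMPTOMATIC)


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed or fails validation."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ArmSpec(_Base):
    """Clinical and cost profile of one comparator arm.

    Drug acquisition cost comes in two flavours: the sublingual tablet is
    priced per treated month (pre-seasonal months plus the pollen season), so
    its annual cost moves with the season length; the subcutaneous allergoid
    mix is priced per annual pack (``fixed_annual_drug_cost``), independent of
    the season. Symptomatic treatment carries no acquisition cost.
    """

    name: str
    rtss: float = Field(ge=0, le=18, description="On-treatment symptom score (RTSS points)")
    disc_y1: float = Field(0.0, ge=0, le=1, description="Discontinuation probability in year 1")
    disc_y2: float = Field(0.0, ge=0, le=1, description="Discontinuation probability in year 2")
    drug_cost_per_month: float = Field(0.0, ge=0, description="EUR per month administered")
    preseasonal_months: float = Field(0.0, ge=0, le=12, description="Pre-seasonal administration months/year")
    fixed_annual_drug_cost: Optional[float] = Field(
        None, ge=0, description="Season-independent EUR/year (per-pack pricing); overrides per-month pricing"
    )
    visits_per_treatment_year: float = Field(0.0, ge=0)
    injections_per_treatment_year: float = Field(0.0, ge=0)
    supervised_first_dose: bool = False
    diagnostic_in_year1: bool = False

    def months_administered_per_year(self, season_months: float) -> float:
        return self.preseasonal_months + season_months


class ClinicalParams(_Base):
    """Natural-history probabilities shared by all arms (annual, cohort age 29)."""

    p_asthma_symptomatic: float = Field(0.0046, ge=0, le=1)
    rr_asthma_ait: float = Field(0.505, ge=0)
    p_death_all: float = Field(0.00046, ge=0, le=1)
    p_death_asthma: float = Field(0.00069, ge=0, le=1)
    mean_age_entry: float = Field(29.0, ge=0)

    @model_validator(mode="after")
    def _asthma_mortality_dominates(self) -> "ClinicalParams":
        if self.p_death_asthma < self.p_death_all:
            raise ValueError(
                f"p_death_asthma ({self.p_death_asthma}) must be >= p_death_all ({self.p_death_all})"
            )
        return self


class UtilityParams(_Base):
    """Utility model: a linear RSUI-style proxy mapping RTSS to a seasonal decrement.

    Annual utility of an alive state is
    ``u_baseline - (season_months/12) * k_rtss_slope * RTSS - asthma_decrement``.
    ``utility_mode='eq5d'`` replaces the seasonal map by year-round EQ-5D
    utilities (on-effect vs off-effect), used by scenario 4.
    """

    u_baseline: float = Field(0.969974, ge=0, le=1, description="Calibrated annual baseline utility")
    k_rtss_slope: float = Field(0.059080, ge=0, description="Calibrated utility decrement per RTSS point in season")
    season_months: float = Field(3.0, gt=0, le=12)
    asthma_decrement: float = Field(0.0, ge=0, description="Annual utility decrement of chronic asthma")
    eq5d_ait: float = Field(0.976, ge=0, le=1)
    eq5d_symptomatic: float = Field(0.947, ge=0, le=1)
    utility_mode: Literal["rsui", "eq5d"] = "rsui"


class CostParams(_Base):
    """Unit costs (EUR, 2013) and resource-use rates from the payer perspective."""

    c_specialist_visit: float = Field(13.29, ge=0)
    c_visit_additional: float = Field(3.69, ge=0, description="Optional surcharge for visits > 10 min; unused in base case")
    c_injection: float = Field(5.11, ge=0)
    c_diagnostics: float = Field(20.61, ge=0)
    c_asthma_annual: float = Field(186.30, ge=0)
    c_loratadine_ait: float = Field(5.14, ge=0)
    c_budesonide_ait: float = Field(2.19, ge=0)
    c_loratadine_sympt: float = Field(7.54, ge=0)
    c_budesonide_sympt: float = Field(3.83, ge=0)
    visits_per_year_off_treatment: float = Field(1.9, ge=0)
    c_labour_hour: float = Field(30.70, ge=0)
    sick_days_symptomatic: float = Field(3.7, ge=0)
    sick_days_ait: float = Field(1.2, ge=0)
    productivity_saving_per_season: float = Field(
        133.289, ge=0, description="Calibrated societal saving per on-effect season (EUR)"
    )
    remuneration_unit_cost_tables: dict[str, dict[str, float]] = Field(
        default_factory=dict,
        description="Per-setting overrides of unit costs for scenarios 1-2 (placeholder, non-validated)",
    )


class EconSettings(_Base):
    horizon_years: int = Field(9, ge=1)
    treatment_years: int = Field(3, ge=1)
    cycle_length_years: float = Field(1.0, gt=0)
    discount_rate: float = Field(0.03, ge=0)
    wtp_grid: list[float] = Field(default_factory=lambda: [float(x) for x in range(0, 50001, 1000)])
    wtp_threshold: float = Field(20000.0, ge=0)
    n_psa: int = Field(1000, ge=1)
    rng_seed: int = Field(20150121, ge=0)
    perspective: Literal["payer", "societal"] = "payer"
    psa_fixed_administration_months: bool = Field(
        True,
        description="In PSA draws, hold per-month-priced arms at their base-case treated "
        "months so the season draw varies symptom burden but not the acquisition price "
        "(the deterministic DSA and scenarios keep the full season-cost linkage)",
    )
    efficacy_se_scale: float = Field(
        0.7673, ge=0,
        description="Scale on the 20%-rule SE of the RTSS differences; calibrated to the "
        "published 95% interval of incremental QALYs (5-grass vs allergoid)",
    )

    @model_validator(mode="after")
    def _horizon_covers_treatment(self) -> "EconSettings":
        if self.horizon_years < self.treatment_years:
            raise ValueError(
                f"horizon_years ({self.horizon_years}) must cover treatment_years ({self.treatment_years})"
            )
        return self


class ModelConfig(_Base):
    """Full model configuration: three arms plus shared parameter blocks."""

    arms: dict[str, ArmSpec]
    clinical: ClinicalParams = Field(default_factory=ClinicalParams)
    utility: UtilityParams = Field(default_factory=UtilityParams)
    costs: CostParams = Field(default_factory=CostParams)
    settings: EconSettings = Field(default_factory=EconSettings)

    @model_validator(mode="after")
    def _check_arms(self) -> "ModelConfig":
        missing = [k for k in ARM_KEYS if k not in self.arms]
        if missing:
            raise ValueError(f"missing arm(s): {missing}; required arms are {list(ARM_KEYS)}")
        sympt = self.arms[SYMPTOMATIC]
        if sympt.disc_y1 != 0 or sympt.disc_y2 != 0:
            raise ValueError("symptomatic arm must have zero discontinuation probabilities")
        if sympt.drug_cost_per_month != 0 or (sympt.fixed_annual_drug_cost or 0) != 0:
            raise ValueError("symptomatic arm must have zero treatment (acquisition) costs")
        if sympt.injections_per_treatment_year != 0:
            raise ValueError("symptomatic arm must have zero injections")
        return self

    def copy_deep(self) -> "ModelConfig":
        return self.model_copy(deep=True)


# --- drug-cost model ------------------------------------------------------

def annual_drug_cost(arm: ArmSpec, season_months: float) -> float:
    """Annual drug acquisition cost (EUR/year) for one treated patient-year.

    Per-month pricing scales with (pre-seasonal + season) months; per-pack
    pricing (``fixed_annual_drug_cost``) is flat.
    """
    if not (0 < season_months <= 12):
        raise ValueError(f"season_months must be in (0, 12], got {season_months}")
    if arm.fixed_annual_drug_cost is not None:
        return arm.fixed_annual_drug_cost
    return arm.drug_cost_per_month * arm.months_administered_per_year(season_months)


# --- defaults -------------------------------------------------------------

# 5-grass tablet: EUR 2,100.10 over a 3-year course of 7 treated months/year
# (4 pre-seasonal + 3 in-season) => EUR 100.004761.../month.
_FIVE_GRASS_COURSE_COST = 2100.10
_FIVE_GRASS_TREATED_MONTHS = 21.0
# Allergoid mix: EUR 1,449.60 per 3-year course, one pack per year.
_ALLERGOID_COURSE_COST = 1449.60


def default_config() -> ModelConfig:
    """The base-case configuration (published inputs + calibrated quantities)."""
    arms = {
        FIVE_GRASS: ArmSpec(
            name="5-grass tablet (SLIT)",
            rtss=3.26,
            disc_y1=0.29,
            disc_y2=0.28,
            drug_cost_per_month=_FIVE_GRASS_COURSE_COST / _FIVE_GRASS_TREATED_MONTHS,
            preseasonal_months=4.0,
            visits_per_treatment_year=3.431544,  # calibrated
            injections_per_treatment_year=0.0,
            supervised_first_dose=True,
            diagnostic_in_year1=True,
        ),
        ALLERGOID: ArmSpec(
            name="Allergoid mix (SCIT)",
            rtss=3.64,
            disc_y1=0.41,
            disc_y2=0.34,
            fixed_annual_drug_cost=_ALLERGOID_COURSE_COST / 3.0,
            visits_per_treatment_year=5.147447,  # calibrated
            injections_per_treatment_year=8.070120,  # calibrated
            supervised_first_dose=False,
            diagnostic_in_year1=True,
        ),
        SYMPTOMATIC: ArmSpec(
            name="Symptomatic treatment",
            rtss=4.47,
        ),
    }
    # Placeholder per-setting unit-cost tables for the remuneration scenarios:
    # the underlying fee-catalogue prices are not published, so these repeat
    # the base-case weighted averages and the scenario results are flagged
    # non-validated until users supply real per-setting prices.
    remuneration_tables = {
        setting: {
            "c_specialist_visit": 13.29,
            "c_injection": 5.11,
            "c_diagnostics": 20.61,
        }
        for setting in ("lump_sum", "ambulatory")
    }
    return ModelConfig(
        arms=arms,
        costs=CostParams(remuneration_unit_cost_tables=remuneration_tables),
    )


# --- I/O ------------------------------------------------------------------

def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML/JSON model configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def save_config(config: ModelConfig, path: str | Path) -> Path:
    """Serialize a config to YAML, round-trip safe."""
    path = Path(path)
    data = config.model_dump(mode="json", exclude_none=True)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def bundled_base_case() -> ModelConfig:
    """Load the base-case config shipped with the package."""
    with resources.as_file(resources.files("aitcea").joinpath("data/base_case.yaml")) as p:
        return load_config(p)


def write_schema(path: str | Path) -> Path:
    """Write the JSON Schema of the config format."""
    path = Path(path)
    path.write_text(json.dumps(ModelConfig.model_json_schema(), indent=2))
    return path
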