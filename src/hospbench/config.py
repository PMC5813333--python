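"""Scenario configuration for the synthetic admissions generator.

A :class:`ScenarioConfig` fully describes a simulated multi-hospital cohort:
hospital count and volumes, diagnosis/procedure groups with baseline outcome
risks and length-of-stay (LOS) distributions, between-hospital variance
components on the log-odds scale, the cross-outcome correlation of hospital
effects, patient-level LOS-mortality coupling, and case-mix covariate effects.

Presets (:func:`scenario_preset`) encode the study conditions used throughout
the package: an all-patients-like cohort, stroke-like / colorectal-like /
heart-failure-like strata, a null scenario, and scenarios used for parameter
recovery and rankability experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

#: Ordered age bands shared by the generator and the case-mix models.
AGE_GROUPS: tuple[str, ...] = ("0-17", "18-44", "45-64", "65-79", "80+")

#: Fixed cohort CSV column order (documented external interface).
COHORT_COLUMNS: tuple[str, ...] = (
    "hospital_id",
    "group",
    "year",
    "age_group",
    "sex",
    "unplanned",
    "transfer_in",
    "urgent_prior",
    "elixhauser_count",
    "los_days",
    "died",
    "readmitted_30d",
)


class ConfigurationError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


@dataclass(frozen=True)
class GroupSpec:
    """One diagnosis/procedure group.

    ``los_location`` and ``los_scale`` parameterize a log-logistic LOS
    distribution: ``log(LOS) ~ Logistic(los_location, los_scale)``.  The
    q-quantile of LOS is ``exp(los_location + los_scale * logit(q))``, so the
    upper quartile cutoff is ``exp(los_location + los_scale * ln 3)``.
    """

    name: str
    p_mortality: float
    p_readmission: float
    los_location: float
    los_scale: float
    weight: float = 1.0

    def los_quantile(self, q: float) -> float:
        return float(np.exp(self.los_location + self.los_scale * np.log(q / (1.0 - q))))


@dataclass(frozen=True)
class CaseMixEffects:
    """Log-odds effects of the case-mix covariates on mortality/readmission.

    ``age_per_step`` multiplies the (0-based) age-band index; ``elixhauser``
    multiplies the comorbidity count; the rest are binary indicator effects.
    Covariate contributions are centered at their population means at
    generation time so the marginal outcome rates stay near the group
    baselines.
    """

    age_per_step: float = 0.0
    sex: float = 0.0
    unplanned: float = 0.0
    transfer_in: float = 0.0
    urgent_prior: float = 0.0
    elixhauser: float = 0.0


def _identity3() -> tuple[tuple[float, ...], ...]:
    return ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


@dataclass
class ScenarioConfig:
    """Full generative specification of a synthetic multi-hospital cohort."""

    n_hospitals: int
    volume_range: tuple[int, int]
    groups: tuple[GroupSpec, ...]
    years: tuple[int, ...] = (2007, 2008, 2009, 2010, 2011, 2012)
    # Per-year linear trends on the outcome log-odds (per year, centered).
    year_trend_mortality: float = 0.0
    year_trend_readmission: float = 0.0
    year_trend_los: float = 0.0
    # Between-hospital variances of the planted effects (log-odds^2 scale).
    tau2_mort: float = 0.0
    tau2_readm: float = 0.0
    tau2_los: float = 0.0
    hospital_effect_correlation: tuple[tuple[float, ...], ...] = field(
        default_factory=_identity3
    )
    # Patient-level log-OR of the latent upper-quartile-LOS indicator on mortality.
    patient_coupling_mort_los: float = 0.0
    # Stroke-like pattern: deaths receive LOS from a short-LOS distribution.
    early_death_short_los: bool = False
    short_los_shift: float = -0.3
    short_los_scale_factor: float = 0.9
    casemix_effects: CaseMixEffects = field(default_factory=CaseMixEffects)
    # Covariate marginals.
    age_probs: tuple[float, ...] = (0.20, 0.25, 0.25, 0.20, 0.10)
    p_male: float = 0.46
    p_unplanned: float = 0.63
    p_transfer: float = 0.05
    p_urgent: float = 0.52
    elixhauser_mean: float = 1.4
    # Optional explicit hospital effects (n_hospitals x 3: mort, readm, los);
    # overrides the random draw (used to plant a known effect in one hospital).
    hospital_effects_override: Optional[tuple[tuple[float, float, float], ...]] = None
    seed: int = 0

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        if self.n_hospitals < 1:
            raise ConfigurationError("n_hospitals must be >= 1")
        lo, hi = self.volume_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("volume_range must satisfy 1 <= min <= max")
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")
        for g in self.groups:
            for p in (g.p_mortality, g.p_readmission):
                if not 0.0 < p < 1.0:
                    raise ConfigurationError(
                        f"group {g.name!r}: probabilities must lie in (0,1)"
                    )
            if g.los_scale <= 0:
                raise ConfigurationError(f"group {g.name!r}: los_scale must be > 0")
            if g.weight <= 0:
                raise ConfigurationError(f"group {g.name!r}: weight must be > 0")
        for tau2 in (self.tau2_mort, self.tau2_readm, self.tau2_los):
            if tau2 < 0:
                raise ConfigurationError("variances tau2 must be >= 0")
        corr = np.asarray(self.hospital_effect_correlation, dtype=float)
        if corr.shape != (3, 3):
            raise ConfigurationError("hospital_effect_correlation must be 3x3")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ConfigurationError("hospital_effect_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ConfigurationError("hospital_effect_correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError(
                "hospital_effect_correlation must be positive semi-definite"
            )
        if abs(sum(self.age_probs) - 1.0) > 1e-8:
            raise ConfigurationError("age_probs must sum to 1")
        if self.hospital_effects_override is not None:
            arr = np.asarray(self.hospital_effects_override, dtype=float)
            if arr.shape != (self.n_hospitals, 3):
                raise ConfigurationError(
                    "hospital_effects_override must be n_hospitals x 3"
                )
        if not self.years:
            raise ConfigurationError("years must be non-empty")

    @property
    def correlation_matrix(self) -> np.ndarray:
        return np.asarray(self.hospital_effect_correlation, dtype=float)

    @property
    def group_weights(self) -> np.ndarray:
        w = np.array([g.weight for g in self.groups], dtype=float)
        return w / w.sum()

    def hospital_ids(self) -> list[str]:
        width = max(2, len(str(self.n_hospitals)))
        return [f"H{i + 1:0{width}d}" for i in range(self.n_hospitals)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with the given fields replaced (validated)."""
        new = dataclasses.replace(self, **kwargs)
        new.validate()
        return new


# --------------------------------------------------------------------------- #
# Presets
# --------------------------------------------------------------------------- #

def _corr(mort_los: float, mort_readm: float = 0.0, readm_los: float = 0.0):
    return (
        (1.0, mort_readm, mort_los),
        (mort_readm, 1.0, readm_los),
        (mort_los, readm_los, 1.0),
    )


_DEFAULT_CASEMIX = CaseMixEffects(
    age_per_step=0.45,
    sex=0.10,
    unplanned=0.70,
    transfer_in=0.30,
    urgent_prior=0.30,
    elixhauser=0.25,
)


def _preset_null() -> ScenarioConfig:
    return ScenarioConfig(
        n_hospitals=26,
        volume_range=(1500, 4500),
        groups=(
            GroupSpec("general", 0.031, 0.078, float(np.log(4.5)), 0.55),
        ),
    )


def _preset_all_patients() -> ScenarioConfig:
    # Baseline rates follow the overall administrative-cohort profile:
    # ~3.1% in-hospital mortality, ~7.8% 30-day readmission among survivors.
    return ScenarioConfig(
        n_hospitals=26,
        volume_range=(1500, 4500),
        groups=(
            GroupSpec("general_medicine", 0.031, 0.078, float(np.log(4.5)), 0.55, 0.5),
            GroupSpec("general_surgery", 0.020, 0.070, float(np.log(5.5)), 0.50, 0.3),
            GroupSpec("cardiology", 0.055, 0.110, float(np.log(5.0)), 0.50, 0.2),
        ),
        tau2_mort=0.15,
        tau2_readm=0.05,
        tau2_los=0.15,
        hospital_effect_correlation=_corr(0.8),
        patient_coupling_mort_los=float(np.log(1.45)),
        casemix_effects=_DEFAULT_CASEMIX,
    )


def _preset_stroke_like() -> ScenarioConfig:
    # High-mortality stratum with the early-death/short-LOS mechanism: deaths
    # cluster early in the admission so dying patients have short LOS, while
    # high-mortality hospitals also keep survivors longer.
    return ScenarioConfig(
        n_hospitals=26,
        volume_range=(1500, 4500),
        groups=(GroupSpec("stroke", 0.136, 0.073, float(np.log(8.0)), 0.60),),
        tau2_mort=0.15,
        tau2_readm=0.05,
        tau2_los=0.15,
        hospital_effect_correlation=_corr(0.8),
        patient_coupling_mort_los=0.0,
        early_death_short_los=True,
        casemix_effects=_DEFAULT_CASEMIX,
        p_unplanned=0.83,
        p_urgent=0.81,
        elixhauser_mean=2.2,
        age_probs=(0.02, 0.10, 0.28, 0.35, 0.25),
    )


def _preset_colorectal_like() -> ScenarioConfig:
    return ScenarioConfig(
        n_hospitals=26,
        volume_range=(700, 2000),
        groups=(GroupSpec("colorectal", 0.050, 0.106, float(np.log(10.0)), 0.55),),
        tau2_mort=0.15,
        tau2_readm=0.05,
        tau2_los=0.15,
        hospital_effect_correlation=_corr(0.8),
        patient_coupling_mort_los=float(np.log(1.31)),
        casemix_effects=_DEFAULT_CASEMIX,
        p_unplanned=0.31,
        p_urgent=0.30,
        elixhauser_mean=1.6,
        age_probs=(0.03, 0.20, 0.35, 0.28, 0.14),
    )


def _preset_heart_failure_like() -> ScenarioConfig:
    return ScenarioConfig(
        n_hospitals=26,
        volume_range=(800, 2500),
        groups=(GroupSpec("heart_failure", 0.067, 0.169, float(np.log(7.0)), 0.50),),
        tau2_mort=0.15,
        tau2_readm=0.05,
        tau2_los=0.15,
        hospital_effect_correlation=_corr(0.8),
        patient_coupling_mort_los=float(np.log(1.38)),
        casemix_effects=_DEFAULT_CASEMIX,
        p_unplanned=0.85,
        p_urgent=0.85,
        elixhauser_mean=3.8,
        age_probs=(0.01, 0.08, 0.25, 0.36, 0.30),
    )


def _preset_coupled() -> ScenarioConfig:
    # Hospital effects on mortality and long LOS strongly correlated;
    # readmission effects independent of both.
    return ScenarioConfig(
        n_hospitals=26,
        volume_range=(1500, 4500),
        groups=(GroupSpec("general", 0.031, 0.078, float(np.log(4.5)), 0.55),),
        tau2_mort=0.20,
        tau2_readm=0.10,
        tau2_los=0.20,
        hospital_effect_correlation=_corr(0.9),
        patient_coupling_mort_los=float(np.log(1.45)),
        casemix_effects=_DEFAULT_CASEMIX,
    )


def _preset_shared_effect() -> ScenarioConfig:
    # One latent hospital quality dimension shared by all three outcomes
    # (correlation 1, equal variances); no covariate effects, single year.
    # Used for parameter-recovery and rankability experiments.
    corr_one = ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))
    return ScenarioConfig(
        n_hospitals=26,
        volume_range=(1500, 4500),
        groups=(GroupSpec("general", 0.031, 0.078, float(np.log(4.5)), 0.55),),
        years=(2010,),
        tau2_mort=0.25,
        tau2_readm=0.25,
        tau2_los=0.25,
        hospital_effect_correlation=corr_one,
    )


def _preset_improving() -> ScenarioConfig:
    # Planted quality improvement over calendar time: mortality log-odds and
    # LOS both trend down, so the share of best composite outcomes rises.
    cfg = _preset_null()
    return cfg.replace(
        year_trend_mortality=-0.06,
        year_trend_los=-0.04,
    )


_PRESETS = {
    "null": _preset_null,
    "all_patients": _preset_all_patients,
    "stroke_like": _preset_stroke_like,
    "colorectal_like": _preset_colorectal_like,
    "heart_failure_like": _preset_heart_failure_like,
    "coupled": _preset_coupled,
    "shared_effect": _preset_shared_effect,
    "improving": _preset_improving,
}


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    """Return a fully populated preset configuration.

    Parameters
    ----------
    name
        One of :func:`list_presets`.
    **overrides
        Field replacements applied on top of the preset (validated).
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(list_presets())}"
        ) from None
    cfg = factory()
    if overrides:
        cfg = cfg.replace(**overrides)
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------- #
# YAML round-trip
# --------------------------------------------------------------------------- #

def config_from_dict(data: dict) -> ScenarioConfig:
    data = dict(data)
    preset = data.pop("preset", None)
    if "groups" in data:
        data["groups"] = tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(**g) for g in data["groups"]
        )
    if "casemix_effects" in data and not isinstance(
        data["casemix_effects"], CaseMixEffects
    ):
        data["casemix_effects"] = CaseMixEffects(**data["casemix_effects"])
    for key in ("volume_range", "years", "age_probs"):
        if key in data:
            data[key] = tuple(data[key])
    if "hospital_effect_correlation" in data:
        data["hospital_effect_correlation"] = tuple(
            tuple(row) for row in data["hospital_effect_correlation"]
        )
    if "hospital_effects_override" in data and data["hospital_effects_override"] is not None:
        data["hospital_effects_override"] = tuple(
            tuple(row) for row in data["hospital_effects_override"]
        )
    if preset is not None:
        cfg = scenario_preset(preset)
        cfg = cfg.replace(**data)
    else:
        cfg = ScenarioConfig(**data)
    cfg.validate()
    return cfg


def config_from_yaml(path) -> ScenarioConfig:
    """Load a config from YAML; a ``preset`` key seeds defaults, other keys override."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
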