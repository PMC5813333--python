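"""Synthetic admission-level cohort generator with known planted hospital effects.

Each hospital receives a trivariate-normal "quality" effect (mortality,
readmission, long LOS) on the log-odds scale; admissions then combine group
baseline risks, case-mix covariate effects, the hospital effect, an optional
patient-level LOS-mortality coupling and optional calendar trends.

Randomness flows from a single integer seed through a documented splitting
scheme: ``SeedSequence(seed)`` is spawned into one child stream for the
hospital effects plus one child stream per hospital, so regenerating any
single hospital reproduces its records exactly.

LOS is log-logistic: ``log(LOS) ~ Logistic(location, scale)``.  The hospital
effect ``eta_los`` (and the calendar trend) enters as a location shift of
``scale * eta``, which makes it an exact log-odds offset on ``P(LOS > c)``
for every fixed cutoff ``c`` — the planted tau2_los really is a variance on
the log-odds scale of the long-LOS outcome.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import AGE_GROUPS, COHORT_COLUMNS, ConfigurationError, ScenarioConfig

__all__ = [
    "generate_hospital_effects",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


def _effect_covariance(config: ScenarioConfig) -> np.ndarray:
    sd = np.sqrt([config.tau2_mort, config.tau2_readm, config.tau2_los])
    return config.correlation_matrix * np.outer(sd, sd)


def generate_hospital_effects(
    config: ScenarioConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Draw per-hospital log-odds effects (eta_mort, eta_readm, eta_los).

    Effects are drawn from a trivariate normal with the configured variances
    and correlation, then centered so each column's sample mean is exactly 0
    (zero variances yield exactly-zero columns).  An explicit
    ``hospital_effects_override`` in the config bypasses the draw and is used
    verbatim (not centered), allowing known effects to be planted.
    """
    config.validate()
    ids = config.hospital_ids()
    if config.hospital_effects_override is not None:
        eta = np.asarray(config.hospital_effects_override, dtype=float)
    else:
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
        cov = _effect_covariance(config)
        eta = rng.multivariate_normal(np.zeros(3), cov, size=config.n_hospitals,
                                      method="svd")
        if config.n_hospitals > 1:
            eta = eta - eta.mean(axis=0, keepdims=True)
        # exact zeros where the variance is zero
        for j, tau2 in enumerate((config.tau2_mort, config.tau2_readm, config.tau2_los)):
            if tau2 == 0.0:
                eta[:, j] = 0.0
    return pd.DataFrame(
        {
            "hospital_id": ids,
            "eta_mort": eta[:, 0],
            "eta_readm": eta[:, 1],
            "eta_los": eta[:, 2],
        }
    )


def _centered_casemix_lp(config: ScenarioConfig, age_idx, sex, unplanned,
                         transfer, urgent, elix) -> np.ndarray:
    """Case-mix linear predictor with covariate contributions mean-centered."""
    eff = config.casemix_effects
    age_mean = float(np.dot(np.arange(len(AGE_GROUPS)), config.age_probs))
    lp = (
        eff.age_per_step * (age_idx - age_mean)
        + eff.sex * (sex - config.p_male)
        + eff.unplanned * (unplanned - config.p_unplanned)
        + eff.transfer_in * (transfer - config.p_transfer)
        + eff.urgent_prior * (urgent - config.p_urgent)
        + eff.elixhauser * (elix - config.elixhauser_mean)
    )
    return lp


def generate_cohort(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an admission-level cohort plus the planted hospital effects.

    Returns
    -------
    records : DataFrame
        One row per admission, columns :data:`hospbench.config.COHORT_COLUMNS`.
        ``readmitted_30d`` is a nullable integer, missing (``pd.NA``) for
        in-hospital deaths: readmission is undefined for non-survivors.
    effects : DataFrame
        hospital_id, eta_mort, eta_readm, eta_los (the ground truth).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_hospitals + 1)
    effects = generate_hospital_effects(config, np.random.default_rng(children[0]))

    years = np.asarray(config.years, dtype=int)
    year_mid = float(years.mean())
    groups = config.groups
    gw = config.group_weights
    g_logit_mort = np.array([logit(g.p_mortality) for g in groups])
    g_logit_readm = np.array([logit(g.p_readmission) for g in groups])
    g_loc = np.array([g.los_location for g in groups])
    g_scale = np.array([g.los_scale for g in groups])
    # base-distribution upper-quartile cutoff on the log scale per group
    g_q75_log = g_loc + g_scale * np.log(3.0)

    frames = []
    vmin, vmax = config.volume_range
    for h, hid in enumerate(config.hospital_ids()):
        rng = np.random.default_rng(children[h + 1])
        n = int(rng.integers(vmin, vmax + 1))
        gi = rng.choice(len(groups), size=n, p=gw)
        age_idx = rng.choice(len(AGE_GROUPS), size=n, p=np.asarray(config.age_probs))
        sex = (rng.random(n) < config.p_male).astype(np.int8)
        unplanned = (rng.random(n) < config.p_unplanned).astype(np.int8)
        transfer = (rng.random(n) < config.p_transfer).astype(np.int8)
        urgent = (rng.random(n) < config.p_urgent).astype(np.int8)
        elix = rng.poisson(config.elixhauser_mean, size=n)
        year = rng.choice(years, size=n)
        yc = year - year_mid

        eta_m = effects["eta_mort"].iloc[h]
        eta_r = effects["eta_readm"].iloc[h]
        eta_l = effects["eta_los"].iloc[h]

        scale = g_scale[gi]
        loc = g_loc[gi] + scale * (eta_l + config.year_trend_los * yc)
        log_los = loc + scale * rng.logistic(0.0, 1.0, size=n)
        long_latent = (log_los > g_q75_log[gi]).astype(np.int8)

        cm = _centered_casemix_lp(config, age_idx, sex, unplanned, transfer,
                                  urgent, elix)
        lp_mort = (
            g_logit_mort[gi]
            + cm
            + eta_m
            + config.patient_coupling_mort_los * (long_latent - 0.25)
            + config.year_trend_mortality * yc
        )
        died = (rng.random(n) < expit(lp_mort)).astype(np.int8)

        if config.early_death_short_los and died.any():
            # deaths occur early in the admission: redraw their LOS from a
            # shorter, tighter log-logistic
            idx = np.flatnonzero(died == 1)
            s = g_scale[gi[idx]]
            loc_short = (
                g_loc[gi[idx]]
                + s * (eta_l + config.year_trend_los * (year[idx] - year_mid))
                + config.short_los_shift
            )
            log_los[idx] = loc_short + s * config.short_los_scale_factor * rng.logistic(
                0.0, 1.0, size=idx.size
            )

        lp_readm = (
            g_logit_readm[gi]
            + cm
            + eta_r
            + config.year_trend_readmission * yc
        )
        readm_draw = (rng.random(n) < expit(lp_readm)).astype(np.int8)
        readm = pd.array(readm_draw, dtype="Int8")
        readm[died == 1] = pd.NA  # undefined for deaths, never 0

        los_days = np.maximum(np.round(np.exp(log_los), 3), 0.01)

        frames.append(
            pd.DataFrame(
                {
                    "hospital_id": hid,
                    "group": [groups[i].name for i in gi],
                    "year": year,
                    "age_group": pd.Categorical.from_codes(
                        age_idx, categories=list(AGE_GROUPS), ordered=True
                    ),
                    "sex": sex,
                    "unplanned": unplanned,
                    "transfer_in": transfer,
                    "urgent_prior": urgent,
                    "elixhauser_count": elix.astype(np.int64),
                    "los_days": los_days,
                    "died": died,
                    "readmitted_30d": readm,
                }
            )
        )

    records = pd.concat(frames, ignore_index=True)
    records = records[list(COHORT_COLUMNS)]
    return records, effects


# --------------------------------------------------------------------------- #
# Persistence
# --------------------------------------------------------------------------- #

def write_cohort(records: pd.DataFrame, effects: pd.DataFrame,
                 config: ScenarioConfig, outdir) -> dict:
    """Write cohort.csv plus truth.json (planted effects + config echo).

    Returns the paths written.  Output is byte-stable for a fixed config/seed.
    """
    os.makedirs(outdir, exist_ok=True)
    cohort_path = os.path.join(outdir, "cohort.csv")
    truth_path = os.path.join(outdir, "truth.json")
    out = records.copy()
    out.to_csv(cohort_path, index=False, na_rep="")
    truth = {
        "config": config.to_dict(),
        "hospital_effects": effects.to_dict(orient="records"),
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"cohort": cohort_path, "truth": truth_path}


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (or conforming)."""
    df = pd.read_csv(
        path,
        dtype={
            "hospital_id": str,
            "group": str,
            "year": np.int64,
            "sex": np.int8,
            "unplanned": np.int8,
            "transfer_in": np.int8,
            "urgent_prior": np.int8,
            "elixhauser_count": np.int64,
            "died": np.int8,
            "readmitted_30d": "Int8",
        },
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort file missing columns: {missing}")
    df["age_group"] = pd.Categorical(df["age_group"], categories=list(AGE_GROUPS),
                                     ordered=True)
    if ((df["died"] == 1) & df["readmitted_30d"].notna()).any():
        raise ConfigurationError("readmitted_30d must be missing for deaths")
    if (df["los_days"] <= 0).any():
        raise ConfigurationError("los_days must be positive")
    return df[list(COHORT_COLUMNS)]
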