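"""Indirect standardization: long-LOS definition, O/E ratios, patient-level
odds ratios and hospital-level correlations.

Long LOS is a stay strictly greater than the group-specific 75th percentile
(90th for the upper-decile sensitivity analysis), computed by the nearest-rank
convention on LOS pooled over all hospitals and years.  Per hospital the
observed outcome count is divided by the expected count from the case-mix
models and multiplied by 100; 100 means "as expected".  Mortality ratios use
all admissions; readmission and long-LOS ratios use survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from .casemix import expected_probabilities, outcome_series
from .design import build_design, casemix_terms

__all__ = [
    "LongLosRule",
    "nearest_rank",
    "long_los_flags",
    "standardized_ratio",
    "standardized_ratios",
    "PatientLevelOR",
    "patient_level_or",
    "hospital_correlations",
    "correlation_matrix",
]


# --------------------------------------------------------------------------- #
# Long LOS
# --------------------------------------------------------------------------- #

@dataclass
class LongLosRule:
    """Group-specific LOS cutoffs for the long-LOS outcome."""

    percentile: int
    cutoffs: dict[str, float]
    low_confidence: set[str] = field(default_factory=set)

    def flag(self, records: pd.DataFrame) -> pd.Series:
        cut = records["group"].map(self.cutoffs)
        if cut.isna().any():
            missing = sorted(records.loc[cut.isna(), "group"].unique())
            raise KeyError(f"no LOS cutoff for group(s): {missing}")
        return records["los_days"] > cut  # strictly greater


def nearest_rank(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("cannot compute a percentile of zero values")
    k = int(np.ceil(percentile / 100.0 * n))
    k = min(max(k, 1), n)
    return float(v[k - 1])


def long_los_flags(
    records: pd.DataFrame, percentile: int = 75
) -> tuple[pd.Series, LongLosRule]:
    """Flag stays strictly above the group-specific percentile cutoff.

    Cutoffs are computed per diagnosis/procedure group on LOS pooled over all
    hospitals and years.  Groups with fewer than 4 records still get a cutoff
    but are marked low-confidence in the returned rule.
    """
    if percentile not in (75, 90):
        raise ValueError("percentile must be 75 or 90")
    cutoffs: dict[str, float] = {}
    low_conf: set[str] = set()
    for grp, sub in records.groupby("group", observed=True):
        cutoffs[str(grp)] = nearest_rank(sub["los_days"].to_numpy(), percentile)
        if len(sub) < 4:
            low_conf.add(str(grp))
    rule = LongLosRule(percentile=percentile, cutoffs=cutoffs, low_confidence=low_conf)
    return rule.flag(records).rename("long_los"), rule


# --------------------------------------------------------------------------- #
# Standardized ratios
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class StandardizedRatio:
    hospital_id: str
    outcome: str
    observed: int
    expected: float
    ratio: float
    denominator_population: str  # all | survivors


def standardized_ratio(observed: int, expected: float) -> float:
    """100 * observed / expected (the standardized rate; 100 = as expected)."""
    if expected <= 0:
        raise ValueError("expected count must be > 0 for a standardized ratio")
    return 100.0 * observed / expected


def standardized_ratios(
    records: pd.DataFrame,
    models: dict,
    outcomes=("mortality", "readmission", "long_los"),
) -> pd.DataFrame:
    """Per-hospital observed, expected and 100*O/E for each outcome.

    ``records`` must carry a ``long_los`` column when that outcome is
    requested.  Expected counts come from summing the case-mix model
    probabilities within each hospital over the outcome's denominator
    population (all admissions for mortality; survivors otherwise).
    """
    probs = expected_probabilities(models, records)
    rows = []
    for outcome in outcomes:
        mask, y = outcome_series(records, outcome)
        denom = "all" if outcome == "mortality" else "survivors"
        sub = records.loc[mask]
        obs = y.loc[sub.index].groupby(sub["hospital_id"]).sum()
        exp = probs.loc[sub.index, outcome].groupby(sub["hospital_id"]).sum()
        for hid in obs.index:
            e = float(exp.loc[hid])
            rows.append(
                {
                    "hospital_id": hid,
                    "outcome": outcome,
                    "observed": int(obs.loc[hid]),
                    "expected": e,
                    "ratio": standardized_ratio(int(obs.loc[hid]), e),
                    "denominator_population": denom,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# Patient-level odds ratios
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PatientLevelOR:
    outcome: str
    adjustment: str          # "none" | "center+casemix"
    odds_ratio: float
    ci_low: float
    ci_high: float
    n: int


def patient_level_or(
    records: pd.DataFrame,
    outcome: str,
    adjusted: bool = False,
    long_los: Optional[pd.Series] = None,
) -> PatientLevelOR:
    """Patient-level OR of upper-quartile LOS on mortality or readmission.

    Unadjusted: logistic regression of the outcome on the long-LOS flag alone.
    Adjusted: adds hospital (fixed-effect dummies) and the case-mix main
    effects.  Readmission is modelled among survivors only.
    """
    if outcome not in ("mortality", "readmission"):
        raise ValueError("patient-level ORs are defined for mortality/readmission")
    df = records
    if long_los is None:
        if "long_los" not in df.columns:
            raise KeyError("records need a 'long_los' column (or pass long_los=)")
        long_los = df["long_los"]
    mask, y = outcome_series(df, outcome)
    df = df.loc[mask]
    yv = y.loc[df.index].to_numpy(dtype=float)
    expo = long_los.loc[df.index].to_numpy(dtype=float)

    if not adjusted:
        tab = np.array(
            [
                [np.sum((expo == 1) & (yv == 1)), np.sum((expo == 1) & (yv == 0))],
                [np.sum((expo == 0) & (yv == 1)), np.sum((expo == 0) & (yv == 0))],
            ]
        )
        if (tab == 0).any():
            raise ValueError(
                "zero cell in the exposure-outcome 2x2 table; continuity "
                "handling is the caller's choice"
            )
        X = np.column_stack([np.ones_like(expo), expo])
        res = sm.GLM(yv, X, family=sm.families.Binomial()).fit()
        coef, se = res.params[1], res.bse[1]
        adjustment = "none"
    else:
        terms = casemix_terms(
            include_year=df["year"].nunique() > 1,
            include_group=df["group"].nunique() > 1,
            interactions=False,
        )
        Xcm, info = build_design(df, terms, intercept=False)
        hosp = pd.get_dummies(df["hospital_id"], drop_first=True).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(df)), expo, Xcm, hosp])
        res = sm.GLM(yv, X, family=sm.families.Binomial()).fit(maxiter=200)
        coef, se = res.params[1], res.bse[1]
        adjustment = "center+casemix"

    z = stats.norm.ppf(0.975)
    return PatientLevelOR(
        outcome=outcome,
        adjustment=adjustment,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        n=len(df),
    )


# --------------------------------------------------------------------------- #
# Hospital-level correlations
# --------------------------------------------------------------------------- #

def hospital_correlations(
    ratios_a: pd.Series, ratios_b: pd.Series
) -> tuple[float, float]:
    """Pearson r (and two-sided p from the t distribution, n-2 df) between two
    per-hospital standardized-ratio vectors aligned on hospital id."""
    a, b = ratios_a.align(ratios_b, join="inner")
    if len(a) < 3:
        raise ValueError("need at least 3 hospitals for a correlation")
    if np.std(a.to_numpy()) == 0 or np.std(b.to_numpy()) == 0:
        raise ValueError("zero variance in a ratio vector; correlation undefined")
    r, p = stats.pearsonr(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
    return float(r), float(p)


def correlation_matrix(ratio_table: pd.DataFrame,
                       extra: Optional[dict[str, pd.Series]] = None) -> pd.DataFrame:
    """Pairwise Pearson r/p between per-hospital standardized outcome ratios.

    ``ratio_table`` is the output of :func:`standardized_ratios`; ``extra``
    adds named per-hospital series (e.g. the standardized composite rate).
    Returns a long-format frame (outcome_a, outcome_b, r, p).
    """
    series = {
        outcome: sub.set_index("hospital_id")["ratio"]
        for outcome, sub in ratio_table.groupby("outcome")
    }
    if extra:
        series.update(extra)
    names = sorted(series)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r, p = hospital_correlations(series[a], series[b])
            rows.append({"outcome_a": a, "outcome_b": b, "r": r, "p": p})
    return pd.DataFrame(rows)
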