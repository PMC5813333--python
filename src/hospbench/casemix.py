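"""Per-group logistic case-mix models with backward elimination.

For every diagnosis/procedure group and every outcome (in-hospital mortality,
30-day unplanned readmission among survivors, long LOS among survivors) a
logistic regression is fitted on the case-mix variables — age group, sex,
method of admission, transfer-in, urgent prior admission, Elixhauser
comorbidity count, discharge year — plus two a-priori interaction candidates
(age x Elixhauser, admission method x transfer).  Backward elimination removes
one term at a time (largest block-Wald p >= 0.1, interactions before their
main effects) with a refit after each removal.  Sparse age bands (< 10 events)
are iteratively merged with the immediately older band before fitting.

The fitted models yield an expected outcome probability per admission; summing
these per hospital gives the expected counts behind the standardized ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import chi2

from .config import AGE_GROUPS
from .design import DesignInfo, Term, build_design, casemix_terms, interaction_parents

__all__ = [
    "OUTCOMES",
    "merge_sparse_age_groups",
    "CaseMixLogit",
    "CaseMixResults",
    "fit_casemix_models",
    "expected_probabilities",
    "outcome_series",
]

OUTCOMES = ("mortality", "readmission", "long_los")

#: Ridge strength used by the separation/non-convergence fallback.
RIDGE_ALPHA = 1e-3

P_REMOVE = 0.1          # backward-elimination retention threshold
MIN_ADMISSIONS = 25     # below this, intercept-only model
MIN_EVENTS = 10         # below this, intercept-only model


def outcome_series(records: pd.DataFrame, outcome: str) -> tuple[pd.Series, pd.Series]:
    """Return (row mask, 0/1 outcome) for one outcome definition.

    Readmission and long LOS are defined over survivors only; mortality over
    all admissions.  ``long_los`` requires a boolean/0-1 ``long_los`` column
    (see :func:`hospbench.standardize.long_los_flags`).
    """
    if outcome == "mortality":
        return pd.Series(True, index=records.index), records["died"].astype(int)
    if outcome == "readmission":
        mask = records["died"] == 0
        return mask, records["readmitted_30d"].astype("Int8").astype("float").fillna(0).astype(int)
    if outcome == "long_los":
        if "long_los" not in records.columns:
            raise KeyError("records need a 'long_los' column for the long_los outcome")
        mask = records["died"] == 0
        return mask, records["long_los"].astype(int)
    raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


# --------------------------------------------------------------------------- #
# Age-group merging
# --------------------------------------------------------------------------- #

def merge_sparse_age_groups(
    age: pd.Series,
    events: pd.Series,
    min_events: int = MIN_EVENTS,
    levels: Sequence[str] = AGE_GROUPS,
) -> dict:
    """Iteratively merge sparse age bands with the immediately older band.

    Repeatedly, the youngest band with fewer than ``min_events`` events is
    merged into the next-older band (the oldest band, if sparse, merges with
    the next-younger one); merging stops when every merged band has at least
    ``min_events`` events or a single band remains.  Returns a total mapping
    original level -> merged label.
    """
    levels = [lev for lev in levels]
    ev = pd.Series(np.asarray(events, dtype=int), index=age.index)
    counts = ev.groupby(pd.Categorical(age, categories=levels), observed=False).sum()
    segments: list[list[str]] = [[lev] for lev in levels]
    seg_events: list[int] = [int(counts.get(lev, 0)) for lev in levels]

    while len(segments) > 1:
        idx = next((i for i, e in enumerate(seg_events) if e < min_events), None)
        if idx is None:
            break
        if idx < len(segments) - 1:          # merge into next-older band
            segments[idx + 1] = segments[idx] + segments[idx + 1]
            seg_events[idx + 1] += seg_events[idx]
        else:                                # oldest band: merge downward
            segments[idx - 1] = segments[idx - 1] + segments[idx]
            seg_events[idx - 1] += seg_events[idx]
        del segments[idx], seg_events[idx]

    mapping: dict = {}
    for seg in segments:
        label = seg[0] if len(seg) == 1 else "+".join(seg)
        for lev in seg:
            mapping[lev] = label
    return mapping


# --------------------------------------------------------------------------- #
# Logistic fitting with ridge fallback
# --------------------------------------------------------------------------- #

@dataclass
class _LogitFit:
    params: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool
    penalized: bool


def _glm_logit(X: np.ndarray, y: np.ndarray) -> _LogitFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
    params = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    ok = bool(
        getattr(res, "converged", True)
        and np.all(np.isfinite(params))
        and np.all(np.isfinite(cov))
        and np.max(np.abs(params)) < 20.0
    )
    return _LogitFit(params, cov, float(res.llf), ok, penalized=False)


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = RIDGE_ALPHA,
                 max_iter: int = 100) -> _LogitFit:
    """Newton-Raphson logistic fit with an L2 penalty on non-intercept terms."""
    n, p = X.shape
    pen = np.full(p, alpha)
    pen[0] = 0.0  # intercept unpenalized (column 0 by construction)
    beta = np.zeros(p)
    beta[0] = logit(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-9:
            converged = True
            break
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = mu * (1 - mu)
    H = (X * w[:, None]).T @ X + np.diag(pen)
    cov = np.linalg.inv(H)
    return _LogitFit(beta, cov, llf, converged, penalized=True)


def _fit_logit(X: np.ndarray, y: np.ndarray) -> _LogitFit:
    fit = _glm_logit(X, y)
    if not fit.converged:
        fit = _ridge_logit(X, y)
    return fit


def _wald_term_p(fit: _LogitFit, cols: list[int]) -> float:
    b = fit.params[cols]
    V = fit.cov[np.ix_(cols, cols)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        stat = float(b @ np.linalg.pinv(V) @ b)
    return float(chi2.sf(stat, len(cols)))


# --------------------------------------------------------------------------- #
# Model / Results
# --------------------------------------------------------------------------- #

@dataclass
class CaseMixResults:
    """Fitted case-mix model for one (outcome, group) cell."""

    outcome: str
    group: Optional[str]
    retained_terms: list[str]
    coefficients: dict[str, float]
    age_merge_map: dict
    design_info: Optional[DesignInfo]
    params: np.ndarray
    cov: Optional[np.ndarray]
    llf: float
    n: int
    n_events: int
    converged: bool
    penalized: bool
    intercept_only: bool
    term_pvalues: dict[str, float] = field(default_factory=dict)

    def predict(self, records: pd.DataFrame) -> pd.Series:
        """Expected outcome probability per record (index-aligned)."""
        if self.intercept_only or self.design_info is None:
            p = expit(self.params[0])
            return pd.Series(np.full(len(records), p), index=records.index)
        X, _ = build_design(records, self.design_info.terms, info=self.design_info)
        return pd.Series(expit(X @ self.params), index=records.index)

    def standard_errors(self) -> Optional[np.ndarray]:
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> str:
        lines = [
            f"Case-mix logistic model  outcome={self.outcome}  group={self.group}",
            f"  n={self.n}  events={self.n_events}  converged={self.converged}"
            f"  penalized={self.penalized}  intercept_only={self.intercept_only}",
            f"  log-likelihood={self.llf:.3f}",
            f"  retained terms: {', '.join(self.retained_terms)}",
            f"  {'coefficient':<32s}{'estimate':>12s}{'std.err':>12s}",
        ]
        se = self.standard_errors()
        names = (self.design_info.column_names if self.design_info is not None
                 else ["Intercept"])
        for i, name in enumerate(names):
            s = f"{se[i]:>12.4f}" if se is not None else " " * 12
            lines.append(f"  {name:<32s}{self.params[i]:>12.4f}{s}")
        return "\n".join(lines)


class CaseMixLogit:
    """Backward-elimination logistic case-mix model (statsmodels-style).

    Parameters
    ----------
    records
        Admission-level records; for ``readmission``/``long_los`` the model is
        fitted on survivors automatically.
    outcome
        One of ``mortality``, ``readmission``, ``long_los``.
    group
        Restrict to one diagnosis/procedure group; ``None`` fits pooled
        (optionally with ``group`` as an eliminable categorical term).
    elimination
        If False, fit the full candidate model without elimination.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        outcome: str,
        group: Optional[str] = None,
        include_group_term: bool = False,
        interactions: bool = True,
        elimination: bool = True,
        p_remove: float = P_REMOVE,
        min_admissions: int = MIN_ADMISSIONS,
        min_events: int = MIN_EVENTS,
        terms: Optional[list[Term]] = None,
    ) -> None:
        mask, y = outcome_series(records, outcome)
        df = records.loc[mask]
        if group is not None:
            sel = df["group"] == group
            df = df.loc[sel]
        self.records = df
        self.y = y.loc[df.index].to_numpy(dtype=float)
        self.outcome = outcome
        self.group = group
        self.elimination = elimination
        self.p_remove = p_remove
        self.min_admissions = min_admissions
        self.min_events = min_events
        if terms is not None:
            self.terms = list(terms)
        else:
            include_year = records["year"].nunique() > 1
            self.terms = casemix_terms(
                include_year=include_year,
                include_group=include_group_term and group is None,
                interactions=interactions,
            )

    # ------------------------------------------------------------------ #

    def _intercept_only(self, reason: str) -> CaseMixResults:
        n = len(self.y)
        events = int(self.y.sum())
        if 0 < events < n:
            b0 = float(logit(events / n))
            converged = True
        else:
            # Haldane-style adjustment: all-or-none events cannot be ML-fitted
            b0 = float(logit((events + 0.5) / (n + 1.0)))
            converged = False
            warnings.warn(
                f"case-mix model ({self.outcome}, {self.group}): {reason}; "
                "intercept-only fit with continuity adjustment",
                stacklevel=2,
            )
        return CaseMixResults(
            outcome=self.outcome,
            group=self.group,
            retained_terms=["Intercept"],
            coefficients={"Intercept": b0},
            age_merge_map={lev: lev for lev in AGE_GROUPS},
            design_info=None,
            params=np.array([b0]),
            cov=None,
            llf=float(
                events * np.log(max(events / n, 1e-12))
                + (n - events) * np.log(max(1 - events / n, 1e-12))
            ) if 0 < events < n else 0.0,
            n=n,
            n_events=events,
            converged=converged,
            penalized=False,
            intercept_only=True,
        )

    def fit(self) -> CaseMixResults:
        n = len(self.y)
        events = int(self.y.sum())
        if n < self.min_admissions:
            return self._intercept_only(f"fewer than {self.min_admissions} admissions")
        if events < self.min_events or n - events < self.min_events:
            return self._intercept_only("too few events (or non-events)")
        if not self.terms:
            return self._intercept_only("no candidate terms supplied")

        merge_map = merge_sparse_age_groups(
            self.records["age_group"], pd.Series(self.y, index=self.records.index),
            min_events=self.min_events,
        )

        terms = list(self.terms)
        fit: _LogitFit
        info: DesignInfo
        while True:
            X, info = build_design(self.records, terms, age_merge_map=merge_map)
            # drop terms that contributed no columns (single observed level)
            empty = [t for t in terms if t.name not in info.term_slices]
            if empty:
                terms = [t for t in terms if t.name in info.term_slices]
                if not terms:
                    return self._intercept_only("no informative terms")
                continue
            fit = _fit_logit(X, self.y)
            if not self.elimination:
                break
            pvals = {
                t.name: _wald_term_p(fit, info.term_slices[t.name]) for t in terms
            }
            protected = set()
            for t in terms:
                protected.update(interaction_parents(t))
            candidates = [
                t for t in terms
                if pvals[t.name] >= self.p_remove and t.name not in protected
            ]
            if not candidates:
                break
            # drop the single worst term; ties broken by reverse-alphabetical name
            worst = max(candidates, key=lambda t: (pvals[t.name], t.name))
            terms = [t for t in terms if t is not worst]
            if not terms:
                X, info = build_design(self.records, [], age_merge_map=merge_map)
                fit = _fit_logit(X, self.y)
                break

        term_pvalues = {
            t.name: _wald_term_p(fit, info.term_slices[t.name]) for t in terms
        }
        coefficients = dict(zip(info.column_names, fit.params.tolist()))
        return CaseMixResults(
            outcome=self.outcome,
            group=self.group,
            retained_terms=["Intercept"] + [t.name for t in terms],
            coefficients=coefficients,
            age_merge_map=merge_map,
            design_info=info,
            params=fit.params,
            cov=fit.cov,
            llf=fit.llf,
            n=n,
            n_events=events,
            converged=fit.converged,
            penalized=fit.penalized,
            intercept_only=len(terms) == 0,
        )


# --------------------------------------------------------------------------- #
# Convenience drivers
# --------------------------------------------------------------------------- #

def fit_casemix_models(
    records: pd.DataFrame,
    outcomes: Sequence[str] = OUTCOMES,
    per_group: bool = True,
    elimination: bool = True,
    interactions: bool = True,
) -> dict[tuple[str, Optional[str]], CaseMixResults]:
    """Fit case-mix models for every (outcome, group) combination.

    With ``per_group=False`` a single pooled model per outcome is fitted with
    ``group`` as an (eliminable) categorical covariate.
    """
    models: dict[tuple[str, Optional[str]], CaseMixResults] = {}
    groups = sorted(records["group"].unique()) if per_group else [None]
    for outcome in outcomes:
        for grp in groups:
            model = CaseMixLogit(
                records,
                outcome,
                group=grp,
                include_group_term=not per_group,
                elimination=elimination,
                interactions=interactions,
            )
            models[(outcome, grp)] = model.fit()
    return models


def expected_probabilities(
    models: dict[tuple[str, Optional[str]], CaseMixResults],
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Per-record expected probability for each outcome.

    Readmission / long-LOS probabilities are NaN for in-hospital deaths
    (undefined denominators).
    """
    out = pd.DataFrame(index=records.index)
    outcomes = sorted({k[0] for k in models})
    per_group = any(k[1] is not None for k in models)
    for outcome in outcomes:
        p = pd.Series(np.nan, index=records.index)
        mask, _ = outcome_series(
            records if "long_los" in records.columns or outcome != "long_los"
            else records.assign(long_los=0),
            outcome,
        )
        if per_group:
            for (oc, grp), res in models.items():
                if oc != outcome or grp is None:
                    continue
                sel = mask & (records["group"] == grp)
                if sel.any():
                    p.loc[sel] = res.predict(records.loc[sel])
        else:
            res = models[(outcome, None)]
            if mask.any():
                p.loc[mask] = res.predict(records.loc[mask])
        out[outcome] = p
    return out
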