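"""Rankability: how much of the between-hospital variation is signal.

Rankability combines (1) tau2, the variance of random hospital effects from a
random-intercept fit, with (2) the median squared standard error of the
per-hospital estimates from the matching fixed-effects fit:

    rankability (%) = 100 * tau2 / (tau2 + median sigma2).

It is a property of the *set* of hospitals being compared: the share of
observed between-hospital spread attributable to true differences rather than
estimation noise.

tau2 is estimated by maximum likelihood with Gauss-Hermite quadrature (binary
and ordinal outcomes); a DerSimonian-Laird moments estimator on the
fixed-effect coefficients serves as fallback and cross-check.  Case-mix
adjustment enters both the random- and fixed-effects fits through a shared
per-record offset (the case-mix linear predictor), keeping tau2 and sigma2 on
the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logit
from .casemix import outcome_series
from .composite import assign_composite_level

__all__ = [
    "RankabilityResult",
    "RandomInterceptLogit",
    "RandomInterceptOrdinal",
    "estimate_tau2_random_effects",
    "estimate_tau2_moments",
    "hospital_fixed_effects_logit",
    "median_sigma2",
    "rankability",
    "rankability_analysis",
]


@dataclass(frozen=True)
class RankabilityResult:
    outcome: str
    tau2: float
    median_sigma2: float
    rankability: float          # percentage in [0, 100]
    estimation_method: str      # quadrature | moments


def rankability(tau2: float, median_sigma2: float) -> float:
    """100 * tau2 / (tau2 + median sigma2)."""
    if median_sigma2 <= 0:
        raise ValueError("median_sigma2 must be > 0")
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    return 100.0 * tau2 / (tau2 + median_sigma2)


def median_sigma2(ses: Sequence[float], exclude: Optional[Sequence[bool]] = None) -> float:
    """Median of squared standard errors.

    ``exclude`` masks entries that are coding artifacts (e.g. the reference
    hospital's identically-zero SE in a dummy-coded fit).
    """
    ses = np.asarray(ses, dtype=float)
    if exclude is not None:
        ses = ses[~np.asarray(exclude, dtype=bool)]
    if ses.size == 0:
        raise ValueError("no standard errors left after exclusion")
    return float(np.median(ses ** 2))


# --------------------------------------------------------------------------- #
# Moments (DerSimonian-Laird) estimator
# --------------------------------------------------------------------------- #

def estimate_tau2_moments(betas: Sequence[float], ses: Sequence[float]) -> float:
    """DerSimonian-Laird between-hospital variance, truncated at zero.

    Operates on (centered) fixed-effect hospital coefficients with their
    standard errors; inverse-variance weights.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 hospitals")
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise ValueError("standard errors must be finite and non-negative")
    s = np.maximum(s, 1e-8)
    w = 1.0 / s ** 2
    mu = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - mu) ** 2))
    denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (Q - (b.size - 1)) / denom)


# --------------------------------------------------------------------------- #
# Fixed-effects logistic per hospital (offset parameterization)
# --------------------------------------------------------------------------- #

def hospital_fixed_effects_logit(
    y: np.ndarray,
    hospital: np.ndarray,
    offset: Optional[np.ndarray] = None,
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Hospital fixed-effect logistic fit, dummy-coded against a reference.

    The model is logit P(y=1) = alpha_h + offset; each hospital's own
    intercept is solved by scalar Newton iteration (the per-hospital profile
    likelihoods separate given the offset).  Reported coefficients are
    contrasts versus the reference hospital (largest volume by default), with
    contrast standard errors — the same convention as the hospital dummies in
    the ordinal fixed-effects fit, so the two median-sigma2 values are
    comparable.  The reference row has coef 0 and se 0 by construction.
    All-events / no-events hospitals get a continuity-adjusted estimate and
    are flagged.
    """
    y = np.asarray(y, dtype=float)
    hospital = np.asarray(hospital)
    off = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    own = []
    for hid in pd.unique(hospital):
        sel = hospital == hid
        yi, oi = y[sel], off[sel]
        n, e = yi.size, yi.sum()
        adjusted = False
        if e == 0 or e == n:
            b = float(logit((e + 0.5) / (n + 1.0)) - oi.mean())
            adjusted = True
        else:
            b = float(logit(e / n) - oi.mean())
            for _ in range(50):
                p = expit(b + oi)
                g = e - p.sum()
                h = np.sum(p * (1 - p))
                step = g / max(h, 1e-12)
                b += step
                if abs(step) < 1e-10:
                    break
        p = expit(b + oi)
        info = float(np.sum(p * (1 - p)))
        own.append({"hospital_id": hid, "alpha": b,
                    "var_own": 1.0 / max(info, 1e-12), "n": n,
                    "events": int(e), "adjusted": adjusted})
    df = pd.DataFrame(own)
    if reference is None:
        reference = df.loc[df["n"].idxmax(), "hospital_id"]
    ref_row = df.loc[df["hospital_id"] == reference]
    if ref_row.empty:
        raise ValueError(f"reference hospital {reference!r} not in data")
    a_ref = float(ref_row["alpha"].iloc[0])
    v_ref = float(ref_row["var_own"].iloc[0])
    is_ref = (df["hospital_id"] == reference).to_numpy()
    coef = df["alpha"].to_numpy() - a_ref
    se = np.sqrt(df["var_own"].to_numpy() + v_ref)
    coef[is_ref] = 0.0
    se[is_ref] = 0.0
    return pd.DataFrame(
        {
            "hospital_id": df["hospital_id"],
            "coef": coef,
            "se": se,
            "n": df["n"],
            "events": df["events"],
            "adjusted": df["adjusted"],
            "is_reference": is_ref,
        }
    )


# --------------------------------------------------------------------------- #
# Random-intercept models (Gauss-Hermite quadrature)
# --------------------------------------------------------------------------- #

def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw Gauss-Hermite nodes/log-weights for adaptive quadrature."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x, np.log(w)


@dataclass
class RandomInterceptResults:
    tau2: float
    intercept: float
    extra: np.ndarray           # model-specific fixed parameters
    llf: float
    converged: bool
    method: str


class _AdaptiveQuadratureMixin:
    """Adaptive Gauss-Hermite integration over the hospital random intercept.

    Subclasses provide ``_ell_vec(u, par)`` -> (per-hospital conditional
    loglik, gradient, curvature) for a vector ``u`` of length H, and
    ``_ell_mat(U, par)`` -> loglik matrix for node points ``U`` (H x J).
    Nodes are recentred and rescaled at each hospital's posterior mode
    (Laplace point), which keeps the quadrature accurate even when the
    per-hospital likelihood is much narrower than the random-effect prior.
    """

    n_nodes: int
    _mode_cache: Optional[np.ndarray] = None

    def _marginal_loglik(self, tau: float, par) -> float:
        tau = max(abs(tau), 1e-6)
        inv_t2 = 1.0 / tau ** 2
        H = self.n_groups
        u = (self._mode_cache.copy() if self._mode_cache is not None
             else np.zeros(H))
        for _ in range(50):
            _, g, c = self._ell_vec(u, par)
            psi_g = g - u * inv_t2
            psi_c = c - inv_t2          # strictly negative
            step = psi_g / psi_c
            step = np.clip(step, -1.0, 1.0)
            u = u - step
            if np.max(np.abs(step)) < 1e-9:
                break
        ell, g, c = self._ell_vec(u, par)
        self._mode_cache = u
        sigma = 1.0 / np.sqrt(np.maximum(-(c - inv_t2), 1e-12))
        x, logw = _gh_nodes(self.n_nodes)
        U = u[:, None] + np.sqrt(2.0) * sigma[:, None] * x[None, :]
        ell_mat = self._ell_mat(U, par)
        logf = (
            ell_mat
            - 0.5 * U ** 2 * inv_t2
            - np.log(tau)
            - 0.5 * np.log(2.0 * np.pi)
        )
        terms = logw[None, :] + x[None, :] ** 2 + logf
        m = terms.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(terms - m).sum(axis=1))
        return float(np.sum(lse + 0.5 * np.log(2.0) + np.log(sigma)))


class RandomInterceptLogit(_AdaptiveQuadratureMixin):
    """Logistic regression with a normal random hospital intercept.

    logit P(y=1 | hospital h) = mu + offset_i + u_h,  u_h ~ N(0, tau2).
    Marginal ML over (mu, tau) by adaptive Gauss-Hermite quadrature.
    """

    def __init__(self, y, hospital, offset=None, n_nodes: int = 15) -> None:
        y = np.asarray(y, dtype=float)
        hospital = np.asarray(hospital)
        order = np.argsort(hospital, kind="stable")
        self.y = y[order]
        self.offset = (
            np.zeros_like(self.y) if offset is None
            else np.asarray(offset, dtype=float)[order]
        )
        hs = hospital[order]
        _, starts = np.unique(hs, return_index=True)
        self.starts = np.sort(starts)
        self.n_groups = self.starts.size
        if self.n_groups < 2:
            raise ValueError("tau2 is undefined with a single hospital")
        self.n_nodes = n_nodes
        self._mode_cache = None
        self.n_h = np.diff(np.append(self.starts, self.y.size)).astype(float)
        self.e_h = np.add.reduceat(self.y, self.starts)
        self.constant_offset = bool(np.allclose(self.offset, self.offset[0]))

    def _ell_vec(self, u, par):
        mu = par[0]
        if self.constant_offset:
            p = expit(mu + self.offset[0] + u)
            ell = self.e_h * np.log(np.maximum(p, 1e-300)) + (
                self.n_h - self.e_h
            ) * np.log(np.maximum(1 - p, 1e-300))
            grad = self.e_h - self.n_h * p
            curv = -self.n_h * p * (1 - p)
            return ell, grad, curv
        hosp_idx = self._hosp_idx()
        lp = mu + self.offset + u[hosp_idx]
        li = np.where(self.y == 1.0, log_expit(lp), log_expit(-lp))
        p = expit(lp)
        ell = np.add.reduceat(li, self.starts)
        grad = np.add.reduceat(self.y - p, self.starts)
        curv = -np.add.reduceat(p * (1 - p), self.starts)
        return ell, grad, curv

    def _ell_mat(self, U, par):
        mu = par[0]
        if self.constant_offset:
            lp = mu + self.offset[0] + U
            return self.e_h[:, None] * log_expit(lp) + (
                self.n_h - self.e_h
            )[:, None] * log_expit(-lp)
        hosp_idx = self._hosp_idx()
        lp = mu + self.offset[:, None] + U[hosp_idx, :]
        li = np.where(self.y[:, None] == 1.0, log_expit(lp), log_expit(-lp))
        return np.add.reduceat(li, self.starts, axis=0)

    def _hosp_idx(self):
        if not hasattr(self, "_hidx"):
            self._hidx = (
                np.searchsorted(self.starts, np.arange(self.y.size), side="right") - 1
            )
        return self._hidx

    def fit(self) -> RandomInterceptResults:
        rate = np.clip(self.y.mean(), 1e-6, 1 - 1e-6)
        x0 = np.array([logit(rate) - self.offset.mean(), 0.3])

        def nll(x):
            return -self._marginal_loglik(x[1], x[:1])

        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
        mu, tau = res.x[0], abs(res.x[1])
        return RandomInterceptResults(
            tau2=float(tau ** 2),
            intercept=float(mu),
            extra=np.zeros(0),
            llf=-float(res.fun),
            converged=bool(res.success),
            method="quadrature",
        )


class RandomInterceptOrdinal(_AdaptiveQuadratureMixin):
    """Cumulative-logit model with a normal random hospital intercept.

    P(Y <= k | h) = logistic(theta_k - offset_i - u_h), u_h ~ N(0, tau2);
    marginal ML over (thresholds, tau) by adaptive Gauss-Hermite quadrature.
    """

    def __init__(self, levels, hospital, offset=None, n_levels=None,
                 n_nodes: int = 15) -> None:
        levels = np.asarray(levels, dtype=int)
        observed = np.unique(levels)
        if observed.size < 2:
            raise ValueError("need at least 2 distinct levels")
        remap = {int(v): i + 1 for i, v in enumerate(observed)}
        self.levels = np.array([remap[int(v)] for v in levels])
        self.K = observed.size
        hospital = np.asarray(hospital)
        order = np.argsort(hospital, kind="stable")
        self.levels = self.levels[order]
        self.offset = (
            np.zeros(levels.size) if offset is None
            else np.asarray(offset, dtype=float)[order]
        )
        hs = hospital[order]
        _, starts = np.unique(hs, return_index=True)
        self.starts = np.sort(starts)
        self.n_groups = self.starts.size
        if self.n_groups < 2:
            raise ValueError("tau2 is undefined with a single hospital")
        self.n_nodes = n_nodes
        self._mode_cache = None
        self.constant_offset = bool(np.allclose(self.offset, self.offset[0]))
        self.hosp_idx = (
            np.searchsorted(self.starts, np.arange(self.levels.size), side="right") - 1
        )
        if self.constant_offset:
            self.counts = np.zeros((self.n_groups, self.K))
            np.add.at(self.counts, (self.hosp_idx, self.levels - 1), 1.0)

    def _record_logp_grad(self, shift):
        """Per-record log p and d log p / d shift, where the record's linear
        shift (offset + u) is subtracted from every threshold."""
        thetas = self._thetas
        th = np.concatenate([[-np.inf], thetas, [np.inf]])
        upper = th[self.levels] - shift
        lower = th[self.levels - 1] - shift
        Fu = np.where(np.isinf(upper), 1.0,
                      expit(np.where(np.isinf(upper), 0.0, upper)))
        Fl = np.where(np.isinf(lower), 0.0,
                      expit(np.where(np.isinf(lower), 0.0, lower)))
        P = np.maximum(Fu - Fl, 1e-300)
        fu = np.where(np.isinf(upper), 0.0, Fu * (1 - Fu))
        fl = np.where(np.isinf(lower), 0.0, Fl * (1 - Fl))
        return np.log(P), (fl - fu) / P

    def _cell_ell_grad(self, u, thetas):
        """(ell, grad) per hospital from level-count sufficient statistics."""
        th = np.concatenate([[-np.inf], thetas, [np.inf]])
        a = th[:, None] - self.offset[0] - u[None, :]        # (K+1, H)
        F = np.where(np.isinf(a), (a > 0).astype(float),
                     expit(np.where(np.isinf(a), 0.0, a)))
        f = np.where(np.isinf(a), 0.0, F * (1 - F))
        P = np.maximum(F[1:] - F[:-1], 1e-300)               # (K, H)
        logp = np.log(P)
        dlogp = (f[:-1] - f[1:]) / P
        ell = np.einsum("hk,kh->h", self.counts, logp)
        grad = np.einsum("hk,kh->h", self.counts, dlogp)
        return ell, grad

    def _ell_vec(self, u, par):
        self._thetas = par
        eps = 1e-4
        if self.constant_offset:
            ell, grad = self._cell_ell_grad(u, par)
            _, g_hi = self._cell_ell_grad(u + eps, par)
            _, g_lo = self._cell_ell_grad(u - eps, par)
            curv = np.minimum((g_hi - g_lo) / (2 * eps), -1e-10)
            return ell, grad, curv
        shift = self.offset + u[self.hosp_idx]
        logp, dlogp = self._record_logp_grad(shift)
        ell = np.add.reduceat(logp, self.starts)
        grad = np.add.reduceat(dlogp, self.starts)
        # curvature via symmetric difference of the analytic gradient
        _, d_hi = self._record_logp_grad(shift + eps)
        _, d_lo = self._record_logp_grad(shift - eps)
        curv = np.add.reduceat((d_hi - d_lo) / (2 * eps), self.starts)
        curv = np.minimum(curv, -1e-10)
        return ell, grad, curv

    def _ell_mat(self, U, par):
        self._thetas = par
        thetas = par
        th = np.concatenate([[-np.inf], thetas, [np.inf]])
        if self.constant_offset:
            # (K, H, J) cell log-probabilities; H and J are small
            a_u = th[1:][:, None, None] - self.offset[0] - U[None, :, :]
            a_l = th[:-1][:, None, None] - self.offset[0] - U[None, :, :]
            Fu = np.where(np.isinf(a_u), 1.0,
                          expit(np.where(np.isinf(a_u), 0.0, a_u)))
            Fl = np.where(np.isinf(a_l), 0.0,
                          expit(np.where(np.isinf(a_l), 0.0, a_l)))
            logp = np.log(np.maximum(Fu - Fl, 1e-300))
            return np.einsum("hk,khj->hj", self.counts, logp)
        upper = th[self.levels][:, None] - self.offset[:, None] - U[self.hosp_idx, :]
        lower = th[self.levels - 1][:, None] - self.offset[:, None] - U[self.hosp_idx, :]
        Fu = np.where(np.isinf(upper), 1.0,
                      expit(np.where(np.isinf(upper), 0.0, upper)))
        Fl = np.where(np.isinf(lower), 0.0,
                      expit(np.where(np.isinf(lower), 0.0, lower)))
        logp = np.log(np.maximum(Fu - Fl, 1e-300))
        return np.add.reduceat(logp, self.starts, axis=0)

    def fit(self) -> RandomInterceptResults:
        freq = np.bincount(self.levels, minlength=self.K + 1)[1:]
        cum = np.clip(np.cumsum(freq)[:-1] / freq.sum(), 1e-4, 1 - 1e-4)
        theta0 = np.maximum.accumulate(logit(cum))
        for i in range(1, theta0.size):
            if theta0[i] <= theta0[i - 1]:
                theta0[i] = theta0[i - 1] + 1e-3
        x0 = np.concatenate([[theta0[0]],
                             np.log(np.maximum(np.diff(theta0), 1e-4)),
                             [0.3]])

        def unpack(x):
            th = np.empty(self.K - 1)
            th[0] = x[0]
            if self.K > 2:
                th[1:] = x[0] + np.cumsum(np.exp(x[1: self.K - 1]))
            return th, abs(x[-1])

        def nll(x):
            th, tau = unpack(x)
            return -self._marginal_loglik(tau, th)

        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000})
        th, tau = unpack(res.x)
        return RandomInterceptResults(
            tau2=float(tau ** 2),
            intercept=float(th[0]),
            extra=th,
            llf=-float(res.fun),
            converged=bool(res.success),
            method="quadrature",
        )


# --------------------------------------------------------------------------- #
# High-level drivers
# --------------------------------------------------------------------------- #

def estimate_tau2_random_effects(
    records: pd.DataFrame,
    outcome: str,
    offset: Optional[pd.Series] = None,
    n_nodes: int = 31,
) -> RandomInterceptResults:
    """tau2 for one outcome (binary or ``composite``) via quadrature ML.

    ``offset`` is a per-record case-mix linear predictor (log-odds scale); the
    random-intercept model then estimates the residual between-hospital
    variance.  Falls back to the moments estimator only on failure.
    """
    if outcome == "composite":
        levels = (
            records["composite_level"].to_numpy()
            if "composite_level" in records.columns
            else assign_composite_level(
                records["died"], records["long_los"], records["readmitted_30d"]
            )
        )
        off = None if offset is None else offset.to_numpy(dtype=float)
        model = RandomInterceptOrdinal(
            levels, records["hospital_id"].to_numpy(), offset=off, n_nodes=n_nodes
        )
        return model.fit()
    mask, y = outcome_series(records, outcome)
    sub = records.loc[mask]
    off = None if offset is None else offset.loc[sub.index].to_numpy(dtype=float)
    model = RandomInterceptLogit(
        y.loc[sub.index].to_numpy(dtype=float),
        sub["hospital_id"].to_numpy(),
        offset=off,
        n_nodes=n_nodes,
    )
    return model.fit()


def rankability_analysis(
    records: pd.DataFrame,
    outcomes: Sequence[str] = ("mortality", "readmission", "long_los", "composite"),
    casemix_offsets: Optional[pd.DataFrame] = None,
    ordinal_results=None,
    n_nodes: int = 31,
) -> list[RankabilityResult]:
    """Rankability per outcome definition.

    Binary outcomes: tau2 from the quadrature random-intercept fit and
    median sigma2 from per-hospital fixed-effect logits (both using the
    case-mix linear predictor as offset when ``casemix_offsets`` provides a
    column for the outcome).  Composite: tau2 from the ordinal
    random-intercept fit; sigma2 from the hospital fixed-effects
    proportional-odds fit (``ordinal_results``; required for composite),
    the reference hospital's artifactual zero SE excluded from the median.
    """
    out: list[RankabilityResult] = []
    for outcome in outcomes:
        if outcome == "composite":
            if ordinal_results is None:
                raise ValueError("composite rankability needs ordinal_results")
            re_fit = estimate_tau2_random_effects(records, "composite",
                                                  n_nodes=n_nodes)
            tau2 = re_fit.tau2
            eff = ordinal_results.hospital_effects
            exclude = (eff["hospital_id"] == ordinal_results.reference).to_numpy()
            ms2 = median_sigma2(eff["se"].to_numpy(), exclude=exclude)
            method = re_fit.method
        else:
            offset = None
            if casemix_offsets is not None and outcome in casemix_offsets:
                offset = casemix_offsets[outcome]
            re_fit = estimate_tau2_random_effects(records, outcome, offset=offset,
                                                  n_nodes=n_nodes)
            tau2 = re_fit.tau2
            mask, y = outcome_series(records, outcome)
            sub = records.loc[mask]
            off = (
                None if offset is None
                else offset.loc[sub.index].to_numpy(dtype=float)
            )
            fe = hospital_fixed_effects_logit(
                y.loc[sub.index].to_numpy(dtype=float),
                sub["hospital_id"].to_numpy(),
                offset=off,
            )
            ms2 = median_sigma2(fe["se"].to_numpy(),
                                exclude=fe["is_reference"].to_numpy())
            method = re_fit.method
        out.append(
            RankabilityResult(
                outcome=outcome,
                tau2=tau2,
                median_sigma2=ms2,
                rankability=rankability(tau2, ms2),
                estimation_method=method,
            )
        )
    return out
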