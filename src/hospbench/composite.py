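"""The 5-level ordinal composite outcome and its hospital standardization.

Levels, best to worst:

1. alive, no long LOS, no readmission
2. alive, long LOS, no readmission
3. alive, no long LOS, readmission
4. alive, long LOS, readmission
5. in-hospital death (regardless of LOS/readmission)

The composite is analysed with a cumulative-logit proportional-odds model
containing the case-mix variables and hospital as a fixed effect (one
reference hospital at 0).  Standardizing a hospital means centering its
coefficient on the unweighted mean of all hospital coefficients (the
reference's 0 included) and exponentiating:
``rate = 100 * exp(beta_h - mean(beta))``, an odds ratio versus the average
hospital, so the geometric mean of rate/100 across hospitals is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import DesignInfo, build_design, casemix_terms
from .ordinal import ProportionalOddsFit, fit_proportional_odds

__all__ = [
    "assign_composite_level",
    "HospitalOrdinalModel",
    "HospitalOrdinalResults",
    "fit_ordinal_model",
    "standardized_composite_rate",
]

N_LEVELS = 5


def assign_composite_level(died, long_los, readmitted) -> np.ndarray:
    """Vectorized composite level assignment (death dominates everything)."""
    died = np.asarray(died, dtype=bool)
    long_los = np.asarray(long_los, dtype=bool)
    # readmitted may carry missing values for deaths; treat them as False,
    # the death branch wins anyway
    readm = pd.array(readmitted)
    if hasattr(readm, "fillna"):
        readm = readm.fillna(0)
    readmitted = np.asarray(readm, dtype=float) > 0
    level = np.ones(died.shape, dtype=np.int64)
    level[~died & long_los & ~readmitted] = 2
    level[~died & ~long_los & readmitted] = 3
    level[~died & long_los & readmitted] = 4
    level[died] = 5
    return level


# --------------------------------------------------------------------------- #
# Hospital fixed-effects ordinal model
# --------------------------------------------------------------------------- #

@dataclass
class HospitalOrdinalResults:
    """Proportional-odds fit with per-hospital fixed effects.

    ``hospital_effects`` has one row per hospital (coef, se); the reference
    hospital carries coef 0 with se 0 by construction.
    """

    thresholds: np.ndarray
    hospital_effects: pd.DataFrame       # hospital_id, coef, se
    reference: str
    casemix_coefficients: dict[str, float]
    fit: ProportionalOddsFit
    hospital_cols: list[int]             # beta indices of the hospital dummies
    n_levels: int
    level_map: dict[int, int]            # observed level -> internal code

    @property
    def llf(self) -> float:
        return self.fit.llf

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def penalized(self) -> bool:
        return self.fit.penalized

    # -- standardization ------------------------------------------------- #

    def centered_effects(self) -> pd.DataFrame:
        """Hospital effects centered on the unweighted all-hospital mean,
        with delta-method standard errors (the reference included at 0)."""
        eff = self.hospital_effects
        coefs = eff["coef"].to_numpy()
        H = len(coefs)
        centered = coefs - coefs.mean()
        ses = np.full(H, np.nan)
        bcov = self.fit.beta_cov()
        if bcov is not None:
            # embed the reference's zero row/col, then Var(A b), A = I - J/H
            V = np.zeros((H, H))
            non_ref = [i for i, hid in enumerate(eff["hospital_id"])
                       if hid != self.reference]
            idx = np.array(self.hospital_cols, dtype=int)
            sub = bcov[np.ix_(idx, idx)]
            for a, i in enumerate(non_ref):
                for b, j in enumerate(non_ref):
                    V[i, j] = sub[a, b]
            A = np.eye(H) - np.full((H, H), 1.0 / H)
            Vc = A @ V @ A.T
            ses = np.sqrt(np.maximum(np.diag(Vc), 0.0))
        return pd.DataFrame(
            {
                "hospital_id": eff["hospital_id"].to_numpy(),
                "effect": centered,
                "se": ses,
            }
        )

    def standardized_rates(self) -> pd.DataFrame:
        """100 * exp(beta_h - mean(beta)); geometric mean of rate/100 is 1."""
        cent = self.centered_effects()
        return pd.DataFrame(
            {
                "hospital_id": cent["hospital_id"],
                "rate": 100.0 * np.exp(cent["effect"].to_numpy()),
            }
        )

    def summary(self) -> str:
        lines = [
            "Proportional-odds composite model with hospital fixed effects",
            f"  n={self.fit.n_obs:.0f}  levels={self.n_levels}"
            f"  log-likelihood={self.llf:.3f}  converged={self.converged}"
            f"  penalized={self.penalized}",
            "  thresholds: "
            + ", ".join(f"{t:+.4f}" for t in self.thresholds),
            f"  reference hospital: {self.reference}",
            f"  {'hospital':<12s}{'coef':>10s}{'se':>10s}{'std.rate':>10s}",
        ]
        rates = self.standardized_rates().set_index("hospital_id")["rate"]
        for _, row in self.hospital_effects.iterrows():
            lines.append(
                f"  {row['hospital_id']:<12s}{row['coef']:>10.4f}"
                f"{row['se']:>10.4f}{rates[row['hospital_id']]:>10.1f}"
            )
        if self.casemix_coefficients:
            lines.append("  case-mix coefficients:")
            for name, val in self.casemix_coefficients.items():
                lines.append(f"    {name:<30s}{val:>10.4f}")
        return "\n".join(lines)


class HospitalOrdinalModel:
    """Cumulative-logit model of the composite with hospital fixed effects.

    The reference hospital (coefficient fixed at 0) is the largest-volume
    hospital for numerical stability; the centering used by
    :meth:`HospitalOrdinalResults.standardized_rates` makes the choice
    immaterial.  With no case-mix terms the data are aggregated to
    (hospital, level) sufficient statistics before fitting.

    Under monotone likelihood (a hospital with all-best or all-worst
    outcomes) the fit is retried with a small ridge penalty on the
    coefficients and flagged as penalized.
    """

    RIDGE_FALLBACK = 1e-3

    def __init__(
        self,
        records: pd.DataFrame,
        levels: Optional[Sequence[int]] = None,
        casemix: bool | Sequence = False,
        reference: Optional[str] = None,
    ) -> None:
        if levels is None:
            if "composite_level" in records.columns:
                levels = records["composite_level"].to_numpy()
            else:
                levels = assign_composite_level(
                    records["died"], records["long_los"], records["readmitted_30d"]
                )
        self.records = records
        self.levels = np.asarray(levels, dtype=int)
        if len(self.records) != self.levels.size:
            raise ValueError("levels and records length mismatch")
        volumes = records.groupby("hospital_id", observed=True).size()
        if len(volumes) < 2:
            raise ValueError("need at least 2 hospitals")
        if reference is None:
            reference = volumes.idxmax()
        self.reference = str(reference)
        self.hospital_ids = sorted(volumes.index.astype(str))
        if casemix is True:
            self.terms = casemix_terms(
                include_year=records["year"].nunique() > 1,
                include_group=records["group"].nunique() > 1,
                interactions=False,
            )
        elif casemix:
            self.terms = list(casemix)
        else:
            self.terms = []

    def fit(self, ridge: float = 0.0) -> HospitalOrdinalResults:
        observed = np.unique(self.levels)
        if observed.size < 2:
            raise ValueError("need at least 2 distinct composite levels")
        level_map = {int(lev): i + 1 for i, lev in enumerate(observed)}
        y = np.array([level_map[int(v)] for v in self.levels])
        K = observed.size

        others = [h for h in self.hospital_ids if h != self.reference]
        hosp = self.records["hospital_id"].astype(str).to_numpy()
        Xh = np.column_stack([(hosp == h).astype(float) for h in others])

        design_info: Optional[DesignInfo] = None
        if self.terms:
            Xcm, design_info = build_design(self.records, self.terms, intercept=False)
            X = np.column_stack([Xh, Xcm])
            weights = None
        else:
            # aggregate to (hospital, level) sufficient statistics
            df = pd.DataFrame({"h": hosp, "y": y})
            agg = df.groupby(["h", "y"], observed=True).size().reset_index(name="w")
            Xh = np.column_stack(
                [(agg["h"].to_numpy() == h).astype(float) for h in others]
            )
            X = Xh
            y = agg["y"].to_numpy()
            weights = agg["w"].to_numpy(dtype=float)

        fit = fit_proportional_odds(X, y, n_levels=K, weights=weights, ridge=ridge)
        if not fit.converged or not np.all(np.isfinite(fit.beta)) or (
            fit.beta.size and np.max(np.abs(fit.beta[: len(others)])) > 15.0
        ):
            if ridge == 0.0:
                fit = fit_proportional_odds(
                    X, y, n_levels=K, weights=weights, ridge=self.RIDGE_FALLBACK
                )
        if not fit.converged:
            raise RuntimeError(
                "proportional-odds fit failed to converge "
                f"(n={len(y)}, K={K}); diagnostics: iterations={fit.n_iter}"
            )

        n_h = len(others)
        beta_se = fit.beta_se()
        coefs = {self.reference: 0.0}
        ses = {self.reference: 0.0}
        for i, h in enumerate(others):
            coefs[h] = float(fit.beta[i])
            ses[h] = float(beta_se[i]) if beta_se is not None else np.nan
        eff = pd.DataFrame(
            {
                "hospital_id": self.hospital_ids,
                "coef": [coefs[h] for h in self.hospital_ids],
                "se": [ses[h] for h in self.hospital_ids],
            }
        )
        casemix_coefficients = {}
        if design_info is not None:
            for j, name in enumerate(design_info.column_names):
                casemix_coefficients[name] = float(fit.beta[n_h + j])
        return HospitalOrdinalResults(
            thresholds=fit.thresholds,
            hospital_effects=eff,
            reference=self.reference,
            casemix_coefficients=casemix_coefficients,
            fit=fit,
            hospital_cols=list(range(n_h)),
            n_levels=K,
            level_map=level_map,
        )


def fit_ordinal_model(
    records: pd.DataFrame,
    levels: Optional[Sequence[int]] = None,
    casemix: bool | Sequence = False,
    reference: Optional[str] = None,
) -> HospitalOrdinalResults:
    """Functional wrapper around :class:`HospitalOrdinalModel`."""
    return HospitalOrdinalModel(records, levels=levels, casemix=casemix,
                                reference=reference).fit()


def standardized_composite_rate(hospital_coefficients: dict[str, float]) -> dict[str, float]:
    """100 * exp(beta_h - unweighted mean of all hospital coefficients)."""
    vals = np.array(list(hospital_coefficients.values()), dtype=float)
    mean = vals.mean()
    return {h: 100.0 * float(np.exp(b - mean))
            for h, b in hospital_coefficients.items()}
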