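"""End-to-end analysis: simulate -> case-mix -> standardize -> composite -> rank.

:func:`run_full_analysis` executes every stage with shared settings and
returns a :class:`ReportBundle` whose tables mirror the standard report
surfaces of a hospital-profiling study: per-hospital crude composite
distributions, standardized-ratio summaries, patient-level OR tables, the
hospital-level correlation matrix, the rankability table and a
calendar-period comparison.  Every number in the bundle is recomputable from
the cohort records alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from importlib.metadata import version as _pkg_version
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import chi2_contingency

from . import standardize as stdz
from .casemix import expected_probabilities, fit_casemix_models
from .composite import HospitalOrdinalModel, assign_composite_level
from .config import ScenarioConfig
from .rankability import (
    RankabilityResult,
    estimate_tau2_moments,
    rankability_analysis,
)
from .simulate import generate_cohort

__all__ = ["ReportBundle", "run_full_analysis", "composite_distribution_table",
           "compare_periods"]

logger = logging.getLogger("hospbench")


@dataclass
class ReportBundle:
    """All report surfaces of one full analysis run."""

    ratios: pd.DataFrame                  # hospital x outcome O/E table
    ratio_summary: pd.DataFrame           # median / IQR per outcome
    patient_level_ors: pd.DataFrame
    correlations: pd.DataFrame            # pairwise r/p incl. composite
    composite_rates: pd.DataFrame         # hospital_id, rate
    composite_distribution: pd.DataFrame  # per-hospital level proportions
    rankability: pd.DataFrame
    period_comparison: Optional[dict]
    provenance: dict
    records: Optional[pd.DataFrame] = None
    ordinal_results: object = None
    casemix_models: Optional[dict] = None
    long_los_rule: object = None

    def to_summary(self) -> dict:
        def df(d: pd.DataFrame):
            return json.loads(d.to_json(orient="records", double_precision=10))

        return {
            "ratios": df(self.ratios.drop(columns=[], errors="ignore")),
            "ratio_summary": df(self.ratio_summary),
            "patient_level_ors": df(self.patient_level_ors),
            "correlations": df(self.correlations),
            "composite_rates": df(self.composite_rates),
            "composite_distribution": df(self.composite_distribution),
            "rankability": df(self.rankability),
            "period_comparison": self.period_comparison,
            "provenance": self.provenance,
        }

    def write(self, outdir, figures: bool = True) -> dict:
        os.makedirs(outdir, exist_ok=True)
        report_dir = os.path.join(outdir, "report")
        os.makedirs(report_dir, exist_ok=True)
        paths = {}
        tables = {
            "ratios.csv": self.ratios,
            "report/patient_level_ors.csv": self.patient_level_ors,
            "report/ratio_summary.csv": self.ratio_summary,
            "report/correlations.csv": self.correlations,
            "report/composite_rates.csv": self.composite_rates,
            "report/composite_distribution.csv": self.composite_distribution,
            "report/rankability.csv": self.rankability,
        }
        for name, table in tables.items():
            path = os.path.join(outdir, name)
            table.to_csv(path, index=False)
            paths[name] = path
        if self.period_comparison is not None:
            path = os.path.join(report_dir, "period_comparison.json")
            with open(path, "w") as fh:
                json.dump(self.period_comparison, fh, indent=2, sort_keys=True)
            paths["period_comparison"] = path
        summary_path = os.path.join(outdir, "summary.json")
        with open(summary_path, "w") as fh:
            json.dump(self.to_summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["summary"] = summary_path
        if figures:
            paths.update(self._write_figures(report_dir))
        return paths

    def _write_figures(self, report_dir) -> dict:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        paths = {}
        # composite distribution, stacked per hospital
        dist = self.composite_distribution.set_index("hospital_id")
        fig, ax = plt.subplots(figsize=(10, 4))
        bottom = np.zeros(len(dist))
        for level in range(1, 6):
            col = f"level_{level}"
            ax.bar(dist.index, dist[col], bottom=bottom, label=f"level {level}")
            bottom += dist[col].to_numpy()
        ax.set_ylabel("proportion of admissions")
        ax.legend(ncol=5, fontsize=7)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        p = os.path.join(report_dir, "composite_distribution.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["fig_composite_distribution"] = p

        fig, ax = plt.subplots(figsize=(6, 4))
        rk = self.rankability
        ax.bar(rk["outcome"], rk["rankability"])
        ax.set_ylabel("rankability (%)")
        ax.set_ylim(0, 100)
        fig.tight_layout()
        p = os.path.join(report_dir, "rankability.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["fig_rankability"] = p
        return paths


# --------------------------------------------------------------------------- #

def composite_distribution_table(records: pd.DataFrame,
                                 levels: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-hospital proportions of the 5 composite levels (rows sum to 1)."""
    if levels is None:
        levels = records["composite_level"].to_numpy()
    df = pd.DataFrame({"hospital_id": records["hospital_id"].to_numpy(),
                       "level": np.asarray(levels, dtype=int)})
    counts = (
        df.groupby(["hospital_id", "level"], observed=True).size()
        .unstack(fill_value=0).reindex(columns=range(1, 6), fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"level_{k}" for k in props.columns]
    return props.reset_index()


def compare_periods(
    records: pd.DataFrame,
    levels: Optional[np.ndarray] = None,
    split_year: int = 2009,
    include_tau2: bool = True,
) -> dict:
    """Compare the share of best composite outcomes between two periods.

    Period A: discharge year <= ``split_year``; period B: later years.
    Returns the level-1 proportions, a two-proportion chi-square p-value, a
    per-group breakdown, and (optionally) the between-hospital variance tau2
    of the composite per period (moments estimator on hospital fixed
    effects).
    """
    if levels is None:
        levels = records["composite_level"].to_numpy()
    levels = np.asarray(levels, dtype=int)
    in_a = (records["year"] <= split_year).to_numpy()
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(
            f"degenerate period split at year {split_year}: "
            f"{n_a} vs {n_b} admissions"
        )
    best = levels == 1
    b_a, b_b = int(best[in_a].sum()), int(best[~in_a].sum())
    table = np.array([[b_a, n_a - b_a], [b_b, n_b - b_b]])
    chi2_stat, p, _, _ = chi2_contingency(table, correction=False)

    by_group = []
    for grp, sub_idx in records.groupby("group", observed=True).indices.items():
        sel_a = in_a[sub_idx]
        ga, gb = best[sub_idx][sel_a], best[sub_idx][~sel_a]
        by_group.append(
            {
                "group": str(grp),
                "proportion_best_A": float(ga.mean()) if ga.size else None,
                "proportion_best_B": float(gb.mean()) if gb.size else None,
            }
        )

    result = {
        "split_year": int(split_year),
        "n_A": n_a,
        "n_B": n_b,
        "proportion_best_A": b_a / n_a,
        "proportion_best_B": b_b / n_b,
        "chi2": float(chi2_stat),
        "p_value": float(p),
        "by_group": by_group,
    }
    if include_tau2:
        for label, sel in (("A", in_a), ("B", ~in_a)):
            sub = records.loc[sel]
            fit = HospitalOrdinalModel(sub, levels=levels[sel]).fit()
            cent = fit.centered_effects()
            result[f"tau2_{label}"] = estimate_tau2_moments(
                cent["effect"].to_numpy(), np.maximum(cent["se"].to_numpy(), 1e-6)
            )
    return result


def run_full_analysis(
    config_or_records: Union[ScenarioConfig, pd.DataFrame],
    percentile: int = 75,
    per_group: bool = True,
    elimination: bool = True,
    casemix_in_ordinal: bool = True,
    period_split_year: Optional[int] = None,
    seed: Optional[int] = None,
    keep_records: bool = True,
) -> ReportBundle:
    """Execute all stages with shared settings; deterministic given the seed."""
    effects = None
    config = None
    if isinstance(config_or_records, ScenarioConfig):
        config = config_or_records
        if seed is not None:
            config = config.replace(seed=seed)
        logger.info("simulating cohort: %d hospitals", config.n_hospitals)
        records, effects = generate_cohort(config)
    else:
        records = config_or_records.copy()
    n_in = len(records)
    logger.info("cohort: %d admissions, %d hospitals", n_in,
                records["hospital_id"].nunique())

    flags, rule = stdz.long_los_flags(records, percentile)
    records = records.assign(long_los=flags.to_numpy())

    logger.info("fitting case-mix models (per_group=%s)", per_group)
    models = fit_casemix_models(records, per_group=per_group,
                                elimination=elimination)
    ratios = stdz.standardized_ratios(records, models)
    ratio_summary = (
        ratios.groupby("outcome")["ratio"]
        .agg(median="median", iqr_low=lambda s: s.quantile(0.25),
             iqr_high=lambda s: s.quantile(0.75))
        .reset_index()
    )

    or_rows = []
    for outcome in ("mortality", "readmission"):
        for adjusted in (False, True):
            res = stdz.patient_level_or(records, outcome, adjusted=adjusted)
            or_rows.append(dataclasses.asdict(res))
    patient_ors = pd.DataFrame(or_rows)

    levels = assign_composite_level(records["died"], records["long_los"],
                                    records["readmitted_30d"])
    records = records.assign(composite_level=levels)
    logger.info("fitting hospital fixed-effects ordinal model")
    ordinal_results = HospitalOrdinalModel(
        records, levels=levels, casemix=casemix_in_ordinal
    ).fit()
    composite_rates = ordinal_results.standardized_rates()
    dist = composite_distribution_table(records, levels)

    correlations = stdz.correlation_matrix(
        ratios,
        extra={"composite": composite_rates.set_index("hospital_id")["rate"]},
    )

    logger.info("estimating rankability")
    probs = expected_probabilities(models, records)
    offsets = pd.DataFrame(
        {
            c: logit(np.clip(probs[c].to_numpy(dtype=float), 1e-6, 1 - 1e-6))
            for c in probs.columns
        },
        index=probs.index,
    )
    rank_results = rankability_analysis(
        records,
        casemix_offsets=offsets,
        ordinal_results=ordinal_results,
    )
    rank_table = pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "tau2": r.tau2,
                "median_sigma2": r.median_sigma2,
                "rankability": r.rankability,
                "method": r.estimation_method,
            }
            for r in rank_results
        ]
    )

    period_cmp = None
    years = sorted(records["year"].unique())
    if len(years) > 1:
        split = period_split_year if period_split_year is not None else int(
            np.median(years)
        )
        if split >= years[-1]:
            split = years[len(years) // 2 - 1]
        period_cmp = compare_periods(records, levels, split_year=split)

    provenance = {
        "package_version": _pkg_version("hospbench"),
        "seed": None if config is None else config.seed,
        "config": None if config is None else config.to_dict(),
        "percentile": percentile,
        "n_admissions": n_in,
        "long_los_cutoffs": rule.cutoffs,
    }
    return ReportBundle(
        ratios=ratios,
        ratio_summary=ratio_summary,
        patient_level_ors=patient_ors,
        correlations=correlations,
        composite_rates=composite_rates,
        composite_distribution=dist,
        rankability=rank_table,
        period_comparison=period_cmp,
        provenance=provenance,
        records=records if keep_records else None,
        ordinal_results=ordinal_results,
        casemix_models=models,
        long_los_rule=rule,
    )
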