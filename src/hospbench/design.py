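"""Term-based design matrices for the case-mix and ordinal models.

A *term* is one case-mix variable in the modelling sense: a multi-level
categorical factor contributes a block of dummy columns but is retained or
dropped as a single unit (block Wald test) during backward elimination.
Supported kinds: numeric, binary indicator, categorical (reference = first
observed level), categorical-x-numeric interaction and binary-x-binary
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class UnseenLevelError(ValueError):
    """A categorical level at prediction time was not seen at fit time."""


@dataclass(frozen=True)
class Term:
    name: str
    kind: str                      # numeric | binary | categorical | cat_x_num | bin_x_bin
    variables: tuple[str, ...]     # underlying data columns


# The standard case-mix candidate set: main effects plus the two a-priori
# interaction candidates (age x comorbidity, admission method x transfer).
def casemix_terms(include_year: bool = True, include_group: bool = False,
                  interactions: bool = True) -> list[Term]:
    terms = [
        Term("age_group", "categorical", ("age_group",)),
        Term("sex", "binary", ("sex",)),
        Term("unplanned", "binary", ("unplanned",)),
        Term("transfer_in", "binary", ("transfer_in",)),
        Term("urgent_prior", "binary", ("urgent_prior",)),
        Term("elixhauser_count", "numeric", ("elixhauser_count",)),
    ]
    if include_year:
        terms.append(Term("year", "categorical", ("year",)))
    if include_group:
        terms.append(Term("group", "categorical", ("group",)))
    if interactions:
        terms.append(
            Term("age_group:elixhauser_count", "cat_x_num",
                 ("age_group", "elixhauser_count"))
        )
        terms.append(
            Term("unplanned:transfer_in", "bin_x_bin", ("unplanned", "transfer_in"))
        )
    return terms


def interaction_parents(term: Term) -> tuple[str, ...]:
    if term.kind in ("cat_x_num", "bin_x_bin"):
        return term.variables
    return ()


@dataclass
class DesignInfo:
    """Fitted design metadata: terms, column layout and categorical levels."""

    terms: list[Term]
    levels: dict[str, list] = field(default_factory=dict)  # variable -> levels seen
    age_merge_map: Optional[dict] = None
    column_names: list[str] = field(default_factory=list)
    term_slices: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)


def _categorical_codes(values: pd.Series, levels: list, varname: str) -> np.ndarray:
    cat = pd.Categorical(values, categories=levels)
    codes = np.asarray(cat.codes)
    if (codes < 0).any():
        bad = sorted(set(np.asarray(values)[codes < 0]))
        raise UnseenLevelError(
            f"variable {varname!r} has level(s) {bad!r} not present at fit time"
        )
    return codes


def _apply_age_merge(values: pd.Series, merge_map: dict) -> pd.Series:
    return values.map(lambda v: merge_map.get(v, v))


def build_design(
    df: pd.DataFrame,
    terms: Sequence[Term],
    info: Optional[DesignInfo] = None,
    age_merge_map: Optional[dict] = None,
    intercept: bool = True,
) -> tuple[np.ndarray, DesignInfo]:
    """Build (X, info).

    When ``info`` is given (prediction), its recorded levels are reused and an
    :class:`UnseenLevelError` is raised for unknown levels; otherwise levels
    are learned from ``df``.
    """
    fitting = info is None
    if fitting:
        info = DesignInfo(terms=list(terms), age_merge_map=age_merge_map)
    merge_map = info.age_merge_map

    cols: list[np.ndarray] = []
    names: list[str] = []
    slices: dict[str, list[int]] = {}

    def add(term_name: str, colname: str, values: np.ndarray) -> None:
        slices.setdefault(term_name, []).append(len(names) + (1 if intercept else 0))
        names.append(colname)
        cols.append(np.asarray(values, dtype=float))

    def get_levels(var: str, series: pd.Series) -> list:
        if fitting:
            if var not in info.levels:
                uniq = pd.unique(series.dropna())
                info.levels[var] = sorted(uniq.tolist())
            return info.levels[var]
        if var not in info.levels:
            raise UnseenLevelError(f"no levels recorded for variable {var!r}")
        return info.levels[var]

    def var_series(var: str) -> pd.Series:
        s = df[var]
        if var == "age_group":
            s = s.astype(object)
            if merge_map:
                s = _apply_age_merge(s, merge_map)
        return s

    for term in info.terms:
        if term.kind == "numeric":
            add(term.name, term.name, df[term.variables[0]].to_numpy(dtype=float))
        elif term.kind == "binary":
            add(term.name, term.name, df[term.variables[0]].to_numpy(dtype=float))
        elif term.kind == "categorical":
            var = term.variables[0]
            s = var_series(var)
            levels = get_levels(var, s)
            codes = _categorical_codes(s, levels, var)
            for j, lev in enumerate(levels[1:], start=1):
                add(term.name, f"{var}[{lev}]", (codes == j).astype(float))
        elif term.kind == "cat_x_num":
            cat_var, num_var = term.variables
            s = var_series(cat_var)
            levels = get_levels(cat_var, s)
            codes = _categorical_codes(s, levels, cat_var)
            num = df[num_var].to_numpy(dtype=float)
            for j, lev in enumerate(levels[1:], start=1):
                add(term.name, f"{cat_var}[{lev}]:{num_var}",
                    (codes == j).astype(float) * num)
        elif term.kind == "bin_x_bin":
            a, b = term.variables
            add(term.name, f"{a}:{b}",
                df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float))
        else:  # pragma: no cover
            raise ValueError(f"unknown term kind {term.kind!r}")

    n = len(df)
    blocks = [np.ones((n, 1))] if intercept else []
    if cols:
        blocks.append(np.column_stack(cols))
    X = np.hstack(blocks) if blocks else np.empty((n, 0))

    if fitting:
        info.column_names = (["Intercept"] if intercept else []) + names
        info.term_slices = slices
        if intercept:
            info.term_slices = {"Intercept": [0], **slices}
    return X, info
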