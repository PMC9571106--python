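"""Factorial linear models of litter mass loss.

Fits fixed-effects general linear models of remaining (or lost) litter mass
on the five design factors — litter species, litter type (origin plot),
precipitation treatment, forest, and decomposition time — and their
interactions.  Model selection is bidirectional stepwise search on AIC with
marginality (hierarchy) enforced; inference tables use Type-I (sequential)
sums of squares, reported with the percentage of total SS per term.

The AIC convention is the Gaussian profile-likelihood form
``n*ln(RSS/n) + 2*(k+1)`` with k mean parameters plus one variance
parameter; only AIC differences are meaningful under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (FORESTS, LITTER_TYPES, SPECIES, TIMES, TREATMENTS,
                      LitterBagRecord, litterbags_to_frame)

__all__ = [
    "ModelFit", "FACTOR_LEVELS", "build_design", "fit_ols", "aic_score",
    "stepwise_select", "sequential_anova", "two_way_anova",
    "records_to_model_frame",
]

#: Canonical level order per design factor (first level = reference).
FACTOR_LEVELS: dict[str, tuple] = {
    "species": SPECIES,
    "litter_type": LITTER_TYPES,
    "treatment": TREATMENTS,
    "forest": FORESTS,
    "time_months": TIMES,
}

Term = tuple[str, ...]


def _canon_term(term: str | Sequence[str]) -> Term:
    factors = (term,) if isinstance(term, str) else tuple(term)
    order = list(FACTOR_LEVELS)
    for f in factors:
        if f not in FACTOR_LEVELS:
            raise ValueError(f"unknown factor {f!r}")
    if len(set(factors)) != len(factors):
        raise ValueError(f"repeated factor in term {factors}")
    return tuple(sorted(factors, key=order.index))


def term_label(term: Term) -> str:
    return ":".join(term)


def term_sort_key(term: Term) -> tuple:
    """Canonical entry order: main effects first, then higher interactions,
    each block in design-factor order."""
    order = list(FACTOR_LEVELS)
    return (len(term), tuple(order.index(f) for f in term))


def records_to_model_frame(records: Sequence[LitterBagRecord],
                           response: str = "remaining_mass_pct"
                           ) -> pd.DataFrame:
    """Design factors plus the chosen decomposition response per bag."""
    frame = litterbags_to_frame(records)
    frame[response] = [getattr(r, response) for r in records]
    return frame


def build_design(data: pd.DataFrame, terms: Sequence[str | Sequence[str]]
                 ) -> tuple[np.ndarray, dict[Term, slice], list[str]]:
    """Treatment-coded design matrix for main effects and interactions.

    Each factor contributes L-1 dummy columns (reference = first canonical
    level); an interaction contributes the products of its margins' dummy
    columns.  Returns the matrix (with leading intercept), a map from term
    to its column slice, and column names.

    Raises on duplicate terms and on rank deficiency, naming the aliased
    columns.
    """
    canon = [_canon_term(t) for t in terms]
    if len(set(canon)) != len(canon):
        seen: set[Term] = set()
        dups = [t for t in canon if t in seen or seen.add(t)]
        raise ValueError(f"duplicate terms: {[term_label(t) for t in dups]}")
    needed = {f for t in canon for f in t}
    missing = sorted(needed - set(data.columns))
    if missing:
        raise ValueError(f"factors absent from data: {missing}")

    dummies: dict[str, tuple[np.ndarray, list[str]]] = {}
    for factor in needed:
        levels = FACTOR_LEVELS[factor]
        col = data[factor]
        bad = set(col) - set(levels)
        if bad:
            raise ValueError(f"unknown {factor} levels: {sorted(map(str, bad))}")
        present = [lv for lv in levels if lv in set(col)]
        if len(present) < 2:
            mat = np.empty((len(data), 0))
        else:
            mat = np.column_stack([(col == lv).to_numpy(float)
                                   for lv in present[1:]])
        names = [f"{factor}[{lv}]" for lv in present[1:]]
        dummies[factor] = (mat, names)

    blocks = [np.ones((len(data), 1))]
    names = ["Intercept"]
    slices: dict[Term, slice] = {}
    start = 1
    for term in canon:
        mats = [dummies[f][0] for f in term]
        labs = [dummies[f][1] for f in term]
        block = mats[0]
        lab = labs[0]
        for m, l2 in zip(mats[1:], labs[1:]):
            block = np.einsum("ij,ik->ijk", block, m).reshape(len(data), -1)
            lab = [f"{a}:{b}" for a in lab for b in l2]
        blocks.append(block)
        names.extend(lab)
        slices[term] = slice(start, start + block.shape[1])
        start += block.shape[1]
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that add no rank, in order
        aliased = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, :j + 1])
            if rj == r:
                aliased.append(names[j])
            r = rj
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return X, slices, names


@dataclass
class ModelFit:
    """An ordinary-least-squares fit of one candidate model."""

    terms: tuple[Term, ...]
    coef: np.ndarray
    column_names: list[str]
    rss: float
    tss: float
    n: int
    k: int  # number of estimated mean parameters (columns)

    @property
    def r2(self) -> float:
        return 1.0 - self.rss / self.tss if self.tss > 0 else 0.0

    @property
    def aic(self) -> float:
        return aic_score(self)


def fit_ols(X: np.ndarray, y: np.ndarray,
            terms: Sequence[Term] = (), names: Sequence[str] = ()) -> ModelFit:
    """Least-squares fit; raises on singular designs."""
    y = np.asarray(y, dtype=float)
    if X.shape[0] < X.shape[1]:
        raise ValueError(
            f"need n >= p, got n={X.shape[0]}, p={X.shape[1]}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return ModelFit(terms=tuple(terms), coef=coef,
                    column_names=list(names) or
                    [f"x{i}" for i in range(X.shape[1])],
                    rss=rss, tss=tss, n=len(y), k=X.shape[1])


def aic_score(fit: ModelFit) -> float:
    """Gaussian AIC: n*ln(RSS/n) + 2*(k+1); -inf flagged for a perfect fit."""
    if fit.rss <= 0:
        return float("-inf")
    return fit.n * float(np.log(fit.rss / fit.n)) + 2 * (fit.k + 1)


def _fit_terms(data: pd.DataFrame, response: str,
               terms: Sequence[Term]) -> ModelFit:
    X, _, names = build_design(data, terms)
    return fit_ols(X, data[response].to_numpy(float), terms=terms, names=names)


def _hierarchy_ok(terms: set[Term], candidate: Term) -> bool:
    """All lower-order margins of ``candidate`` are present in ``terms``."""
    for k in range(1, len(candidate)):
        for sub in combinations(candidate, k):
            if tuple(sub) not in terms:
                return False
    return True


def _droppable(terms: set[Term], candidate: Term) -> bool:
    """No retained interaction has ``candidate`` as a margin."""
    return not any(set(candidate) < set(t) for t in terms if t != candidate)


DEFAULT_SCOPE: tuple[Term, ...] = tuple(
    _canon_term(t) for t in (
        list(FACTOR_LEVELS)
        + [c for c in combinations(FACTOR_LEVELS, 2)]
    )
)


def stepwise_select(data: pd.DataFrame | Sequence[LitterBagRecord],
                    response: str = "remaining_mass_pct",
                    scope_terms: Sequence[str | Sequence[str]] | None = None,
                    start_terms: Sequence[str | Sequence[str]] | None = None
                    ) -> ModelFit:
    """Bidirectional AIC stepwise selection with marginality enforced.

    Starts from the full scope (all candidate terms) and repeatedly applies
    the single add or drop move that most lowers the AIC, never dropping a
    margin of a retained interaction nor adding an interaction before its
    margins.  Deterministic given the data.
    """
    if not isinstance(data, pd.DataFrame):
        data = records_to_model_frame(data, response)
    scope = ([_canon_term(t) for t in scope_terms]
             if scope_terms is not None else list(DEFAULT_SCOPE))
    current = (set(_canon_term(t) for t in start_terms)
               if start_terms is not None else set(scope))
    fit = _fit_terms(data, response, sorted(current, key=term_sort_key))
    best_aic = fit.aic
    while True:
        moves: list[tuple[float, set[Term]]] = []
        for t in sorted(current, key=term_sort_key):
            if _droppable(current, t):
                moves.append((None, current - {t}))
        for t in scope:
            if t not in current and _hierarchy_ok(current, t):
                moves.append((None, current | {t}))
        best_move = None
        for _, cand in moves:
            cand_fit = _fit_terms(data, response, sorted(cand, key=term_sort_key))
            if cand_fit.aic < best_aic - 1e-10:
                best_aic = cand_fit.aic
                best_move = (cand, cand_fit)
        if best_move is None:
            return fit
        current, fit = best_move[0], best_move[1]


def sequential_anova(data: pd.DataFrame | Sequence[LitterBagRecord],
                     response: str = "remaining_mass_pct",
                     terms: Sequence[str | Sequence[str]] | None = None
                     ) -> pd.DataFrame:
    """Type-I (sequential) ANOVA table in the declared term order.

    Columns: term, df, ss, pct_ss, F, p; the final row is the residual.
    ``pct_ss`` over all terms plus the residual sums to 100.
    """
    if not isinstance(data, pd.DataFrame):
        data = records_to_model_frame(data, response)
    if terms is None:
        terms = list(DEFAULT_SCOPE)
    canon = [_canon_term(t) for t in terms]
    y = data[response].to_numpy(float)
    tss = float(((y - y.mean()) ** 2).sum())
    rows = []
    prev_rss = tss
    prev_k = 1
    fit = None
    for i in range(len(canon)):
        fit = _fit_terms(data, response, canon[:i + 1])
        ss = prev_rss - fit.rss
        rows.append({"term": term_label(canon[i]),
                     "df": fit.k - prev_k, "ss": ss})
        prev_rss, prev_k = fit.rss, fit.k
    df_res = fit.n - fit.k
    if df_res <= 0:
        raise ValueError("zero residual degrees of freedom")
    ms_res = fit.rss / df_res
    for row in rows:
        row["pct_ss"] = 100.0 * row["ss"] / tss if tss > 0 else float("nan")
        if row["df"] == 0 or ms_res == 0:
            row["F"], row["p"] = float("nan"), float("nan")
        else:
            row["F"] = (row["ss"] / row["df"]) / ms_res
            row["p"] = float(stats.f.sf(row["F"], row["df"], df_res))
    rows.append({"term": "Residuals", "df": df_res, "ss": fit.rss,
                 "pct_ss": 100.0 * fit.rss / tss if tss > 0 else float("nan"),
                 "F": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows, columns=["term", "df", "ss", "pct_ss", "F", "p"])


def two_way_anova(data: pd.DataFrame, response: str = "value",
                  factor_a: str = "litter_type", factor_b: str = "species"
                  ) -> pd.DataFrame:
    """Classical two-way ANOVA with interaction for initial-trait tables.

    Expects a balanced factor_a x factor_b layout with replicates.  Returns
    the sequential table (orthogonal for balanced data, so order-free) with
    F-tests against the residual mean square.  If any cell has fewer than 2
    replicates the interaction is untestable and a ``flag`` column says so;
    a zero residual variance also flags the table (F undefined).
    """
    counts = data.groupby([factor_a, factor_b], observed=True)[response].count()
    table = sequential_anova(
        data, response, [factor_a, factor_b, (factor_a, factor_b)])
    flag = ""
    if (counts < 2).any():
        flag = "interaction untestable: fewer than 2 replicates per cell"
    resid = table.loc[table["term"] == "Residuals", "ss"].iloc[0]
    if resid <= 1e-12:
        flag = (flag + "; " if flag else "") + \
            "zero residual variance: F undefined"
        table.loc[table["term"] != "Residuals", ["F", "p"]] = float("nan")
    table.attrs["flag"] = flag
    return table
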