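"""Intention scoring and the statistical comparison with reported intention.

The model's intention readout is the mean activation of the intend bank
minus the mean of the not-intend bank — a continuous score in (-1, 1),
negative meaning "not intend".  The score is binned into four categories
aligned with the 4-level survey intention item (NO!/no/yes/YES!) by
equally spaced cut-points.  Model and reported categories are compared by
a 4x4 cross-tabulation with an exact conditional test (multivariate
hypergeometric point probability and the Freeman-Halton tail sum), by
per-category score means, and by a dummy-coded OLS regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
import statsmodels.api as sm

__all__ = [
    "IntentionResult",
    "CrossTab",
    "RegressionResult",
    "intention_score",
    "categorize",
    "crosstab",
    "exact_point_probability",
    "enumerate_tables",
    "freeman_halton_p",
    "group_stats",
    "dummy_regression",
]

#: cut-points mapping the continuous score to categories 1..4:
#: (-1, -0.5] -> 1, (-0.5, 0] -> 2, (0, 0.5] -> 3, (0.5, 1) -> 4
_CUTS = (-0.5, 0.0, 0.5)


@dataclass(frozen=True)
class IntentionResult:
    score: float
    category: int


def intention_score(state, topology) -> float:
    """Mean intend-bank activation minus mean not-intend-bank activation."""
    a = getattr(state, "activations", state)
    a = np.asarray(a, dtype=float)
    return float(a[topology.intend].mean() - a[topology.not_intend].mean())


def categorize(score: float) -> int:
    """Bin a score into categories 1..4 by the printed half-open intervals
    (right-closed on the negative side); a score of exactly -0.5 falls in
    category 1 and exactly 0 in category 2."""
    if not -1.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [-1, 1]")
    if score <= -0.5:
        return 1
    if score <= 0.0:
        return 2
    if score <= 0.5:
        return 3
    return 4


def score_states(states, topology) -> list[IntentionResult]:
    """Intention score and category for each recorded state."""
    out = []
    for s in states:
        sc = intention_score(s, topology)
        out.append(IntentionResult(sc, categorize(sc)))
    return out


@dataclass(frozen=True)
class CrossTab:
    """4x4 counts of reported intention (rows) by model intention (cols)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def crosstab(model_cats, empirical_cats, levels=(1, 2, 3, 4)) -> CrossTab:
    """Cross-tabulate reported (rows) against model (columns) categories."""
    m = np.asarray(model_cats)
    e = np.asarray(empirical_cats)
    if m.size != e.size:
        raise ValueError("category sequences differ in length")
    k = len(levels)
    counts = np.zeros((k, k), dtype=np.int64)
    for i, re in enumerate(levels):
        for j, cm in enumerate(levels):
            counts[i, j] = int(np.sum((e == re) & (m == cm)))
    return CrossTab(counts)


def _log_point_prob(counts, log_rc_term):
    return log_rc_term - gammaln(np.asarray(counts) + 1.0).sum()


def _log_rc_term(table: CrossTab) -> float:
    return float(
        gammaln(table.row_totals + 1.0).sum()
        + gammaln(table.col_totals + 1.0).sum()
        - gammaln(table.total + 1.0)
    )


def exact_point_probability(table: CrossTab) -> float:
    """Multivariate hypergeometric probability of the observed table
    conditional on both margins, computed in log space:

        P = (prod_i R_i!)(prod_j C_j!) / (N! prod_ij n_ij!)
    """
    return float(np.exp(_log_point_prob(table.counts, _log_rc_term(table))))


def enumerate_tables(row_totals, col_totals):
    """Yield every non-negative integer table with the given margins."""
    rows = [int(v) for v in row_totals]
    cols = [int(v) for v in col_totals]
    if sum(rows) != sum(cols):
        raise ValueError("margins are inconsistent")
    R, C = len(rows), len(cols)

    def fill_row(i, colrem, acc):
        if i == R - 1:
            if all(v >= 0 for v in colrem) and sum(colrem) == rows[i]:
                yield acc + [list(colrem)]
            return
        # enumerate compositions of rows[i] bounded by the column remainders
        def comp(j, rem, row):
            if j == C - 1:
                if 0 <= rem <= colrem[j]:
                    yield row + [rem]
                return
            for v in range(min(rem, colrem[j]) + 1):
                yield from comp(j + 1, rem - v, row + [v])

        for row in comp(0, rows[i], []):
            yield from fill_row(
                i + 1, [colrem[j] - row[j] for j in range(C)], acc + [row]
            )

    yield from fill_row(0, cols, [])


def freeman_halton_p(
    table: CrossTab,
    mode: str = "enumerate",
    n_mc: int = 100_000,
    seed: int = 0,
    guard_limit: int = 2_000_000,
) -> float:
    """Two-sided exact test for an RxC table with fixed margins: the sum of
    point probabilities over all margin-consistent tables no more probable
    than the observed one (the Freeman-Halton generalization of Fisher's
    exact test).

    ``enumerate`` sums over the complete enumeration; ``montecarlo``
    estimates the same tail by sampling tables with the observed margins.
    """
    log_rc = _log_rc_term(table)
    lp_obs = _log_point_prob(table.counts, log_rc)
    tol = 1e-9  # ties at the observed probability count toward the tail
    if mode == "enumerate":
        tail = 0.0
        n_seen = 0
        for t in enumerate_tables(table.row_totals, table.col_totals):
            n_seen += 1
            if n_seen > guard_limit:
                raise ValueError(
                    f"enumeration exceeds the guard limit ({guard_limit} "
                    f"tables); use mode='montecarlo'"
                )
            lp = _log_point_prob(t, log_rc)
            if lp <= lp_obs + tol:
                tail += np.exp(lp)
        return float(min(tail, 1.0))
    if mode == "montecarlo":
        rng = np.random.default_rng(seed)
        hits = 0
        for t in _sample_margin_tables(table.row_totals, table.col_totals, n_mc, rng):
            if _log_point_prob(t, log_rc) <= lp_obs + tol:
                hits += 1
        return hits / n_mc
    raise ValueError(f"unknown mode {mode!r}")


def _sample_margin_tables(row_totals, col_totals, n, rng):
    """Sample tables with both margins fixed by random permutation pairing
    (equivalent to the conditional multivariate hypergeometric)."""
    rows = np.repeat(np.arange(len(row_totals)), row_totals)
    cols = np.repeat(np.arange(len(col_totals)), col_totals)
    R, C = len(row_totals), len(col_totals)
    for _ in range(n):
        perm = rng.permutation(cols)
        t = np.zeros((R, C), dtype=np.int64)
        np.add.at(t, (rows, perm), 1)
        yield t


def group_stats(scores, categories, levels=(1, 2, 3, 4)) -> pd.DataFrame:
    """Per-category mean, standard error (sample sd / sqrt(n); missing when
    n < 2) and count of the continuous score."""
    s = np.asarray(scores, dtype=float)
    c = np.asarray(categories)
    if s.size != c.size:
        raise ValueError("scores and categories differ in length")
    rows = []
    for lev in levels:
        sel = s[c == lev]
        n = sel.size
        if n == 0:
            rows.append({"category": lev, "mean": np.nan, "se": np.nan, "n": 0})
            continue
        mean = float(sel.mean())
        se = float(sel.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append({"category": lev, "mean": mean, "se": se, "n": n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    """Dummy-coded OLS of score on category."""

    reference: int
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    adj_r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int


def dummy_regression(scores, categories, reference: int = 1) -> RegressionResult:
    """Ordinary least squares of the continuous score on indicator
    variables for every non-reference category present in the data.

    The intercept equals the reference-category mean and each coefficient
    the difference of that category's mean from the reference (the one-way
    ANOVA identity).
    """
    s = np.asarray(scores, dtype=float)
    c = np.asarray(categories)
    if s.size != c.size:
        raise ValueError("scores and categories differ in length")
    present = sorted(set(int(v) for v in c))
    if reference not in present:
        raise ValueError(f"reference category {reference} absent from data")
    if len(present) < 2:
        raise ValueError("need at least two categories for regression")
    X = pd.DataFrame({"const": np.ones(s.size)})
    for lev in present:
        if lev == reference:
            continue
        X[f"cat_{lev}"] = (c == lev).astype(float)
    if s.size <= X.shape[1]:
        raise ValueError("not enough observations for the number of parameters")
    fit = sm.OLS(s, X).fit()
    return RegressionResult(
        reference=reference,
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
    )
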