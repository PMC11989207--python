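"""Statistical machinery for the response analyses.

Implements the specific conventions the analyses rely on, from first
principles:

* exact tests for 2x2 and 2x3 contingency tables by full enumeration of
  all tables with the observed margins (Fisher's exact test; the 2x3 case
  is the Freeman-Halton generalization);
* Welch's unequal-variance t test;
* the Kaplan-Meier product-limit estimator (events before censorings at
  tied times) and the K-group Mantel-Haenszel log-rank test.

scipy supplies only distribution functions; the combinatorics and the
risk-set bookkeeping are written out here so tests can check them against
independent oracles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist

__all__ = [
    "ContingencyTable",
    "ExactTestResult",
    "SurvivalCurve",
    "crosstab",
    "fisher_exact",
    "t_test_independent",
    "km_estimate",
    "survival_at",
    "event_free_proportion",
    "logrank_test",
]

# relative tolerance in the "probability <= observed" rule, for float safety
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of nonnegative integer counts with row/column labels."""

    counts: Tuple[Tuple[int, ...], ...]
    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match table shape")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if arr.sum() == 0:
            raise ValueError("table must contain at least one count")

    @classmethod
    def from_array(cls, counts, row_labels, col_labels) -> "ContingencyTable":
        return cls(
            counts=tuple(tuple(int(v) for v in row) for row in counts),
            row_labels=tuple(str(r) for r in row_labels),
            col_labels=tuple(str(c) for c in col_labels),
        )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def total(self) -> int:
        return int(self.to_array().sum())


@dataclass(frozen=True)
class ExactTestResult:
    p_value: float
    observed_table_prob: float
    n_tables_enumerated: int


def crosstab(labels_a: Sequence, labels_b: Sequence,
             row_order: Optional[Sequence] = None,
             col_order: Optional[Sequence] = None) -> ContingencyTable:
    """Cross-tabulate two categorical vectors, dropping incomplete pairs.

    Rows are the categories of ``labels_a``; ``None``/NaN entries are
    removed pairwise (complete-case).
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("labels_a and labels_b must have equal length")

    def _missing(v) -> bool:
        return v is None or (isinstance(v, float) and math.isnan(v))

    pairs = [(a, b) for a, b in zip(labels_a, labels_b)
             if not _missing(a) and not _missing(b)]
    if not pairs:
        raise ValueError("no complete pairs to tabulate")
    rows = list(row_order) if row_order is not None else sorted(
        {a for a, _ in pairs}, key=str)
    cols = list(col_order) if col_order is not None else sorted(
        {b for _, b in pairs}, key=str)
    counts = [[sum(1 for a, b in pairs if a == r and b == c) for c in cols]
              for r in rows]
    return ContingencyTable.from_array(counts, rows, cols)


def _log_table_prob(table: np.ndarray, row_m: np.ndarray, col_m: np.ndarray,
                    log_n_fact: float) -> float:
    """Log multivariate hypergeometric probability of a table with fixed margins."""
    lg = sum(math.lgamma(m + 1) for m in row_m) + \
        sum(math.lgamma(m + 1) for m in col_m) - log_n_fact
    lg -= sum(math.lgamma(v + 1) for v in table.ravel())
    return lg


def fisher_exact(table: ContingencyTable) -> ExactTestResult:
    """Exact test of independence for a 2x2 or 2x3 table.

    Enumerates every table with the observed row and column margins; each
    has multivariate hypergeometric probability
    (prod r_i! * prod c_j!) / (N! * prod n_ij!); the two-sided p-value
    sums the probabilities of tables no more probable than the observed
    one.  For 2x2 tables this is the classic two-sided Fisher test; for
    2x3 it is the Freeman-Halton generalization.
    """
    arr = table.to_array()
    if arr.shape not in ((2, 2), (2, 3), (3, 2)):
        raise ValueError(f"unsupported table shape {arr.shape}; only 2x2 and 2x3")
    if arr.shape == (3, 2):
        arr = arr.T
    row_m = arr.sum(axis=1)
    col_m = arr.sum(axis=0)
    # A zero *column* needs no special case: enumeration forces that cell
    # to 0, so the result equals the test on the reduced table.  A zero
    # row margin makes the conditional distribution degenerate.
    if np.any(row_m == 0):
        warnings.warn("zero row margin: exact test degenerate, p = 1",
                      stacklevel=2)
        return ExactTestResult(p_value=1.0, observed_table_prob=1.0,
                               n_tables_enumerated=1)
    n = int(arr.sum())
    log_n_fact = math.lgamma(n + 1)
    obs_lp = _log_table_prob(arr, row_m, col_m, log_n_fact)
    obs_prob = math.exp(obs_lp)

    # enumerate first-row cells; second row follows from the column margins
    r1 = int(row_m[0])
    ranges = [range(0, min(r1, int(c)) + 1) for c in col_m[:-1]]
    p = 0.0
    n_tables = 0
    for cells in product(*ranges):
        last = r1 - sum(cells)
        if last < 0 or last > col_m[-1]:
            continue
        first_row = np.array(cells + (last,))
        cand = np.vstack([first_row, col_m - first_row])
        n_tables += 1
        lp = _log_table_prob(cand, row_m, col_m, log_n_fact)
        if math.exp(lp) <= obs_prob * (1.0 + _TIE_RTOL):
            p += math.exp(lp)
    return ExactTestResult(p_value=min(p, 1.0), observed_table_prob=obs_prob,
                           n_tables_enumerated=n_tables)


def t_test_independent(x: Sequence[float], y: Sequence[float]
                       ) -> Tuple[float, float, float]:
    """Welch's two-sided independent-sample t test.

    Returns (t, df, p) with Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx = x.var(ddof=1) / x.size
    vy = y.var(ddof=1) / y.size
    if vx + vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both samples have zero variance with unequal means")
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1) + vy ** 2 / (y.size - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass(frozen=True)
class SurvivalCurve:
    """Stepwise event-free probability over time with at-risk counts.

    ``times`` starts at 0 with survival 1; subsequent entries are the
    distinct event times.
    """

    times: Tuple[float, ...]
    survival: Tuple[float, ...]
    at_risk: Tuple[int, ...]
    n_events: int
    n_censored: int


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times events precede censorings: subjects censored at t are
    still at risk for events at t.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")

    out_t = [0.0]
    out_s = [1.0]
    out_r = [int(t.size)]
    s = 1.0
    for ti in np.unique(t[e == 1]):
        n_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d / n_risk
        out_t.append(float(ti))
        out_s.append(s)
        out_r.append(n_risk)
    return SurvivalCurve(times=tuple(out_t), survival=tuple(out_s),
                         at_risk=tuple(out_r), n_events=int(e.sum()),
                         n_censored=int((1 - e).sum()))


def survival_at(curve: SurvivalCurve, horizon: float) -> float:
    """Step-function value of the KM curve at ``horizon``."""
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    idx = np.searchsorted(np.asarray(curve.times), horizon, side="right") - 1
    return curve.survival[idx]


def event_free_proportion(times: Sequence[float], events: Sequence[int],
                          horizon: float) -> float:
    """KM event-free probability at ``horizon`` months."""
    return survival_at(km_estimate(times, events), horizon)


def logrank_test(groups: Sequence[Tuple[Sequence[float], Sequence[int]]]
                 ) -> Tuple[float, int, float]:
    """K-group Mantel-Haenszel log-rank test.

    Returns (chi2, df, p) with df = K - 1.  The statistic is
    (O - E)' V^{-1} (O - E) over the first K-1 groups, with the usual
    hypergeometric covariance at each distinct event time.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ts, es, gs = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {gi} has zero subjects")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        ts.append(t)
        es.append(e)
        gs.append(np.full(t.size, gi))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(gs)

    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = at_risk.sum()
        d = int(np.sum((t == ti) & (e == 1)))
        n_g = np.array([np.sum(at_risk & (g == gi)) for gi in range(k)],
                       dtype=float)
        d_g = np.array([np.sum((t == ti) & (e == 1) & (g == gi))
                        for gi in range(k)], dtype=float)
        frac = n_g / n
        o_minus_e += d_g - d * frac
        if n > 1:
            mult = d * (n - d) / (n - 1)
            cov += mult * (np.diag(frac) - np.outer(frac, frac))

    v = cov[: k - 1, : k - 1]
    u = o_minus_e[: k - 1]
    chi2 = float(u @ np.linalg.pinv(v) @ u) if np.any(v) else 0.0
    df = k - 1
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p
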