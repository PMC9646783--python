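"""Reader-agreement, diagnostic-performance and association statistics.

Implements, from first principles, the statistics used to compare human
readers with the automated classifier on binary slide calls: majority-rule
consensus with a designated tie-break reader, Cohen's and Light's kappa,
the two-sided Fisher exact test for 2x2 tables (point-probability rule, the
convention of R's ``fisher.test``), sensitivity/specificity, "mean (SD)"
reporting with sample SD and half-away-from-zero integer rounding, and
Spearman rank correlation with a t-distribution p-value (exact permutation
p optional for small n).

Missing calls (e.g. insufficient remaining material) are excluded case-wise
per statistic, so per-marker denominators may differ.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "POS",
    "NEG",
    "MISSING",
    "RatingTable",
    "ContingencyTable2x2",
    "UndefinedStatisticError",
    "round_half_away",
    "majority_rule",
    "cohen_kappa",
    "light_kappa",
    "fisher_exact_2x2",
    "confusion_metrics",
    "mean_sd_report",
    "spearman",
]

POS = "POS"
NEG = "NEG"
MISSING = "MISSING"


class UndefinedStatisticError(ValueError):
    """Raised when a statistic has no defined value for the given data."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (83.5 -> 84)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class RatingTable:
    """Binary calls of several raters over the same cases.

    ``calls`` is a cases x raters DataFrame with values POS/NEG/MISSING.
    """

    calls: pd.DataFrame

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        df = pd.read_csv(path, index_col=0, dtype=str).fillna(MISSING)
        return cls(calls=df)

    @property
    def raters(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def cases(self) -> list[str]:
        return list(self.calls.index.astype(str))

    def pair(self, r1: str, r2: str) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise-complete call vectors for two raters."""
        a = self.calls[r1].to_numpy()
        b = self.calls[r2].to_numpy()
        keep = (a != MISSING) & (b != MISSING)
        return a[keep], b[keep]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = condition strata, columns = call."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")


def majority_rule(table: RatingTable, tiebreak_rater: str) -> pd.Series:
    """Per-case consensus call: strict majority, ties resolved by the
    designated rater; missing raters drop out of the count for that case."""
    if tiebreak_rater not in table.raters:
        raise ValueError(f"tie-break rater {tiebreak_rater!r} not in table")
    out = {}
    for case, row in table.calls.iterrows():
        votes = [v for v in row if v != MISSING]
        n_pos = votes.count(POS)
        n_neg = votes.count(NEG)
        if n_pos > n_neg:
            out[case] = POS
        elif n_neg > n_pos:
            out[case] = NEG
        else:
            tb = row[tiebreak_rater]
            if tb == MISSING:
                raise UndefinedStatisticError(
                    f"case {case!r}: votes tie and the tie-break rater's "
                    "call is missing")
            out[case] = tb
    return pd.Series(out, name="majority")


def _kappa_from_pair(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0:
        raise UndefinedStatisticError("no pairwise-complete cases")
    cats = (POS, NEG)
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = sum(float(np.mean(a == c)) * float(np.mean(b == c)) for c in cats)
    if p_e >= 1.0 - 1e-15:
        raise UndefinedStatisticError("chance agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def cohen_kappa(r1_calls, r2_calls) -> float:
    """Chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    """
    a = np.asarray(r1_calls, dtype=object)
    b = np.asarray(r2_calls, dtype=object)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    keep = (a != MISSING) & (b != MISSING)
    return _kappa_from_pair(a[keep], b[keep])


def light_kappa(table: RatingTable) -> float:
    """Light's kappa: the mean of all pairwise Cohen kappas.

    Pairs with an undefined kappa are excluded with a warning; with two
    raters this reduces to Cohen's kappa.
    """
    raters = table.raters
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    kappas = []
    for r1, r2 in itertools.combinations(raters, 2):
        try:
            kappas.append(_kappa_from_pair(*table.pair(r1, r2)))
        except UndefinedStatisticError:
            warnings.warn(f"kappa undefined for pair ({r1}, {r2}); excluded",
                          stacklevel=2)
    if not kappas:
        raise UndefinedStatisticError("every pairwise kappa is undefined")
    return float(np.mean(kappas))


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    With margins fixed, sums the hypergeometric point probabilities of every
    table whose probability does not exceed that of the observed table
    (within a 1e-7 relative slack for floating-point ties).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    # support of the top-left cell given the margins
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(xs, n, col1, row1)
    p_obs = sps.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def confusion_metrics(calls, truth) -> tuple[float, float]:
    """Sensitivity and specificity in percent; POS/1 is the positive class."""
    c = np.asarray([1 if v in (POS, 1, True) else 0 for v in calls])
    t = np.asarray([1 if v in (POS, 1, True) else 0 for v in truth])
    if t.min() == t.max():
        raise ValueError("truth must contain both classes")
    tp = int(np.sum((c == 1) & (t == 1)))
    fn = int(np.sum((c == 0) & (t == 1)))
    tn = int(np.sum((c == 0) & (t == 0)))
    fp = int(np.sum((c == 1) & (t == 0)))
    return 100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp)


def mean_sd_report(values) -> str:
    """'mean (SD)' with sample SD (n-1) and half-away-from-zero integers."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least two values for a mean (SD) report")
    return f"{round_half_away(v.mean())} ({round_half_away(np.std(v, ddof=1))})"


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise UndefinedStatisticError("constant input; rho undefined")
    return float(np.sum(rx * ry) / denom)


def spearman(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p.

    ``method='t'`` uses the t-distribution approximation with n-2 degrees of
    freedom (the default of mainstream correlation tests); ``'permutation'``
    enumerates all orderings exactly (n <= 8 only).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    rho = _spearman_rho(x, y)
    if method == "t":
        if abs(rho) >= 1.0:
            return rho, 0.0
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * float(sps.t.sf(abs(tstat), df=n - 2))
        return rho, min(p, 1.0)
    if method == "permutation":
        if n > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(x, y[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    raise ValueError("method must be 't' or 'permutation'")
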