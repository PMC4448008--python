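"""Two-library differential expression on digital counts.

Each miRNA is a 2x2 table [[a, Na-a], [b, Nb-b]] of its raw count against
the remaining clean reads of each library. The primary test is Fisher's
exact test (two-sided, summing hypergeometric probabilities of all tables
at most as probable as the observed one); a Pearson chi-squared 2x2 test
(no continuity correction) is reported alongside. Species with fewer than
10 raw reads in both libraries are excluded before testing;
Benjamini-Hochberg q-values are computed over the retained set, and a
species is called DE when fold change >= 2 and q <= 0.01 (both inclusive),
with fold change taken on normalized (per-million) values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DETestResult",
    "fisher_exact_2x2",
    "fisher_grid",
    "chi2_2x2",
    "bh_adjust",
    "call_de",
]

_TIE_REL = 1e-7  # tables within this relative pmf tolerance count as ties


def _check_table(a: int, b: int, Na: int, Nb: int) -> None:
    for v in (a, b, Na, Nb):
        if not isinstance(v, (int, np.integer)):
            raise ValueError(f"counts must be integers, got {v!r}")
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a > Na or b > Nb:
        raise ValueError("cell count exceeds its library total")


def fisher_exact_2x2(a: int, b: int, Na: int, Nb: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, Na-a], [b, Nb-b]].

    Computed in log space: hypergeometric log-pmf over the full support of
    K = a + b successes split between the two libraries, summing the
    probability of every table at most as probable as the observed one.
    """
    _check_table(a, b, Na, Nb)
    K = a + b
    if K == 0 or K == Na + Nb:
        return 1.0
    kmin = max(0, K - Nb)
    kmax = min(K, Na)
    k = np.arange(kmin, kmax + 1)
    logpmf = (
        gammaln(Na + 1) - gammaln(k + 1) - gammaln(Na - k + 1)
        + gammaln(Nb + 1) - gammaln(K - k + 1) - gammaln(Nb - K + k + 1)
        - (gammaln(Na + Nb + 1) - gammaln(K + 1) - gammaln(Na + Nb - K + 1))
    )
    obs = logpmf[a - kmin]
    sel = logpmf <= obs + math.log1p(_TIE_REL)
    m = logpmf.max()
    p = np.exp(logpmf - m)
    return float(min(1.0, p[sel].sum() / p.sum()))


@njit(cache=True)
def _fisher_grid_njit(Na: int, Nb: int, tie_rel: float):  # pragma: no cover
    out = np.ones((Na + 1, Nb + 1))
    lg = np.empty(Na + Nb + 2)
    lg[0] = 0.0
    for i in range(1, Na + Nb + 2):
        lg[i] = lg[i - 1] + math.log(i)
    # lg[i] = log(i!)
    for K in range(1, Na + Nb):
        kmin = max(0, K - Nb)
        kmax = min(K, Na)
        s = kmax - kmin + 1
        logpmf = np.empty(s)
        for idx in range(s):
            k = kmin + idx
            logpmf[idx] = (
                lg[Na] - lg[k] - lg[Na - k]
                + lg[Nb] - lg[K - k] - lg[Nb - K + k]
                - (lg[Na + Nb] - lg[K] - lg[Na + Nb - K])
            )
        m = logpmf.max()
        w = np.exp(logpmf - m)
        order = np.argsort(w)
        wsorted = w[order]
        cum = np.cumsum(wsorted)
        tot = cum[s - 1]
        for idx in range(s):
            thr = w[idx] * (1.0 + tie_rel)
            lo, hi = 0, s  # rightmost index with wsorted <= thr
            while lo < hi:
                mid = (lo + hi) // 2
                if wsorted[mid] <= thr:
                    lo = mid + 1
                else:
                    hi = mid
            p = cum[lo - 1] / tot if lo > 0 else 0.0
            a = kmin + idx
            out[a, K - a] = min(1.0, p)
    return out


def fisher_grid(Na: int, Nb: int) -> np.ndarray:
    """All two-sided Fisher p-values for margins (Na, Nb) as an (Na+1, Nb+1) array."""
    if Na < 0 or Nb < 0:
        raise ValueError("library totals must be non-negative")
    return _fisher_grid_njit(Na, Nb, _TIE_REL)


def chi2_2x2(a: int, b: int, Na: int, Nb: int) -> tuple[float, bool]:
    """Pearson chi-squared (1 df, no continuity correction) on the same table.

    Returns (p, unreliable); tables with any expected cell < 1 are flagged
    unreliable and given p = 1.
    """
    _check_table(a, b, Na, Nb)
    N = Na + Nb
    K = a + b
    if N == 0 or K == 0 or K == N:
        return 1.0, True
    obs = np.array([[a, Na - a], [b, Nb - b]], dtype=float)
    exp = np.outer([Na, Nb], [K, N - K]) / N
    if (exp < 1).any():
        return 1.0, True
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2_dist.sf(stat, 1)), False


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DETestResult:
    """Per-miRNA differential-expression test outcome."""

    name: str
    a: int
    b: int
    Na: int
    Nb: int
    na: float
    nb: float
    fold_change: float
    p_fisher: float | None
    p_chi2: float | None
    chi2_unreliable: bool
    q: float | None
    call: str  # up-in-B | down-in-B | not-DE | excluded-low-abundance


def _fold_change(na: float, nb: float, pseudo: float = 0.5) -> float:
    """Fold change on normalized values; a zero side gets a 0.5-unit pseudocount."""
    x = na if na > 0 else pseudo
    y = nb if nb > 0 else pseudo
    return max(x, y) / min(x, y)


def call_de(
    names: Sequence[str],
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    total_a: int,
    total_b: int,
    fc_min: float = 2.0,
    q_max: float = 0.01,
    min_raw: int = 10,
) -> list[DETestResult]:
    """Run the two-test DE procedure over a table of per-miRNA counts.

    Species with raw counts < *min_raw* in both libraries are excluded
    first; BH adjustment runs over the retained set only. Tests use raw
    counts with library clean totals as margins; fold change and direction
    use per-million normalized values.
    """
    results: list[DETestResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for i, name in enumerate(names):
        a, b = int(counts_a[i]), int(counts_b[i])
        na = a * 1e6 / total_a if total_a else 0.0
        nb = b * 1e6 / total_b if total_b else 0.0
        fc = _fold_change(na, nb)
        if a < min_raw and b < min_raw:
            results.append(
                DETestResult(name, a, b, total_a, total_b, na, nb, fc,
                             None, None, True, None, "excluded-low-abundance")
            )
            continue
        pf = fisher_exact_2x2(a, b, total_a, total_b)
        pc, unreliable = chi2_2x2(a, b, total_a, total_b)
        results.append(
            DETestResult(name, a, b, total_a, total_b, na, nb, fc,
                         pf, pc, unreliable, None, "not-DE")
        )
        tested_idx.append(len(results) - 1)
        pvals.append(pf)
    if tested_idx:
        qvals = bh_adjust(pvals)
        for idx, q in zip(tested_idx, qvals):
            r = results[idx]
            r.q = float(q)
            if r.fold_change >= fc_min and r.q <= q_max:
                r.call = "up-in-B" if r.nb > r.na else "down-in-B"
    return results
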