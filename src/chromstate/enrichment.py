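"""Region-overlap association statistics.

The hypergeometric overlap test asks: drawing ``n`` regions from a
universe of ``N`` of which ``K`` are marked, how surprising is observing
``k`` or more marked regions among the draw?  The tail sum is evaluated
in log space (log-gamma terms combined with logsumexp) so that p-values
far below double underflow in a naive product — the headline use case is
of order 1e-90 — remain exact, and the log10 of the p-value is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .intervals import IntervalSet, merge

__all__ = ["OverlapTestResult", "hypergeom_upper_tail", "count_region_overlap"]


@dataclass(frozen=True)
class OverlapTestResult:
    """Upper-tail hypergeometric overlap test."""

    universe_n: int
    marked_k: int
    drawn_n: int
    observed_k: int
    expected: float
    p_upper: float
    log10_p: float
    tail: str = "geq"


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(
    N: int, K: int, n: int, k: int, tail: str = "geq"
) -> OverlapTestResult:
    """Upper-tail probability of the hypergeometric overlap.

    ``tail="geq"`` (default) gives the standard p-value
    ``P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n)``;
    ``tail="gt"`` gives the strictly-greater tail ``P(X > k)``, the
    convention of R's ``phyper(..., lower.tail=FALSE)``, provided for
    reproducing results computed that way.

    The sum is evaluated with log-gamma terms, so extreme tails keep full
    relative precision; ``log10_p`` carries the magnitude for values that
    would underflow in downstream output files.
    """
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}, min={min(n, K)}")
    if tail not in ("geq", "gt"):
        raise ValueError(f"unknown tail {tail!r}")
    lo = k + 1 if tail == "gt" else k
    hi = min(n, K)
    if lo > hi:  # empty strict tail: P(X > min(n, K)) = 0 exactly
        log_p = -np.inf
    else:
        i = np.arange(lo, hi + 1)
        log_terms = (
            _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
        )
        log_p = float(logsumexp(log_terms))
    log_p = min(log_p, 0.0)
    p = float(np.exp(log_p))
    return OverlapTestResult(
        universe_n=N,
        marked_k=K,
        drawn_n=n,
        observed_k=k,
        expected=n * K / N if N else 0.0,
        p_upper=p,
        log10_p=log_p / np.log(10.0),
        tail=tail,
    )


def count_region_overlap(
    query: IntervalSet, reference: IntervalSet, min_bp: int = 1
) -> int:
    """Number of query intervals overlapping the reference by >= min_bp.

    Each query interval counts at most once however many reference
    intervals it touches; overlap bp against the merged reference is
    accumulated per query interval before the threshold is applied.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    ref = merge(reference)
    count = 0
    for chrom in query.chroms():
        rs, re_ = ref.by_chrom(chrom)
        if len(rs) == 0:
            continue
        qs, qe = query.by_chrom(chrom)
        for s, e in zip(qs, qe):
            # reference intervals that can overlap [s, e)
            i0 = int(np.searchsorted(re_, s, side="right"))
            i1 = int(np.searchsorted(rs, e, side="left"))
            ov = 0
            for i in range(i0, i1):
                ov += min(int(e), int(re_[i])) - max(int(s), int(rs[i]))
                if ov >= min_bp:
                    count += 1
                    break
    return count
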