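"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: interval algebra
is checked against explicit per-bp membership sets, and HMM quantities
against explicit enumeration of every hidden-state path.
"""

from __future__ import annotations

import itertools

import numpy as np

from chromstate import IntervalSet


# -- per-bp interval membership ---------------------------------------------


def bp_set(s: IntervalSet) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for iv in s:
        for p in range(iv.start, iv.end):
            out.add((iv.chrom, p))
    return out


def bp_jaccard(a: IntervalSet, b: IntervalSet) -> float:
    sa, sb = bp_set(a), bp_set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


# -- explicit path enumeration for small HMMs --------------------------------


def _emission_prob(emission: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(K,) probability of one binary observation row under each state."""
    return np.prod(emission**x * (1.0 - emission) ** (1.0 - x), axis=1)


def enumerate_paths(start, trans, emission, X):
    """Yield (path, joint probability) over all K^T hidden paths."""
    T = X.shape[0]
    K = len(start)
    frame = np.array([_emission_prob(emission, X[t]) for t in range(T)])
    for path in itertools.product(range(K), repeat=T):
        p = start[path[0]] * frame[0, path[0]]
        for t in range(1, T):
            p *= trans[path[t - 1], path[t]] * frame[t, path[t]]
        yield path, p


def enum_loglik(start, trans, emission, X) -> float:
    return float(np.log(sum(p for _, p in enumerate_paths(start, trans, emission, X))))


def enum_posteriors(start, trans, emission, X) -> np.ndarray:
    T = X.shape[0]
    K = len(start)
    post = np.zeros((T, K))
    total = 0.0
    for path, p in enumerate_paths(start, trans, emission, X):
        total += p
        for t, k in enumerate(path):
            post[t, k] += p
    return post / total


def enum_viterbi(start, trans, emission, X) -> tuple[tuple[int, ...], float]:
    """(best path, best log joint); ties broken to the lexicographically
    smallest path, matching a smallest-index tie-break."""
    paths = list(enumerate_paths(start, trans, emission, X))
    mx = max(p for _, p in paths)
    ties = [path for path, p in paths if p >= mx * (1 - 1e-12)]
    return min(ties), float(np.log(mx))


def random_hmm(rng: np.random.Generator, K: int, M: int):
    start = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K), size=K)
    emission = rng.uniform(0.05, 0.95, size=(K, M))
    return start, trans, emission
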