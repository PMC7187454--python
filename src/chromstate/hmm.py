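"""Multivariate Bernoulli hidden-Markov chromatin-state model.

The genome is modelled as a first-order Markov chain over K hidden
chromatin states; in state k each of M histone marks is present in a bin
independently with probability ``emission[k, m]`` (a product-Bernoulli
observation model).  Chains are independent per chromosome, each
restarting from the initial distribution.  Training is Baum-Welch EM
with per-position scaled forward-backward recursions; the training
log-likelihood is accumulated from the scaling factors and is
non-decreasing over iterations.

:class:`BernoulliHMM` is a scikit-learn-style estimator (``fit`` /
``predict`` / ``predict_proba`` / ``score``); the module-level functions
(:func:`fit_model`, :func:`viterbi_decode`, :func:`posterior_marginals`,
:func:`select_state_count`, :func:`label_states`) are thin wrappers that
operate on the portable :class:`ChromatinStateModel` container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .layout import GenomeLayout
from .segmentation import Segmentation

__all__ = [
    "ChromatinStateModel",
    "BernoulliHMM",
    "fit_model",
    "viterbi_decode",
    "posterior_marginals",
    "select_state_count",
    "StateCountReport",
    "label_states",
    "LabelRule",
    "DEFAULT_LABEL_RULES",
    "match_states",
    "read_model_tsv",
    "write_model_tsv",
]

_PROB_TOL = 1e-9
_EM_CLIP = 1e-10


# ---------------------------------------------------------------------------
# numba kernels: scaled forward/backward, transition stats, Viterbi
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward_scaled(startprob, transmat, frameprob, alpha, c):
    T, K = frameprob.shape
    for k in range(K):
        alpha[0, k] = startprob[k] * frameprob[0, k]
    s = 0.0
    for k in range(K):
        s += alpha[0, k]
    if s <= 0.0:
        s = 1e-300
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * transmat[i, j]
            a *= frameprob[t, j]
            alpha[t, j] = a
            s += a
        if s <= 0.0:
            s = 1e-300
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s


@njit(cache=True)
def _backward_scaled(transmat, frameprob, c, beta):
    T, K = frameprob.shape
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            b = 0.0
            for j in range(K):
                b += transmat[i, j] * frameprob[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / c[t + 1]


@njit(cache=True)
def _xi_sum(alpha, beta, c, transmat, frameprob, xi):
    T, K = frameprob.shape
    for t in range(T - 1):
        for i in range(K):
            ai = alpha[t, i]
            for j in range(K):
                xi[i, j] += (
                    ai
                    * transmat[i, j]
                    * frameprob[t + 1, j]
                    * beta[t + 1, j]
                    / c[t + 1]
                )


@njit(cache=True)
def _viterbi_path(log_start, log_trans, log_frame):
    T, K = log_frame.shape
    delta = np.empty(K)
    newdelta = np.empty(K)
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[k] = log_start[k] + log_frame[0, k]
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[i] + log_trans[i, j]
                if v > best:  # strict: smallest predecessor index wins ties
                    best = v
                    arg = i
            newdelta[j] = best + log_frame[t, j]
            psi[t, j] = arg
        for j in range(K):
            delta[j] = newdelta[j]
    best = -np.inf
    last = 0
    for k in range(K):
        if delta[k] > best:  # strict: smallest final index wins ties
            best = delta[k]
            last = k
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = last
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


# ---------------------------------------------------------------------------
# portable model container
# ---------------------------------------------------------------------------


@dataclass
class ChromatinStateModel:
    """Initial, transition and per-mark Bernoulli emission parameters."""

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    mark_names: tuple[str, ...]
    state_labels: tuple[str, ...]
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.emission = np.asarray(self.emission, dtype=np.float64)
        self.mark_names = tuple(self.mark_names)
        self.state_labels = tuple(self.state_labels)
        K, M = self.emission.shape
        if self.initial.shape != (K,) or self.transition.shape != (K, K):
            raise ValueError("parameter shapes inconsistent")
        if len(self.mark_names) != M or len(self.state_labels) != K:
            raise ValueError("name lists inconsistent with parameter shapes")
        if len(set(self.state_labels)) != K:
            raise ValueError("state labels must be unique")
        if abs(self.initial.sum() - 1.0) > _PROB_TOL:
            raise ValueError("initial distribution does not sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1.0).max() > _PROB_TOL:
            raise ValueError("transition rows do not sum to 1")
        if self.emission.min() < 0 or self.emission.max() > 1:
            raise ValueError("emission probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.emission.shape[0]

    @property
    def n_marks(self) -> int:
        return self.emission.shape[1]


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


def _validate_obs(X: np.ndarray, lengths: Sequence[int] | None):
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("observations must be a 2-D (bins x marks) matrix")
    if X.size and not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("observations must be binary (0/1)")
    if lengths is None:
        lengths = [X.shape[0]]
    lengths = [int(l) for l in lengths]
    if sum(lengths) != X.shape[0]:
        raise ValueError("lengths do not sum to the number of rows")
    if any(l < 1 for l in lengths):
        raise ValueError("every chain must have at least one bin")
    return X, lengths


def _chain_slices(lengths: Sequence[int]):
    off = 0
    for l in lengths:
        yield slice(off, off + l)
        off += l


def _frame_logprob(X: np.ndarray, emission: np.ndarray) -> np.ndarray:
    e = np.clip(emission, _EM_CLIP, 1.0 - _EM_CLIP)
    return X @ np.log(e).T + (1.0 - X) @ np.log1p(-e).T


class BernoulliHMM(BaseEstimator):
    """Hidden Markov model with independent Bernoulli emissions per mark.

    Parameters
    ----------
    n_states
        Number of hidden chromatin states K.
    max_iter, tol
        Baum-Welch stopping rule: stop after ``max_iter`` iterations or
        when the total log-likelihood improves by less than ``tol``.
    random_state
        Seed controlling emission initialization (k-means on a bin
        subsample plus jitter).
    self_weight
        Initial self-transition probability; the remainder is spread
        uniformly over the other states.
    n_init_subsample
        Maximum number of bins fed to the k-means seeding step.

    Attributes
    ----------
    startprob_, transmat_, emissionprob_ : fitted parameters.
    loglik_ : final training log-likelihood.
    history_ : per-iteration log-likelihoods.
    n_iter_ : iterations actually run.
    """

    def __init__(
        self,
        n_states: int = 2,
        max_iter: int = 200,
        tol: float = 1e-4,
        random_state: int | None = 0,
        self_weight: float = 0.9,
        n_init_subsample: int = 10_000,
        init_params: tuple | None = None,
    ):
        self.n_states = n_states
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.self_weight = self_weight
        self.n_init_subsample = n_init_subsample
        self.init_params = init_params

    # -- initialization -----------------------------------------------------

    def _init_params(self, X: np.ndarray, rng: np.random.Generator):
        K = self.n_states
        if self.init_params is not None:
            start, trans, emis = (np.array(a, dtype=np.float64) for a in self.init_params)
            return start, trans, np.clip(emis, _EM_CLIP, 1 - _EM_CLIP)
        M = X.shape[1]
        start = np.full(K, 1.0 / K)
        if K == 1:
            trans = np.ones((1, 1))
        else:
            off = (1.0 - self.self_weight) / (K - 1)
            trans = np.full((K, K), off)
            np.fill_diagonal(trans, self.self_weight)
        n_sub = min(self.n_init_subsample, X.shape[0])
        sub = X[rng.choice(X.shape[0], size=n_sub, replace=False)]
        if K > 1 and len(np.unique(sub, axis=0)) >= K:
            km = KMeans(
                n_clusters=K,
                n_init=3,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(sub)
            emis = km.cluster_centers_
        else:
            emis = rng.uniform(0.25, 0.75, size=(K, M))
        emis = emis + rng.uniform(-0.02, 0.02, size=(K, M))
        return start, trans, np.clip(emis, 0.02, 0.98)

    # -- EM -----------------------------------------------------------------

    def fit(self, X, lengths: Sequence[int] | None = None) -> "BernoulliHMM":
        X, lengths = _validate_obs(X, lengths)
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_states > X.shape[0]:
            raise ValueError("n_states exceeds the number of bins")
        rng = np.random.default_rng(self.random_state)
        start, trans, emis = self._init_params(X, rng)

        history: list[float] = []
        prev_ll = -np.inf
        for _ in range(max(1, self.max_iter)):
            ll, start_acc, xi_acc, em_num, em_den = self._e_step(
                X, lengths, start, trans, emis
            )
            history.append(ll)
            # M-step
            start = start_acc / start_acc.sum()
            row = xi_acc.sum(axis=1, keepdims=True)
            trans = np.where(row > 0, xi_acc / np.where(row > 0, row, 1.0), trans)
            emis = np.where(
                em_den[:, None] > 0,
                em_num / np.where(em_den[:, None] > 0, em_den[:, None], 1.0),
                emis,
            )
            emis = np.clip(emis, _EM_CLIP, 1.0 - _EM_CLIP)
            if ll - prev_ll < self.tol and np.isfinite(prev_ll):
                break
            prev_ll = ll

        self.startprob_ = start
        self.transmat_ = trans
        self.emissionprob_ = emis
        self.history_ = np.array(history)
        self.loglik_ = history[-1]
        self.n_iter_ = len(history)
        self.n_features_in_ = X.shape[1]
        return self

    def _e_step(self, X, lengths, start, trans, emis):
        K = self.n_states
        frame = np.exp(_frame_logprob(X, emis))
        ll = 0.0
        start_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        em_num = np.zeros((K, X.shape[1]))
        em_den = np.zeros(K)
        for sl in _chain_slices(lengths):
            fp = np.ascontiguousarray(frame[sl])
            T = fp.shape[0]
            alpha = np.empty((T, K))
            beta = np.empty((T, K))
            c = np.empty(T)
            _forward_scaled(start, trans, fp, alpha, c)
            _backward_scaled(trans, fp, c, beta)
            gamma = alpha * beta
            gamma /= np.maximum(gamma.sum(axis=1, keepdims=True), 1e-300)
            ll += float(np.log(c).sum())
            start_acc += gamma[0]
            if T > 1:
                _xi_sum(alpha, beta, c, trans, fp, xi_acc)
            em_num += gamma.T @ X[sl]
            em_den += gamma.sum(axis=0)
        return ll, start_acc, xi_acc, em_num, em_den

    # -- inference ----------------------------------------------------------

    def _check_fitted_obs(self, X, lengths):
        if not hasattr(self, "emissionprob_"):
            raise AttributeError("estimator is not fitted")
        X, lengths = _validate_obs(X, lengths)
        if X.shape[1] != self.emissionprob_.shape[1]:
            raise ValueError(
                f"observation has {X.shape[1]} marks, model has "
                f"{self.emissionprob_.shape[1]}"
            )
        return X, lengths

    def score(self, X, lengths: Sequence[int] | None = None) -> float:
        """Total log-likelihood of the observations under the fitted model."""
        X, lengths = self._check_fitted_obs(X, lengths)
        frame = np.exp(_frame_logprob(X, self.emissionprob_))
        ll = 0.0
        for sl in _chain_slices(lengths):
            fp = np.ascontiguousarray(frame[sl])
            T = fp.shape[0]
            alpha = np.empty((T, self.n_states))
            c = np.empty(T)
            _forward_scaled(self.startprob_, self.transmat_, fp, alpha, c)
            ll += float(np.log(c).sum())
        return ll

    def predict_proba(self, X, lengths: Sequence[int] | None = None) -> np.ndarray:
        """Posterior state marginals per bin (rows sum to 1)."""
        X, lengths = self._check_fitted_obs(X, lengths)
        frame = np.exp(_frame_logprob(X, self.emissionprob_))
        out = np.empty((X.shape[0], self.n_states))
        for sl in _chain_slices(lengths):
            fp = np.ascontiguousarray(frame[sl])
            T = fp.shape[0]
            alpha = np.empty((T, self.n_states))
            beta = np.empty((T, self.n_states))
            c = np.empty(T)
            _forward_scaled(self.startprob_, self.transmat_, fp, alpha, c)
            _backward_scaled(self.transmat_, fp, c, beta)
            gamma = alpha * beta
            gamma /= np.maximum(gamma.sum(axis=1, keepdims=True), 1e-300)
            out[sl] = gamma
        return out

    def predict(self, X, lengths: Sequence[int] | None = None) -> np.ndarray:
        """Most probable state path (Viterbi) per chain.

        Ties are broken toward the smallest state index, making the
        decoding deterministic.
        """
        X, lengths = self._check_fitted_obs(X, lengths)
        with np.errstate(divide="ignore"):
            log_start = np.log(self.startprob_)
            log_trans = np.log(self.transmat_)
            log_frame = _frame_logprob(X, self.emissionprob_)
        out = np.empty(X.shape[0], dtype=np.int64)
        for sl in _chain_slices(lengths):
            path, _ = _viterbi_path(
                log_start, log_trans, np.ascontiguousarray(log_frame[sl])
            )
            out[sl] = path
        return out

    # -- interop ------------------------------------------------------------

    def to_model(
        self,
        mark_names: Sequence[str] | None = None,
        state_labels: Sequence[str] | None = None,
    ) -> ChromatinStateModel:
        if mark_names is None:
            mark_names = [f"mark{m}" for m in range(self.emissionprob_.shape[1])]
        if state_labels is None:
            state_labels = [f"S{k}" for k in range(self.n_states)]
        return ChromatinStateModel(
            initial=self.startprob_,
            transition=self.transmat_,
            emission=self.emissionprob_,
            mark_names=tuple(mark_names),
            state_labels=tuple(state_labels),
            log_likelihood=self.loglik_,
        )

    @classmethod
    def from_model(cls, model: ChromatinStateModel) -> "BernoulliHMM":
        est = cls(n_states=model.n_states)
        est.startprob_ = model.initial
        est.transmat_ = model.transition
        est.emissionprob_ = model.emission
        est.loglik_ = model.log_likelihood
        est.n_features_in_ = model.n_marks
        return est


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def fit_model(
    obs: np.ndarray,
    K: int,
    lengths: Sequence[int] | None = None,
    seed: int | None = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    mark_names: Sequence[str] | None = None,
) -> ChromatinStateModel:
    """Baum-Welch fit of a K-state product-Bernoulli HMM.

    ``lengths`` gives the per-chromosome bin counts (chains restart from
    the initial distribution at each chromosome).
    """
    est = BernoulliHMM(n_states=K, max_iter=max_iter, tol=tol, random_state=seed)
    est.fit(obs, lengths)
    return est.to_model(mark_names=mark_names)


def viterbi_decode(
    model: ChromatinStateModel,
    obs: np.ndarray,
    layout: GenomeLayout,
) -> Segmentation:
    """Per-chromosome most-probable state path as a :class:`Segmentation`."""
    est = BernoulliHMM.from_model(model)
    states = est.predict(obs, lengths=layout.chain_lengths())
    return Segmentation(layout, states, model.state_labels)


def posterior_marginals(
    model: ChromatinStateModel,
    obs: np.ndarray,
    lengths: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-bin posterior state probabilities (each row sums to 1)."""
    return BernoulliHMM.from_model(model).predict_proba(obs, lengths)


# -- state-count selection --------------------------------------------------


@dataclass
class StateCountReport:
    """Per-K training log-likelihood and emission-redundancy score."""

    K_values: list[int]
    log_likelihoods: list[float]
    redundancies: list[float]
    recommended_K: int
    models: dict[int, ChromatinStateModel] = field(default_factory=dict)


def emission_redundancy(emission: np.ndarray) -> float:
    """Max Pearson correlation between any two emission rows (0 for K=1).

    Rows with (numerically) zero variance correlate 1 with an equal
    constant row and 0 with anything else.
    """
    K = emission.shape[0]
    if K < 2:
        return 0.0
    best = -np.inf
    for i in range(K):
        for j in range(i + 1, K):
            a, b = emission[i], emission[j]
            sa, sb = a.std(), b.std()
            if sa < 1e-12 or sb < 1e-12:
                r = 1.0 if np.abs(a - b).max() < 1e-6 else 0.0
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            best = max(best, r)
    return float(best)


def select_state_count(
    obs: np.ndarray,
    K_range: Sequence[int],
    seed: int | None = 0,
    lengths: Sequence[int] | None = None,
    redundancy_threshold: float = 0.95,
    **fit_kwargs,
) -> StateCountReport:
    """Train one model per K and recommend a state count.

    The redundancy score of a model is the maximum Pearson correlation
    between any two emission rows; the recommended K is the largest K in
    the range whose redundancy stays at or below the threshold — the
    operational form of "increase K until states stop separating".
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    if sorted(K_range) != K_range:
        raise ValueError("K_range must be ascending")
    lls, reds, models = [], [], {}
    for K in K_range:
        m = fit_model(obs, K, lengths=lengths, seed=seed, **fit_kwargs)
        models[K] = m
        lls.append(m.log_likelihood)
        reds.append(emission_redundancy(m.emission))
    ok = [K for K, r in zip(K_range, reds) if r <= redundancy_threshold]
    if ok:
        rec = max(ok)
    else:
        rec = K_range[0]
        warnings.warn(
            "no K in range met the redundancy threshold; recommending the smallest"
        )
    return StateCountReport(K_range, lls, reds, rec, models)


# -- semantic state labelling ----------------------------------------------


@dataclass(frozen=True)
class LabelRule:
    """One labelling rule: fires when every emission bound holds.

    ``min_emission`` maps mark name -> inclusive lower bound; ``max_emission``
    maps mark name -> exclusive upper bound.  The wildcard mark ``"*"``
    applies the bound to every mark in the model.
    """

    name: str
    min_emission: dict = field(default_factory=dict)
    max_emission: dict = field(default_factory=dict)


DEFAULT_LABEL_RULES: tuple[LabelRule, ...] = (
    LabelRule("TssS", min_emission={"H3K4me3": 0.5}),
    LabelRule("EnhS", min_emission={"H3K4me1": 0.5, "H3K27ac": 0.5}),
    LabelRule("EnhW", min_emission={"H3K4me1": 0.5}),
    LabelRule("Tx", min_emission={"H3K36me3": 0.5}),
    LabelRule("ReprPC", min_emission={"H3K27me3": 0.5}),
    LabelRule("Quies", max_emission={"*": 0.2}),
)


def label_states(
    model: ChromatinStateModel,
    rules: Sequence[LabelRule] = DEFAULT_LABEL_RULES,
    fallback: str = "Mixed",
) -> ChromatinStateModel:
    """Assign semantic labels to states from their emission profiles.

    Rules are applied in priority order; the first rule whose bounds all
    hold names the state.  Labels get a 1-based state-index prefix
    (``"13_EnhS"`` style) so they are unique.
    """
    marks = list(model.mark_names)
    for rule in rules:
        for key in list(rule.min_emission) + list(rule.max_emission):
            if key != "*" and key not in marks:
                raise KeyError(
                    f"rule {rule.name!r} references unknown mark {key!r}; "
                    f"model marks: {marks}"
                )
    labels = []
    for k in range(model.n_states):
        e = {m: model.emission[k, i] for i, m in enumerate(marks)}
        name = fallback
        for rule in rules:
            ok = True
            for mk, lo in rule.min_emission.items():
                vals = e.values() if mk == "*" else [e[mk]]
                ok &= all(v >= lo for v in vals)
            for mk, hi in rule.max_emission.items():
                vals = e.values() if mk == "*" else [e[mk]]
                ok &= all(v < hi for v in vals)
            if ok:
                name = rule.name
                break
        labels.append(f"{k + 1}_{name}")
    return replace(model, state_labels=tuple(labels))


# -- utilities ---------------------------------------------------------------


def match_states(emission_true: np.ndarray, emission_est: np.ndarray) -> np.ndarray:
    """Optimal state matching between two emission matrices.

    Returns ``perm`` such that ``emission_est[perm[k]]`` corresponds to
    true state ``k``, minimizing total L1 emission distance (Hungarian
    assignment).
    """
    cost = np.abs(
        emission_true[:, None, :] - emission_est[None, :, :]
    ).sum(axis=2)
    _, perm = linear_sum_assignment(cost)
    return perm


# -- model TSV round-trip -----------------------------------------------------


def write_model_tsv(model: ChromatinStateModel, path: str | Path) -> None:
    """Plain-TSV model file, bit-exactly round-trippable (``%.17g`` floats)."""

    def fmt(xs):
        return "\t".join(f"{x:.17g}" for x in xs)

    with Path(path).open("w") as fh:
        fh.write("#chromstate model v1\n")
        fh.write(f"n_states\t{model.n_states}\n")
        fh.write(f"n_marks\t{model.n_marks}\n")
        fh.write(f"log_likelihood\t{model.log_likelihood:.17g}\n")
        fh.write("marks\t" + "\t".join(model.mark_names) + "\n")
        fh.write("labels\t" + "\t".join(model.state_labels) + "\n")
        fh.write("initial\t" + fmt(model.initial) + "\n")
        for row in model.transition:
            fh.write("transition\t" + fmt(row) + "\n")
        for row in model.emission:
            fh.write("emission\t" + fmt(row) + "\n")


def read_model_tsv(path: str | Path) -> ChromatinStateModel:
    fields: dict[str, list[list[str]]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, *rest = line.split("\t")
            fields.setdefault(key, []).append(rest)
    K = int(fields["n_states"][0][0])
    M = int(fields["n_marks"][0][0])
    model = ChromatinStateModel(
        initial=np.array([float(x) for x in fields["initial"][0]]),
        transition=np.array(
            [[float(x) for x in row] for row in fields["transition"]]
        ),
        emission=np.array([[float(x) for x in row] for row in fields["emission"]]),
        mark_names=tuple(fields["marks"][0]),
        state_labels=tuple(fields["labels"][0]),
        log_likelihood=float(fields["log_likelihood"][0][0]),
    )
    if model.n_states != K or model.n_marks != M:
        raise ValueError("model file header inconsistent with matrix blocks")
    return model
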