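"""Ground-truth simulators for every stage of the pipeline.

The generators emit inputs with the statistical structure the analysis
assumes, so each downstream stage can be tested against known truth
without any external data:

* a hidden chromatin-state chain per chromosome (first-order Markov,
  restarting at chromosome boundaries) and per-bin binary mark calls
  emitted from it (product Bernoulli),
* a paired-condition segmentation generated by resampling each bin's
  state from a per-state flow distribution,
* array-style CpG methylation tables whose demethylation probability
  depends on the destination chromatin state,
* enhancer sequence sets with a motif planted at class-specific rates,
* replicate enhancer maps in two groups for similarity clustering.

One global seed is expanded into independent per-generator substreams by
a fixed scheme (SeedSequence spawn keys derived from a CRC32 of a stage
label), so regenerating one stage never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binarize import BinaryMarkTrack
from .intervals import IntervalSet
from .layout import GenomeLayout
from .methylation import CpGTable
from .motifs import MotifPWM
from .segmentation import Segmentation

__all__ = [
    "SimulationConfig",
    "default_config",
    "substream",
    "simulate_state_chain",
    "simulate_marks",
    "simulate_condition_pair",
    "simulate_methylation",
    "simulate_enhancer_sequences",
    "simulate_enhancer_replicates",
    "DEFAULT_MARKS",
    "DEFAULT_STATES",
    "SOX9_LIKE_PWM",
]

DEFAULT_MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "H3K36me3")
DEFAULT_STATES = ("TssS", "EnhS", "EnhW", "Tx", "ReprPC", "Quies")
_CODE_ACGT = {b: i for i, b in enumerate("ACGT")}

# Synthetic SOX9-like PWM: a sharp AACAAT core (the conserved SOX
# half-site) plus one flanking position.  A stand-in constructed for
# testing, not a database matrix.  Sharp enough that, at the default
# 60%-of-max scan threshold, only the exact consensus scores as a hit.
def _consensus_pwm(name: str, consensus: str, p: float = 0.97) -> MotifPWM:
    off = (1.0 - p) / 3.0
    mat = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus):
        mat[i, "ACGT".index(base)] = p
    return MotifPWM(name=name, matrix=mat)


SOX9_LIKE_PWM = _consensus_pwm("SOX9_like_synthetic", "AACAATG")


def _default_emission() -> np.ndarray:
    # rows = DEFAULT_STATES, columns = DEFAULT_MARKS
    return np.array(
        [
            [0.90, 0.30, 0.55, 0.02, 0.10],  # TssS
            [0.05, 0.90, 0.85, 0.02, 0.10],  # EnhS
            [0.05, 0.80, 0.10, 0.05, 0.05],  # EnhW
            [0.02, 0.10, 0.05, 0.02, 0.90],  # Tx
            [0.02, 0.10, 0.02, 0.85, 0.02],  # ReprPC
            [0.01, 0.02, 0.02, 0.05, 0.01],  # Quies
        ]
    )


def _sticky_matrix(K: int, self_weight: float) -> np.ndarray:
    if K == 1:
        return np.ones((1, 1))
    off = (1.0 - self_weight) / (K - 1)
    t = np.full((K, K), off)
    np.fill_diagonal(t, self_weight)
    return t


def _derive_flow(state_names: tuple[str, ...]) -> np.ndarray:
    # mostly stable states; quiescent and repressed chromatin feeds the
    # strong enhancer state, emulating differentiation-driven enhancer gain
    K = len(state_names)
    flow = _sticky_matrix(K, 0.90)
    if "EnhS" in state_names and K > 1:
        e = state_names.index("EnhS")
        for src in ("Quies", "ReprPC"):
            if src not in state_names:
                continue
            i = state_names.index(src)
            flow[i] = (1.0 - 0.82 - 0.10) / max(K - 2, 1)
            flow[i, i] = 0.82
            flow[i, e] = 0.10
    return flow


def _derive_demeth(state_names: tuple[str, ...]) -> np.ndarray:
    # demethylation concentrates in the strong enhancer state; weakly
    # elevated at promoters/weak enhancers, near baseline elsewhere
    rates = {"EnhS": 0.40, "TssS": 0.05, "EnhW": 0.05, "Quies": 0.01}
    return np.array([rates.get(s, 0.02) for s in state_names])


@dataclass
class SimulationConfig:
    """All ground-truth parameters for the synthetic study.

    Probability rows (transition, flow, emission rows, initial) are
    validated at construction; identical seeds reproduce all outputs
    bit-identically.
    """

    layout: GenomeLayout = field(
        default_factory=lambda: GenomeLayout(
            chrom_names=tuple(f"chr{i + 1}" for i in range(4)),
            chrom_lengths=(10_000_000,) * 4,
            bin_size=200,
        )
    )
    state_names: tuple[str, ...] = DEFAULT_STATES
    mark_names: tuple[str, ...] = DEFAULT_MARKS
    emission_truth: np.ndarray | None = None
    transition_truth: np.ndarray | None = None
    initial_truth: np.ndarray | None = None
    flow_truth: np.ndarray | None = None
    seed: int = 0
    cpg_density: float = 0.5  # sites per kb; scaled for desk-size genomes
    demeth_prob_by_state: np.ndarray | None = None
    demeth_effect: float = 0.3
    beta_noise_sd: float = 0.02
    hyper_prob: float = 0.002  # small hypermethylation rate (most changes are hypo)
    motif_pwm: MotifPWM = SOX9_LIKE_PWM
    motif_plant_rate_new: float = 0.6
    motif_plant_rate_constant: float = 0.1

    def __post_init__(self) -> None:
        # unspecified truth parameters derive from the state list
        K = self.n_states
        if self.emission_truth is None:
            if self.state_names != DEFAULT_STATES:
                raise ValueError("emission_truth required for custom state names")
            self.emission_truth = _default_emission()
        if self.transition_truth is None:
            self.transition_truth = _sticky_matrix(K, 0.90)
        if self.initial_truth is None:
            self.initial_truth = np.full(K, 1.0 / K)
        if self.flow_truth is None:
            self.flow_truth = _derive_flow(self.state_names)
        if self.demeth_prob_by_state is None:
            self.demeth_prob_by_state = _derive_demeth(self.state_names)
        self.emission_truth = np.asarray(self.emission_truth, dtype=np.float64)
        self.transition_truth = np.asarray(self.transition_truth, dtype=np.float64)
        self.initial_truth = np.asarray(self.initial_truth, dtype=np.float64)
        self.flow_truth = np.asarray(self.flow_truth, dtype=np.float64)
        self.demeth_prob_by_state = np.asarray(
            self.demeth_prob_by_state, dtype=np.float64
        )
        K, M = self.n_states, self.n_marks
        if self.emission_truth.shape != (K, M):
            raise ValueError("emission_truth shape inconsistent with names")
        for name, arr, shape in (
            ("transition_truth", self.transition_truth, (K, K)),
            ("flow_truth", self.flow_truth, (K, K)),
            ("initial_truth", self.initial_truth, (K,)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            rows = arr.reshape(-1, K) if arr.ndim == 2 else arr.reshape(1, K)
            if np.abs(rows.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"{name} rows must sum to 1")
            if rows.min() < 0:
                raise ValueError(f"{name} entries must be non-negative")
        for name, arr in (
            ("emission_truth", self.emission_truth),
            ("demeth_prob_by_state", self.demeth_prob_by_state),
        ):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if self.demeth_prob_by_state.shape != (K,):
            raise ValueError("demeth_prob_by_state must have one entry per state")
        if self.cpg_density <= 0:
            raise ValueError("cpg_density must be positive")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_marks(self) -> int:
        return len(self.mark_names)

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(f"{i + 1}_{s}" for i, s in enumerate(self.state_names))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The package's standard synthetic study conditions."""
    return SimulationConfig(seed=seed, **overrides)


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible random stream for one generator stage.

    The global seed is combined with a CRC32 of the stage label as a
    SeedSequence spawn key, so every stage has its own stream and
    regenerating one stage leaves the others untouched.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _sample_chain(
    rng: np.random.Generator,
    n: int,
    initial: np.ndarray,
    transition: np.ndarray,
) -> np.ndarray:
    cum_init = np.cumsum(initial)
    cum_trans = np.cumsum(transition, axis=1)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int32)
    out[0] = np.searchsorted(cum_init, u[0], side="right")
    for t in range(1, n):
        out[t] = np.searchsorted(cum_trans[out[t - 1]], u[t], side="right")
    np.clip(out, 0, len(initial) - 1, out=out)
    return out


def simulate_state_chain(config: SimulationConfig) -> Segmentation:
    """Condition-A segmentation: a Markov chain per chromosome.

    The chain restarts from the initial distribution at every chromosome.
    """
    rng = substream(config.seed, "state_chain")
    layout = config.layout
    states = np.empty(layout.n_bins, dtype=np.int32)
    for name in layout.chrom_names:
        sl = layout.chrom_slice(name)
        states[sl] = _sample_chain(
            rng, sl.stop - sl.start, config.initial_truth, config.transition_truth
        )
    return Segmentation(layout, states, config.state_labels)


def simulate_marks(
    seg: Segmentation, config: SimulationConfig
) -> list[BinaryMarkTrack]:
    """Binary mark tracks emitted from a segmentation (product Bernoulli)."""
    if seg.states.size and seg.states.max() >= config.n_states:
        raise ValueError("segmentation states exceed configured state count")
    rng = substream(config.seed, "marks")
    p = config.emission_truth[seg.states]  # (n_bins, M)
    calls = (rng.random(p.shape) < p).astype(np.uint8)
    return [
        BinaryMarkTrack(seg.layout, mark, calls[:, j])
        for j, mark in enumerate(config.mark_names)
    ]


def simulate_condition_pair(
    segA: Segmentation, config: SimulationConfig
) -> Segmentation:
    """Condition-B segmentation: per-bin state resampled from flow_truth."""
    rng = substream(config.seed, "condition_pair")
    cum = np.cumsum(config.flow_truth, axis=1)
    u = rng.random(len(segA.states))
    segB = (cum[segA.states] < u[:, None]).sum(axis=1).astype(np.int32)
    np.clip(segB, 0, config.n_states - 1, out=segB)
    return Segmentation(segA.layout, segB, config.state_labels)


def _unique_positions(
    rng: np.random.Generator, length: int, n: int
) -> np.ndarray:
    """n distinct 1-based positions in [1, length], sorted."""
    draw = rng.integers(1, length + 1, size=int(n * 1.2) + 16)
    pos = np.unique(draw)
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_methylation(segB: Segmentation, config: SimulationConfig) -> CpGTable:
    """Array-style CpG table whose demethylation tracks chromatin state.

    Sites are placed uniformly at ``cpg_density`` per kb.  Baseline betas
    are a bimodal Beta mixture (methylation arrays are U-shaped); a site
    is flagged significant-hypomethylated with the probability configured
    for its containing bin's state, in which case the post beta drops by
    the demethylation effect; other sites keep their beta up to small
    noise, with a small hypermethylation rate independent of state.
    """
    rng = substream(config.seed, "methylation")
    layout = segB.layout
    frames = []
    for name, length in zip(layout.chrom_names, layout.chrom_lengths):
        n_sites = max(1, round(config.cpg_density * length / 1000))
        pos = _unique_positions(rng, length, n_sites)
        off = layout.chrom_offsets[layout.chrom_index(name)]
        state = segB.states[off + (pos - 1) // layout.bin_size]
        n = len(pos)
        low_mode = rng.random(n) < 0.5
        beta_before = np.where(
            low_mode, rng.beta(0.5, 5.0, size=n), rng.beta(5.0, 0.5, size=n)
        )
        hypo = rng.random(n) < config.demeth_prob_by_state[state]
        hyper = (~hypo) & (rng.random(n) < config.hyper_prob)
        noise = rng.normal(0.0, config.beta_noise_sd, size=n)
        beta_after = np.where(
            hypo,
            beta_before - config.demeth_effect,
            np.where(hyper, beta_before + config.demeth_effect, beta_before + noise),
        )
        beta_after = np.clip(beta_after, 0.0, 1.0)
        direction = np.where(hypo, "hypo", np.where(hyper, "hyper", ""))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "beta_before": beta_before,
                    "beta_after": beta_after,
                    "significant": hypo | hyper,
                    "direction": direction,
                }
            )
        )
    return CpGTable(pd.concat(frames, ignore_index=True))


def _random_sequences(
    rng: np.random.Generator, n: int, length: int
) -> list[np.ndarray]:
    return [rng.integers(0, 4, size=length, dtype=np.int8) for _ in range(n)]


def simulate_enhancer_sequences(
    n_new: int,
    n_constant: int,
    length: int,
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Two FASTA-ready sequence sets with class-specific motif planting.

    Sequences are i.i.d. uniform background; with the class's planting
    probability one consensus motif instance is inserted at a uniform
    offset, so every planted instance is detectable by a scan.  Returns
    (new, constant) lists of (name, sequence).
    """
    pwm = config.motif_pwm
    m = len(pwm)
    if length < m:
        raise ValueError(f"sequence length {length} shorter than motif length {m}")
    rng = substream(config.seed, "enhancer_sequences")
    bases = np.array(list("ACGT"))
    inst = np.array([_CODE_ACGT[b] for b in pwm.consensus()], dtype=np.int8)

    def make(n: int, rate: float, prefix: str) -> list[tuple[str, str]]:
        out = []
        for i, codes in enumerate(_random_sequences(rng, n, length)):
            if rng.random() < rate:
                start = int(rng.integers(0, length - m + 1))
                codes[start : start + m] = inst
            out.append((f"{prefix}_{i}", "".join(bases[codes])))
        return out

    new = make(n_new, config.motif_plant_rate_new, "new")
    constant = make(n_constant, config.motif_plant_rate_constant, "constant")
    return new, constant


def simulate_enhancer_replicates(
    config: SimulationConfig,
    n_per_group: int = 5,
    n_slots: int = 400,
    slot_bins: int = 5,
    within_keep: float = 0.9,
    between_share: float = 0.05,
) -> tuple[dict[str, IntervalSet], dict[str, str]]:
    """Replicate enhancer maps in two planted groups.

    Candidate enhancer slots tile the genome; a small fraction is common
    to both groups (``between_share``) while the rest is split into two
    disjoint group cores.  Each replicate keeps every slot of its group
    core independently with probability ``within_keep``, so within-group
    Jaccard is high and between-group Jaccard is near the shared
    fraction.  Returns (interval sets by sample name, group by name).
    """
    rng = substream(config.seed, "enhancer_replicates")
    layout = config.layout
    spacing = layout.n_bins // n_slots
    if spacing < slot_bins + 1:
        raise ValueError("too many slots for the layout")
    slot_ids = rng.permutation(n_slots)
    n_common = max(1, int(round(between_share * n_slots)))
    common = slot_ids[:n_common]
    rest = slot_ids[n_common:]
    half = len(rest) // 2
    cores = {
        "g1": np.concatenate([common, rest[:half]]),
        "g2": np.concatenate([common, rest[half:]]),
    }
    sets: dict[str, IntervalSet] = {}
    groups: dict[str, str] = {}
    for g in ("g1", "g2"):
        for r in range(n_per_group):
            keep = cores[g][rng.random(len(cores[g])) < within_keep]
            mask = np.zeros(layout.n_bins, dtype=bool)
            for slot in keep:
                b0 = int(slot) * spacing
                mask[b0 : b0 + slot_bins] = True
            name = f"{g}_rep{r}"
            sets[name] = IntervalSet.from_bin_mask(layout, mask)
            groups[name] = g
    return sets, groups
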