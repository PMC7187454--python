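"""PWM motif scanning and relative enrichment between sequence classes.

A position weight matrix (base probabilities per motif position) is
scored against both strands of a sequence by log2 odds versus a
background base composition.  Enrichment between two sequence classes
("new" vs "constant" enhancers) uses the sequence-level binary hit
definition — a sequence has the motif iff it contains at least one hit
at the threshold — tested with a one-sided Fisher exact test, the
canonical statistic family of AME-style relative enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import fisher_exact

__all__ = [
    "MotifPWM",
    "MotifHit",
    "MotifEnrichmentResult",
    "read_meme",
    "write_meme",
    "scan_sequence",
    "relative_enrichment",
    "read_fasta",
    "write_fasta",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT_ORDER = [3, 2, 1, 0]  # A<->T, C<->G in ACGT column order


@dataclass(frozen=True)
class MotifPWM:
    """Base-probability motif matrix (L x 4, column order A, C, G, T)."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        bg = np.asarray(self.background, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("matrix must be L x 4 with L >= 1")
        if np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("each matrix row must sum to 1")
        if abs(bg.sum() - 1.0) > 1e-9 or bg.shape != (4,):
            raise ValueError("background must be 4 probabilities summing to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2((p + pseudocount*bg) / bg) per position and base."""
        bg = self.background
        return np.log2((self.matrix + self.pseudocount * bg) / bg)

    def max_score(self) -> float:
        """Best achievable log-odds score (consensus on the plus strand)."""
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "MotifPWM":
        return MotifPWM(
            name=self.name,
            matrix=self.matrix[::-1, _COMPLEMENT_ORDER],
            background=self.background[_COMPLEMENT_ORDER],
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHit:
    """One scan hit: plus-strand window start, strand, log-odds score."""

    position: int
    strand: str
    score: float


@dataclass(frozen=True)
class MotifEnrichmentResult:
    """2x2 sequence-level motif presence contrast between two classes."""

    hits_new: int
    n_new: int
    hits_constant: int
    n_constant: int
    odds_ratio: float
    p_one_sided: float


# -- MEME minimal format ----------------------------------------------------


def read_meme(path: str | Path) -> list[MotifPWM]:
    """Read motifs from a MEME-minimal letter-probability file."""
    with Path(path).open() as fh:
        record = bio_motifs.parse(fh, "minimal")
    bg_map = record[0].background if record else {b: 0.25 for b in _BASES}
    bg = np.array([bg_map[b] for b in _BASES], dtype=np.float64)
    bg = bg / bg.sum()
    out = []
    for m in record:
        mat = np.array([[m.pwm[b][i] for b in _BASES] for i in range(m.length)])
        mat = mat / mat.sum(axis=1, keepdims=True)
        out.append(MotifPWM(name=m.name, matrix=mat, background=bg))
    return out


def write_meme(pwms: list[MotifPWM], path: str | Path) -> None:
    """Write motifs in MEME-minimal letter-probability format."""
    if not pwms:
        raise ValueError("no motifs to write")
    bg = pwms[0].background
    with Path(path).open("w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {p:.6f}" for b, p in zip(_BASES, bg)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            # large nsites: downstream readers that quantize probabilities
            # to integer counts (p * nsites) keep six-figure fidelity
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# -- scanning ----------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)  # everything non-ACGT behaves as N
    for b, i in _CODE.items():
        code[ord(b)] = i
    return code[arr]


def _strand_scores(code: np.ndarray, pwm: MotifPWM) -> tuple[np.ndarray, np.ndarray]:
    """(scores per window, validity mask) for one strand's log-odds matrix."""
    m = len(pwm)
    windows = sliding_window_view(code, m)
    valid = (windows < 4).all(axis=1)
    lo = np.hstack([pwm.log_odds(), np.zeros((m, 1))])  # N column scores 0, masked out
    scores = lo[np.arange(m)[None, :], windows].sum(axis=1)
    return scores, valid


def scan_sequence(
    seq: str, pwm: MotifPWM, score_threshold: float
) -> list[MotifHit]:
    """All positions where the motif scores at or above the threshold.

    Both strands are scanned; minus-strand hits are reported at the
    plus-strand start coordinate of the window.  Windows containing N
    (or any non-ACGT character) are skipped.  Sequences shorter than the
    motif yield an empty list.
    """
    code = _encode(seq)
    m = len(pwm)
    if code.size < m:
        return []
    hits: list[MotifHit] = []
    for strand, matrix in (("+", pwm), ("-", pwm.reverse_complement())):
        scores, valid = _strand_scores(code, matrix)
        for pos in np.flatnonzero(valid & (scores >= score_threshold)):
            hits.append(MotifHit(int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _has_hit(seq: str, pwm: MotifPWM, threshold: float) -> bool:
    code = _encode(seq)
    if code.size < len(pwm):
        return False
    for matrix in (pwm, pwm.reverse_complement()):
        scores, valid = _strand_scores(code, matrix)
        if (valid & (scores >= threshold)).any():
            return True
    return False


def relative_enrichment(
    seqs_new: list[str],
    seqs_constant: list[str],
    pwm: MotifPWM,
    score_threshold: float | None = None,
    threshold_frac: float = 0.6,
) -> MotifEnrichmentResult:
    """One-sided Fisher exact test of motif presence, new vs constant.

    A sequence "has the motif" iff it contains at least one hit.  The
    default threshold is ``threshold_frac`` (60%) of the PWM's maximum
    achievable log-odds score.  The odds ratio uses the Haldane 0.5
    correction when any cell is zero.
    """
    if not seqs_new or not seqs_constant:
        raise ValueError("both sequence classes must be non-empty")
    if score_threshold is None:
        score_threshold = threshold_frac * pwm.max_score()
    hits_new = sum(_has_hit(s, pwm, score_threshold) for s in seqs_new)
    hits_const = sum(_has_hit(s, pwm, score_threshold) for s in seqs_constant)
    table = [
        [hits_new, len(seqs_new) - hits_new],
        [hits_const, len(seqs_constant) - hits_const],
    ]
    _, p = fisher_exact(table, alternative="greater")
    a, b_, c, d = table[0][0], table[0][1], table[1][0], table[1][1]
    if 0 in (a, b_, c, d):
        a, b_, c, d = a + 0.5, b_ + 0.5, c + 0.5, d + 0.5
    return MotifEnrichmentResult(
        hits_new=hits_new,
        n_new=len(seqs_new),
        hits_constant=hits_const,
        n_constant=len(seqs_constant),
        odds_ratio=(a * d) / (b_ * c),
        p_one_sided=float(p),
    )


# -- FASTA -------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )
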