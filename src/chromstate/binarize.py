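"""Poisson binarization of binned ChIP-seq count tracks.

Binned read counts for one histone mark are converted to per-bin 0/1
calls by an upper-tail Poisson test against a background rate: a bin is
"on" when ``P(X >= observed | lambda) <= p_threshold``.  The background
``lambda`` per bin comes from a matched input-control track, scaled so
the control's total mass equals the signal's (depth matching); without a
control the global mean signal count is used.  This is the standard
background convention of chromatin-state tools, applied with a single
global scaling (no local background windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .layout import GenomeLayout

__all__ = [
    "CountTrack",
    "BinaryMarkTrack",
    "poisson_binarize",
    "stack_tracks",
    "unstack_tracks",
    "read_count_track",
    "write_count_track",
    "read_binary_track",
    "write_binary_track",
]

_EPS = 1e-8


@dataclass
class CountTrack:
    """Non-negative integer read counts per bin for one mark."""

    layout: GenomeLayout
    mark: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.layout.n_bins,):
            raise ValueError("counts length does not match layout bin count")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class BinaryMarkTrack:
    """Per-bin 0/1 presence calls for one mark."""

    layout: GenomeLayout
    mark: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.shape != (self.layout.n_bins,):
            raise ValueError("calls length does not match layout bin count")
        if self.calls.size and not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be 0/1")


def poisson_binarize(
    signal: CountTrack,
    control: CountTrack | None = None,
    p_threshold: float = 1e-4,
) -> BinaryMarkTrack:
    """Call bins by the Poisson upper tail against a background rate.

    Parameters
    ----------
    signal, control
        Binned counts on the same layout.  The control is scaled by
        (total signal)/(total control) before use as per-bin ``lambda``;
        with no control a flat ``lambda`` equal to the global mean signal
        count is used.
    p_threshold
        Tail probability at or below which a bin is called 1.  Default
        1e-4, the dominant convention in chromatin-state studies.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    total = signal.counts.sum()
    if total == 0:
        warnings.warn(f"track {signal.mark!r} has zero total signal; all-zero calls")
        return BinaryMarkTrack(signal.layout, signal.mark, np.zeros(signal.layout.n_bins))
    if control is None:
        lam = np.full(signal.layout.n_bins, total / signal.layout.n_bins)
    else:
        if control.layout != signal.layout:
            raise ValueError("signal and control layouts differ")
        ctot = control.counts.sum()
        if ctot == 0:
            lam = np.full(signal.layout.n_bins, total / signal.layout.n_bins)
        else:
            lam = control.counts * (total / ctot)
    lam = np.maximum(lam, _EPS)
    # P(X >= obs) = sf(obs - 1); obs = 0 gives tail probability 1.
    tail = poisson.sf(signal.counts - 1, lam)
    return BinaryMarkTrack(signal.layout, signal.mark, (tail <= p_threshold).astype(np.uint8))


def stack_tracks(tracks: list[BinaryMarkTrack]) -> tuple[np.ndarray, list[str]]:
    """Stack per-mark call vectors into a (bins x marks) 0/1 matrix.

    Column order follows the input order; returns (matrix, mark_names).
    """
    if not tracks:
        raise ValueError("no tracks to stack")
    layout = tracks[0].layout
    names = [t.mark for t in tracks]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate mark names: {names}")
    for t in tracks:
        if t.layout != layout:
            raise ValueError("all tracks must share one layout")
    return np.column_stack([t.calls for t in tracks]).astype(np.uint8), names


def unstack_tracks(
    obs: np.ndarray, mark_names: list[str], layout: GenomeLayout
) -> list[BinaryMarkTrack]:
    """Inverse of :func:`stack_tracks`."""
    obs = np.asarray(obs)
    if obs.shape != (layout.n_bins, len(mark_names)):
        raise ValueError("observation matrix shape mismatch")
    return [
        BinaryMarkTrack(layout, name, obs[:, j]) for j, name in enumerate(mark_names)
    ]


# -- track I/O (bedGraph-like TSV: chrom, start, end, value) ----------------


def _read_track_values(path: str | Path, layout: GenomeLayout) -> np.ndarray:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    values = np.zeros(layout.n_bins, dtype=np.int64)
    seen = np.zeros(layout.n_bins, dtype=bool)
    for chrom, grp in df.groupby("chrom", sort=False):
        if not layout.has_chrom(str(chrom)):
            raise ValueError(f"chromosome {chrom!r} not in layout")
        off = layout.chrom_offsets[layout.chrom_index(str(chrom))]
        idx = off + grp["start"].to_numpy() // layout.bin_size
        values[idx] = grp["value"].to_numpy()
        seen[idx] = True
    if not seen.all():
        raise ValueError("track file does not cover every bin of the layout")
    return values


def _write_track_values(
    values: np.ndarray, layout: GenomeLayout, path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            sub = values[layout.chrom_slice(name)]
            for i, v in enumerate(sub):
                start = i * layout.bin_size
                end = min(start + layout.bin_size, length)
                fh.write(f"{name}\t{start}\t{end}\t{int(v)}\n")


def read_count_track(path: str | Path, layout: GenomeLayout, mark: str) -> CountTrack:
    return CountTrack(layout, mark, _read_track_values(path, layout))


def write_count_track(track: CountTrack, path: str | Path) -> None:
    _write_track_values(track.counts, track.layout, path)


def read_binary_track(
    path: str | Path, layout: GenomeLayout, mark: str
) -> BinaryMarkTrack:
    return BinaryMarkTrack(layout, mark, _read_track_values(path, layout))


def write_binary_track(track: BinaryMarkTrack, path: str | Path) -> None:
    _write_track_values(track.calls, track.layout, path)
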