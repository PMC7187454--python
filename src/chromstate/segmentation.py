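"""Per-bin chromatin-state assignments and their dense-BED representation.

A :class:`Segmentation` assigns one state index to every bin of a
:class:`~chromstate.layout.GenomeLayout`.  On disk it is a dense BED4:
one line per maximal run of a state, labelled with the state name, with
the final interval of each chromosome clamped at the chromosome end.
Reading the file back and re-expanding per bin reproduces the
segmentation exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import IntervalSet
from .layout import GenomeLayout

__all__ = [
    "Segmentation",
    "write_segmentation_bed",
    "read_segmentation_bed",
    "resolve_state",
]

_DEFAULT_LABEL = re.compile(r"^S(\d+)$")


@dataclass
class Segmentation:
    """Genome-wide per-bin state assignment on a fixed layout."""

    layout: GenomeLayout
    states: np.ndarray
    state_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int32)
        if self.states.shape != (self.layout.n_bins,):
            raise ValueError(
                f"states length {self.states.shape} does not match "
                f"layout bin count {self.layout.n_bins}"
            )
        if len(self.states) and self.states.min() < 0:
            raise ValueError("state indices must be non-negative")
        if self.state_labels is not None:
            self.state_labels = tuple(self.state_labels)
            if self.states.size and self.states.max() >= len(self.state_labels):
                raise ValueError("state index exceeds label list")

    @property
    def n_states(self) -> int:
        if self.state_labels is not None:
            return len(self.state_labels)
        return int(self.states.max()) + 1 if self.states.size else 0

    def label_of(self, state: int) -> str:
        if self.state_labels is not None:
            return self.state_labels[state]
        return f"S{state}"

    def chrom_states(self, chrom: str) -> np.ndarray:
        return self.states[self.layout.chrom_slice(chrom)]

    def state_mask(self, state: int) -> np.ndarray:
        return self.states == state

    def state_intervals(self, state: int | str) -> IntervalSet:
        """Merged intervals covering exactly the bins assigned one state."""
        idx = resolve_state(self, state) if isinstance(state, str) else int(state)
        return IntervalSet.from_bin_mask(self.layout, self.state_mask(idx))

    def state_histogram(self) -> np.ndarray:
        return np.bincount(self.states, minlength=self.n_states)


def resolve_state(seg_or_labels, state: str) -> int:
    """Map a state label to its index.

    Accepts the full label (``"13_EnhS"``) or the bare mnemonic
    (``"EnhS"``, matching one label's part after the index prefix).
    Raises ``KeyError`` listing the available labels otherwise.
    """
    labels = (
        seg_or_labels
        if isinstance(seg_or_labels, (list, tuple))
        else [seg_or_labels.label_of(k) for k in range(seg_or_labels.n_states)]
    )
    labels = list(labels)
    if state in labels:
        return labels.index(state)
    suffix_hits = [
        i for i, lab in enumerate(labels) if lab.split("_", 1)[-1] == state
    ]
    if len(suffix_hits) == 1:
        return suffix_hits[0]
    raise KeyError(f"unknown state {state!r}; available: {labels}")


def write_segmentation_bed(seg: Segmentation, path: str | Path) -> None:
    """Write a dense BED4: one line per maximal run of one state."""
    if seg.layout is None:  # pragma: no cover - dataclass requires layout
        raise ValueError("segmentation is not bound to a layout")
    layout = seg.layout
    with Path(path).open("w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            sub = seg.chrom_states(name)
            if sub.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(sub)) + 1
            run_starts = np.concatenate([[0], breaks])
            run_ends = np.concatenate([breaks, [len(sub)]])
            for rs, re_ in zip(run_starts, run_ends):
                start = int(rs) * layout.bin_size
                end = min(int(re_) * layout.bin_size, length)
                fh.write(f"{name}\t{start}\t{end}\t{seg.label_of(int(sub[rs]))}\n")


def read_segmentation_bed(
    path: str | Path,
    layout: GenomeLayout,
    state_labels: tuple[str, ...] | list[str] | None = None,
) -> Segmentation:
    """Read a dense segmentation BED4 back into per-bin states.

    With ``state_labels`` given, labels map to their list index; without,
    default ``S<k>`` labels map to ``k`` directly, and any other label
    vocabulary is indexed by sorted order of first appearance.
    """
    from .intervals import read_bed

    ivs = read_bed(path, expect_label=True)
    states = np.full(layout.n_bins, -1, dtype=np.int32)
    if state_labels is not None:
        mapping = {lab: i for i, lab in enumerate(state_labels)}
    else:
        seen = sorted({iv.label for iv in ivs})
        if all(_DEFAULT_LABEL.match(lab) for lab in seen):
            mapping = {lab: int(_DEFAULT_LABEL.match(lab).group(1)) for lab in seen}
            state_labels = tuple(f"S{k}" for k in range(max(mapping.values()) + 1))
        else:
            mapping = {lab: i for i, lab in enumerate(seen)}
            state_labels = tuple(seen)
    for iv in ivs:
        if not layout.has_chrom(iv.chrom):
            raise ValueError(f"chromosome {iv.chrom!r} not in layout")
        if iv.label not in mapping:
            raise KeyError(f"label {iv.label!r} not in state label list")
        off = layout.chrom_offsets[layout.chrom_index(iv.chrom)]
        b0 = iv.start // layout.bin_size
        b1 = -(-iv.end // layout.bin_size)  # ceil: includes clamped final bin
        states[off + b0 : off + b1] = mapping[iv.label]
    if (states < 0).any():
        raise ValueError("segmentation BED does not cover every bin of the layout")
    return Segmentation(layout, states, tuple(state_labels))
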