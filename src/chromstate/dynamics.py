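"""Chromatin-state dynamics between two conditions.

Paired segmentations (e.g. stem cells before and chondrocytes after
differentiation) on the same layout are compared bin by bin: the state
flow matrix counts bins moving from each state in condition A to each
state in condition B (the riverplot matrix), and condition-B enhancer
bins are classified by their condition-A origin as *new* (from quiescent
or Polycomb-repressed chromatin), *constant* (already enhancers), or the
residual *other_gain* (from any other active state — kept separate so
the two named classes stay pure).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .segmentation import Segmentation, resolve_state

__all__ = ["StateFlowMatrix", "EnhancerClassification", "flow_matrix", "classify_enhancers"]


@dataclass
class StateFlowMatrix:
    """Bin counts flowing from each A-state (rows) to each B-state (columns)."""

    states_from: tuple[str, ...]
    states_to: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.states_from), len(self.states_to)):
            raise ValueError("counts shape inconsistent with label lists")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Empirical condition-B state distribution given each A-state."""
        row = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore"):
            out = self.counts / np.where(row > 0, row, np.nan)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.states_from), columns=list(self.states_to)
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="from\\to")


@dataclass
class EnhancerClassification:
    """Disjoint partition of condition-B enhancer territory by A-origin."""

    new_enhancers: IntervalSet
    constant_enhancers: IntervalSet
    other_gain: IntervalSet


def flow_matrix(segA: Segmentation, segB: Segmentation) -> StateFlowMatrix:
    """Count bins with state i in condition A and state j in condition B."""
    if segA.layout != segB.layout:
        raise ValueError("segmentations are on different layouts")
    ka, kb = segA.n_states, segB.n_states
    counts = np.bincount(
        segA.states.astype(np.int64) * kb + segB.states, minlength=ka * kb
    ).reshape(ka, kb)
    return StateFlowMatrix(
        states_from=tuple(segA.label_of(k) for k in range(ka)),
        states_to=tuple(segB.label_of(k) for k in range(kb)),
        counts=counts,
    )


def classify_enhancers(
    segA: Segmentation,
    segB: Segmentation,
    enhancer_states: tuple[str, ...] = ("EnhS",),
    source_states_new: tuple[str, ...] = ("Quies", "ReprPC"),
) -> EnhancerClassification:
    """Partition condition-B enhancer bins by their condition-A state.

    A bin in a B enhancer state is *new* when its A-state is quiescent or
    repressed, *constant* when it was already an enhancer state, and
    *other_gain* otherwise.  Bins are classified individually and then
    collapsed to merged intervals per class, so the three interval sets
    partition the B enhancer territory exactly.
    """
    if segA.layout != segB.layout:
        raise ValueError("segmentations are on different layouts")
    enh_b = np.isin(
        segB.states, [resolve_state(segB, s) for s in enhancer_states]
    )
    enh_a = np.isin(
        segA.states, [resolve_state(segA, s) for s in enhancer_states]
    )
    src_a = np.isin(
        segA.states, [resolve_state(segA, s) for s in source_states_new]
    )
    layout = segA.layout
    return EnhancerClassification(
        new_enhancers=IntervalSet.from_bin_mask(layout, enh_b & src_a),
        constant_enhancers=IntervalSet.from_bin_mask(layout, enh_b & enh_a),
        other_gain=IntervalSet.from_bin_mask(layout, enh_b & ~src_a & ~enh_a),
    )
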