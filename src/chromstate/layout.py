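"""Genome coordinate frame shared by tracks and segmentations.

Every per-bin object in the package (count tracks, binary mark calls,
state segmentations) lives on a :class:`GenomeLayout`: an ordered set of
chromosomes, each split into fixed-width bins.  Bins are indexed globally
(concatenated in chromosome order) so that genome-wide arrays are flat;
the layout owns the arithmetic for converting between the two views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeLayout"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths (bp) and a fixed bin size (bp).

    Coordinates are 0-based half-open throughout.  The number of bins on a
    chromosome is ``ceil(length / bin_size)``; the final bin may be
    truncated at the chromosome end.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        if len(names) == 0:
            raise ValueError("layout needs at least one chromosome")
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        if len(lengths) != len(names):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def bins_per_chrom(self) -> np.ndarray:
        """ceil(length / bin_size) per chromosome."""
        return np.array(
            [-(-l // self.bin_size) for l in self.chrom_lengths], dtype=np.int64
        )

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global bin index at which each chromosome starts (+ total at end)."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)])

    @property
    def n_bins(self) -> int:
        return int(self.bins_per_chrom.sum())

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in layout") from None

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_index(chrom)]

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the flat genome-wide bin array covering one chromosome."""
        i = self.chrom_index(chrom)
        off = self.chrom_offsets
        return slice(int(off[i]), int(off[i + 1]))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index containing 0-based position ``pos``."""
        i = self.chrom_index(chrom)
        if not 0 <= pos < self.chrom_lengths[i]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.chrom_offsets[i] + pos // self.bin_size)

    def bin_bounds(self, chrom: str, local_bin: int) -> tuple[int, int]:
        """(start, end) bp of a bin, end clamped at the chromosome end."""
        length = self.chrom_length(chrom)
        start = local_bin * self.bin_size
        if not 0 <= start < length:
            raise ValueError(f"bin {local_bin} outside {chrom}")
        return start, min(start + self.bin_size, length)

    def chain_lengths(self) -> list[int]:
        """Per-chromosome bin counts, the ``lengths`` argument for HMM fitting."""
        return [int(x) for x in self.bins_per_chrom]


def read_layout_tsv(path, bin_size: int) -> GenomeLayout:
    """Layout from a two-column TSV of chromosome name and length (bp)."""
    names, lengths = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            names.append(chrom)
            lengths.append(int(length))
    return GenomeLayout(tuple(names), tuple(lengths), bin_size)


def write_layout_tsv(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{name}\t{length}\n")
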