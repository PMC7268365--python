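"""Reference CpG maps.

A :class:`GenomeCpGMap` lists, per chromosome, the 1-based positions of the
forward-strand cytosine of every CpG dyad. All downstream coordinate logic
(tiling, promoter windows, region overlap) is driven by this map rather than
by a FASTA, so the package can run on simulated genomes of any size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["GenomeCpGMap"]


@dataclass(frozen=True)
class GenomeCpGMap:
    """Per-chromosome sorted CpG dyad positions (1-based, forward-strand C).

    Parameters
    ----------
    positions
        Mapping of chromosome name to a strictly increasing integer array of
        CpG positions, each >= 1. Gaps must be >= 2 bp so dyads never overlap.
    """

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1 or arr.size == 0:
                raise InvalidParameterError(f"{chrom}: empty or non-1D position list")
            if arr[0] < 1:
                raise InvalidParameterError(f"{chrom}: positions must be >= 1")
            if arr.size > 1 and np.any(np.diff(arr) < 2):
                raise InvalidParameterError(
                    f"{chrom}: CpG positions must increase by >= 2 (dyads cannot overlap)"
                )
            clean[str(chrom)] = arr
        object.__setattr__(self, "positions", clean)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    @property
    def n_cpgs(self) -> int:
        return int(sum(arr.size for arr in self.positions.values()))

    def chrom_extent(self, chrom: str) -> tuple[int, int]:
        """(1, max position + 1) — the coordinate span usable on ``chrom``."""
        arr = self.positions[chrom]
        return 1, int(arr[-1]) + 1

    def site_index(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Indices of ``pos`` within the chromosome's CpG list; -1 if absent."""
        arr = self.positions[chrom]
        idx = np.searchsorted(arr, pos)
        idx = np.clip(idx, 0, arr.size - 1)
        hit = arr[idx] == pos
        return np.where(hit, idx, -1)
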