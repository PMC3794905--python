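"""Fixed-size genomic window grids.

The whole analysis operates on non-overlapping fixed-size windows (100 kb by
default), ordered by (chromosome, start).  :class:`WindowGrid` is the shared
index for every per-window quantity (mark densities, replication timing,
state labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class WindowGrid:
    """Ordered, non-overlapping fixed-size windows over a genome.

    Coordinates are 0-based half-open.  ``mrt_defined`` flags windows with a
    valid mean-replication-timing value; analyses that need MRT restrict to
    those windows.
    """

    chroms: np.ndarray  # per-window chromosome name (str dtype)
    starts: np.ndarray  # per-window start (bp)
    window_size: int
    mrt_defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.chroms.shape != self.starts.shape:
            raise ValueError("chroms and starts must have equal length")
        if self.mrt_defined is None:
            self.mrt_defined = np.ones(len(self.starts), dtype=bool)
        self.mrt_defined = np.asarray(self.mrt_defined, dtype=bool)
        # windows must be sorted and non-overlapping within each chromosome
        for sl in self.chrom_slices().values():
            s = self.starts[sl]
            if np.any(np.diff(s) < self.window_size):
                raise ValueError("windows overlap or are unsorted within a chromosome")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window_size

    def chrom_slices(self) -> dict[str, slice]:
        """Mapping chromosome -> slice of window indices, in grid order."""
        out: dict[str, slice] = {}
        if len(self.chroms) == 0:
            return out
        change = np.flatnonzero(self.chroms[1:] != self.chroms[:-1]) + 1
        bounds = np.concatenate(([0], change, [len(self.chroms)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            name = str(self.chroms[a])
            if name in out:
                raise ValueError(f"chromosome {name} appears in two separate runs")
            out[name] = slice(int(a), int(b))
        return out

    @classmethod
    def from_chrom_sizes(cls, sizes: dict[str, int], window_size: int) -> "WindowGrid":
        """Tile each chromosome with as many full windows as fit."""
        chroms: list[str] = []
        starts: list[int] = []
        for name, size in sizes.items():
            n = int(size) // window_size
            chroms.extend([name] * n)
            starts.extend(range(0, n * window_size, window_size))
        return cls(np.array(chroms, dtype=object), np.array(starts), window_size)

    def window_index(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Indices of the windows containing each position (-1 if none)."""
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(pos.shape, -1, dtype=np.int64)
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            return out
        starts = self.starts[sl]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos - starts[np.clip(j, 0, None)] < self.window_size)
        out[ok] = j[ok] + sl.start
        return out
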