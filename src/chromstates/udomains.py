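"""Chromatin-state organization inside replication-timing U-domains.

U-domains are megabase-scale regions whose mean-replication-timing profile is
U-shaped: early at both borders (flanking "master" replication origins) and
late at the center.  The analyses here measure, per domain size class, the
mean coverage of each chromatin state as a function of the distance to the
nearest domain border, plus a centered per-domain state map and the MRT of
merged chromatin blocks as a function of block length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks_markov import StateBlock
from .grid import WindowGrid
from .tracks_io import UDomain

#: Domain size classes in Mb (half-open; domains above the last bound are excluded).
SIZE_CLASSES: tuple[tuple[float, float], ...] = (
    (0.0, 0.8),
    (0.8, 1.2),
    (1.2, 1.8),
    (1.8, 3.0),
)


def size_class_of(domain: UDomain) -> tuple[float, float] | None:
    mb = domain.length / 1e6
    for lo, hi in SIZE_CLASSES:
        if lo <= mb < hi:
            return (lo, hi)
    return None


@dataclass
class UDomainProfile:
    size_class: tuple[float, float]
    states: tuple[str, ...]
    distance_bins_kb: np.ndarray      # left edge of each distance bin
    mean_coverage: np.ndarray         # bins x states
    sem_coverage: np.ndarray          # standard deviation of the mean
    n_domains: np.ndarray             # domains contributing per bin


def _domain_windows(grid: WindowGrid, domain: UDomain) -> np.ndarray:
    """Indices of grid windows whose midpoint lies inside the domain."""
    sl = grid.chrom_slices().get(domain.chrom)
    if sl is None:
        return np.array([], dtype=int)
    mids = grid.starts[sl] + grid.window_size // 2
    ok = (mids >= domain.start) & (mids < domain.end)
    return np.arange(sl.start, sl.stop)[ok]


def udomain_state_profile(
    labels: np.ndarray,
    grid: WindowGrid,
    udomains: list[UDomain],
    size_class: tuple[float, float],
    states: tuple[str, ...] = ("C1", "C2", "C3", "C4", "D"),
    bin_kb: float = 100.0,
) -> UDomainProfile:
    """Mean state coverage vs distance to the nearest U-domain border.

    For every window inside a domain of the size class, the distance from the
    window midpoint to the nearer domain edge is floored to ``bin_kb`` bins
    (both domain halves fold onto one axis).  Coverage fractions are averaged
    over domains; the error is the standard deviation of the mean across
    domains.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    lo, hi = size_class
    selected = [d for d in udomains if size_class_of(d) == (lo, hi)]
    n_bins = int(np.ceil(hi * 1e6 / 2.0 / (bin_kb * 1e3)))
    per_domain = np.full((len(selected), n_bins, len(states)), np.nan)
    for di, d in enumerate(selected):
        idx = _domain_windows(grid, d)
        if idx.size == 0:
            continue
        mids = grid.starts[idx] + grid.window_size // 2
        dist = np.minimum(mids - d.start, d.end - mids)
        bins = np.minimum((dist // int(bin_kb * 1e3)).astype(int), n_bins - 1)
        for b in np.unique(bins):
            sub = labels[idx[bins == b]]
            per_domain[di, b] = [np.mean(sub == s) for s in states]
    n_domains = np.sum(~np.isnan(per_domain[:, :, 0]), axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins dropped below
        mean = np.nanmean(per_domain, axis=0)
        sd = np.nanstd(per_domain, axis=0, ddof=0)
    sem = np.where(n_domains[:, None] > 0, sd / np.sqrt(np.maximum(n_domains[:, None], 1)), np.nan)
    keep = n_domains > 0
    return UDomainProfile(
        size_class=(lo, hi),
        states=tuple(states),
        distance_bins_kb=np.arange(n_bins)[keep] * bin_kb,
        mean_coverage=mean[keep],
        sem_coverage=sem[keep],
        n_domains=n_domains[keep],
    )


def domain_alignment_map(
    labels: np.ndarray, grid: WindowGrid, udomains: list[UDomain]
) -> pd.DataFrame:
    """Centered state segments per domain, smallest domain first.

    Each row is a maximal same-state segment of one domain in coordinates
    relative to the domain center (bp), ready for a stacked plot.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    rows = []
    for rank, d in enumerate(sorted(udomains, key=lambda d: d.length)):
        idx = _domain_windows(grid, d)
        if idx.size == 0:
            continue
        center = (d.start + d.end) / 2.0
        labs = labels[idx]
        change = np.flatnonzero(labs[1:] != labs[:-1]) + 1
        bounds = np.concatenate(([0], change, [len(labs)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append(
                {
                    "domain_rank": rank,
                    "chrom": d.chrom,
                    "domain_length": d.length,
                    "state": labs[a],
                    "rel_start": float(grid.starts[idx[a]] - center),
                    "rel_end": float(grid.starts[idx[b - 1]] + grid.window_size - center),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BlockMrtProfile:
    merge_class: str
    group_mean_length_kb: np.ndarray
    group_mean_mrt: np.ndarray
    group_sd_mrt: np.ndarray
    group_length_range_kb: np.ndarray  # n_groups x 2
    group_sizes: np.ndarray


def block_mrt_profile(
    blocks: list[StateBlock],
    mrt: np.ndarray,
    grid: WindowGrid,
    n_groups: int = 20,
) -> BlockMrtProfile:
    """MRT of merged-block windows vs block length, in equal-count groups.

    Every window of every block contributes one (block length, window MRT)
    point; points are ordered by block length and split into ``n_groups``
    groups whose sizes differ by at most one.
    """
    lengths = []
    mrts = []
    for b in blocks:
        sl = grid.chrom_slices().get(b.chrom)
        if sl is None:
            continue
        idx = np.arange(sl.start, sl.stop)
        ok = (grid.starts[idx] >= b.start) & (grid.starts[idx] < b.end)
        for i in idx[ok]:
            if np.isfinite(mrt[i]):
                lengths.append(b.length_kb)
                mrts.append(mrt[i])
    lengths = np.asarray(lengths)
    mrts = np.asarray(mrts)
    if len(lengths) < n_groups:
        raise ValueError(f"only {len(lengths)} windows for {n_groups} groups")
    order = np.argsort(lengths, kind="stable")
    groups = np.array_split(order, n_groups)
    mc = blocks[0].state if blocks else ""
    return BlockMrtProfile(
        merge_class=mc,
        group_mean_length_kb=np.array([lengths[g].mean() for g in groups]),
        group_mean_mrt=np.array([mrts[g].mean() for g in groups]),
        group_sd_mrt=np.array([mrts[g].std(ddof=0) for g in groups]),
        group_length_range_kb=np.array(
            [[lengths[g].min(), lengths[g].max()] for g in groups]
        ),
        group_sizes=np.array([len(g) for g in groups]),
    )
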