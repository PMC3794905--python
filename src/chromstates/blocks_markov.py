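"""Chromatin-state blocks and Markov run-length models.

A block is a maximal run of contiguous equal-state windows on one chromosome.
Merged block classes "1+2" (C1 or C2) and "3+4" (C3 or C4) additionally
bridge runs of exactly one interior unclassified window so that very long
blocks are not disrupted.

Two analytic null models predict block lengths from the window-level state
statistics.  Under M0 (windows i.i.d. with state probability p) and under M1
(first-order Markov with self-transition probability q) run lengths are
geometric, so with window size w:

    mean = w / (1 - r),   sigma = w * sqrt(r) / (1 - r),   r in {p, q}.

The transition matrix is estimated from undirected window adjacencies: each
adjacent pair contributes to both orientations, and rows are normalized by
their adjacency totals, which makes the estimate row-stochastic by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import WindowGrid
from .reference import STATES

MERGE_CLASSES = {"1+2": ("C1", "C2"), "3+4": ("C3", "C4")}


@dataclass
class StateBlock:
    chrom: str
    start: int
    end: int
    state: str          # a state name or a merged class "1+2"/"3+4"
    n_windows: int      # windows covered, bridged unclassified ones included

    @property
    def length_kb(self) -> float:
        return (self.end - self.start) / 1000.0


@dataclass
class TransitionModel:
    states: tuple[str, ...]
    pi: np.ndarray          # marginal state probabilities (window counts)
    counts: np.ndarray      # symmetric bidirectional adjacency counts
    n_windows: np.ndarray   # per-state window counts
    P: np.ndarray           # row-stochastic transition probabilities


def _chrom_runs(labels: np.ndarray, grid: WindowGrid):
    """Yield (chrom, idx_array, labels_subarray) for each contiguous window run.

    A gap in window coordinates (missing window) splits a run.
    """
    for chrom, sl in grid.chrom_slices().items():
        starts = grid.starts[sl]
        idx = np.arange(sl.start, sl.stop)
        if len(starts) == 0:
            continue
        breaks = np.flatnonzero(np.diff(starts) != grid.window_size) + 1
        for seg in np.split(np.arange(len(starts)), breaks):
            yield chrom, idx[seg], labels[idx[seg]]


def detect_blocks(
    labels: np.ndarray, grid: WindowGrid, merge_class: str | None = None
) -> list[StateBlock]:
    """Maximal same-state runs, or merged-class runs with single-D bridging.

    For merged classes, a single interior unclassified (D) window does not
    break a block; two or more consecutive D windows do, and leading/trailing
    D windows are never included.
    """
    labels = np.asarray(labels, dtype=object)
    blocks: list[StateBlock] = []
    if merge_class is None:
        for chrom, idx, labs in _chrom_runs(labels, grid):
            change = np.flatnonzero(labs[1:] != labs[:-1]) + 1
            bounds = np.concatenate(([0], change, [len(labs)]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                state = str(labs[a])
                if state == "D":
                    continue
                blocks.append(
                    StateBlock(
                        chrom,
                        int(grid.starts[idx[a]]),
                        int(grid.starts[idx[b - 1]]) + grid.window_size,
                        state,
                        int(b - a),
                    )
                )
        return blocks
    members = MERGE_CLASSES[merge_class]
    for chrom, idx, labs in _chrom_runs(labels, grid):
        in_class = np.isin(labs.astype(str), members)
        is_d = labs.astype(str) == "D"
        # bridge: a D window with class members on both sides counts as in-class
        bridged = in_class.copy()
        for i in np.flatnonzero(is_d):
            if 0 < i < len(labs) - 1 and in_class[i - 1] and in_class[i + 1]:
                bridged[i] = True
        change = np.flatnonzero(bridged[1:] != bridged[:-1]) + 1
        bounds = np.concatenate(([0], change, [len(labs)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if not bridged[a]:
                continue
            blocks.append(
                StateBlock(
                    chrom,
                    int(grid.starts[idx[a]]),
                    int(grid.starts[idx[b - 1]]) + grid.window_size,
                    merge_class,
                    int(b - a),
                )
            )
    return blocks


@dataclass
class BlockLengthStats:
    state: str
    count: int
    total_mb: float
    mean_kb: float
    sigma_kb: float
    hist_edges: np.ndarray   # log10(kb) bin edges
    hist_counts: np.ndarray


def block_length_stats(
    blocks: list[StateBlock], state: str | None = None, log_bin_width: float = 0.1
) -> BlockLengthStats:
    """Count, total, mean and sample SD of block lengths, plus a log10 histogram."""
    if state is not None:
        blocks = [b for b in blocks if b.state == state]
    name = state if state is not None else "all"
    if not blocks:
        return BlockLengthStats(name, 0, 0.0, 0.0, 0.0, np.array([]), np.array([]))
    lengths = np.array([b.length_kb for b in blocks])
    logs = np.log10(lengths)
    lo = np.floor(logs.min() / log_bin_width) * log_bin_width
    hi = np.ceil(logs.max() / log_bin_width) * log_bin_width + log_bin_width / 2
    edges = np.arange(lo, hi + log_bin_width, log_bin_width)
    counts, edges = np.histogram(logs, bins=edges)
    sigma = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    return BlockLengthStats(
        name, len(lengths), float(lengths.sum() / 1000.0), float(lengths.mean()), sigma,
        edges, counts,
    )


def estimate_transition_model(
    labels: np.ndarray,
    grid: WindowGrid,
    states: tuple[str, ...] = STATES,
    denominator: str = "adjacency",
) -> TransitionModel:
    """Estimate the window-to-window state transition matrix.

    Each adjacent window pair is counted in both orientations (the sense of
    the chromosome carries no meaning), giving symmetric counts N.  With
    ``denominator="adjacency"`` rows are normalized by their own totals
    (row-stochastic by construction); ``denominator="windows"`` divides by
    the per-state window counts instead, for comparison.
    """
    labels = np.asarray(labels, dtype=object)
    code = {s: i for i, s in enumerate(states)}
    k = len(states)
    N = np.zeros((k, k))
    n_windows = np.zeros(k)
    for s, c in code.items():
        n_windows[c] = np.sum(labels.astype(str) == s)
    for _, _, labs in _chrom_runs(labels, grid):
        c = np.array([code[str(x)] for x in labs])
        for a, b in zip(c[:-1], c[1:]):
            N[a, b] += 1
            N[b, a] += 1
    denom = N.sum(axis=1) if denominator == "adjacency" else n_windows
    undefined = denom == 0
    if undefined.any():
        bad = [states[i] for i in np.flatnonzero(undefined)]
        import logging

        logging.getLogger(__name__).warning("states with no adjacencies: %s", bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = N / denom[:, None]
    total = n_windows.sum()
    pi = n_windows / total if total else n_windows
    return TransitionModel(tuple(states), pi, N, n_windows, P)


def _geometric_run_stats(r: float, window_kb: float) -> tuple[float, float]:
    if not 0 <= r < 1:
        raise ValueError(f"persistence probability must lie in [0, 1), got {r}")
    mean = window_kb / (1.0 - r)
    sigma = window_kb * np.sqrt(r) / (1.0 - r)
    return mean, sigma


def m0_prediction(p: float, window_size: int = 100_000) -> tuple[float, float]:
    """Block mean/sigma (kb) if window states were spatially independent."""
    return _geometric_run_stats(p, window_size / 1000.0)


def m1_prediction(q_self: float, window_size: int = 100_000) -> tuple[float, float]:
    """Block mean/sigma (kb) under nearest-neighbor (first-order Markov) dependence."""
    return _geometric_run_stats(q_self, window_size / 1000.0)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(P, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def validate_stochastic(P: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if (P < 0).any():
        raise ValueError("transition matrix has negative entries")
    sums = P.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        raise ValueError(f"transition-matrix row(s) {bad.tolist()} sum to {sums[bad]}, not 1")
    return P


def sample_markov_sequence(
    P: np.ndarray,
    n: int,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a length-n state-index sequence; start from the stationary law."""
    P = validate_stochastic(P)
    k = P.shape[0]
    start_p = stationary_distribution(P) if init is None else np.asarray(init, float)
    seq = np.empty(n, dtype=np.int8)
    if n == 0:
        return seq
    # pre-draw per-state pools of next states so the hot loop is index lookups
    pools = [rng.choice(k, size=n, p=P[i]).tolist() for i in range(k)]
    ptr = [0] * k
    s = int(rng.choice(k, p=start_p / start_p.sum()))
    for t in range(n):
        seq[t] = s
        nxt = pools[s][ptr[s]]
        ptr[s] += 1
        s = nxt
    return seq


def simulate_from_model(
    P: np.ndarray,
    n_windows: int,
    seed: int | np.random.Generator = 0,
    states: tuple[str, ...] = STATES,
    window_size: int = 100_000,
) -> tuple[np.ndarray, WindowGrid]:
    """Simulate one synthetic chromosome of window states from a transition matrix."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seq = sample_markov_sequence(np.asarray(P, float), n_windows, rng)
    labels = np.array([states[i] for i in seq], dtype=object)
    grid = WindowGrid.from_chrom_sizes({"chrSim": n_windows * window_size}, window_size)
    return labels, grid
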