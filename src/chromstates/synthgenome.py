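"""Synthetic epigenome generator.

Generates genomes with the statistical structure the downstream analyses
assume, so the whole pipeline can be exercised and validated without any
external data:

* a latent five-state (C1-C4 + unclassified D) first-order Markov sequence
  along fixed-size windows, with the K562 transition matrix as default;
* state-conditional log-normal ChIP-seq mark densities, with a few signature
  marks per state elevated above background (active marks for C1, a
  Polycomb-like mark for C2, an HP1-like mark for C4, none for C3);
  unclassified windows are emitted from mixtures of two states so that they
  fall between clusters and silhouette filtering has something to remove;
* state-ordered Beta-distributed mean replication timing, including
  U-shaped replication domains with a C1 -> C2 -> C3 -> C4 border-to-center
  chromatin gradient;
* state-dependent gene density, gene length, expression (RPKM) and sequence
  composition (GC content and CpG o/e via a first-order dinucleotide model).

Everything is deterministic given the seed; fixtures written to disk are
byte-identical across runs.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import tracks_io
from .blocks_markov import sample_markov_sequence, validate_stochastic
from .grid import WindowGrid
from .reference import K562_MARKS, STATES, renormalized_transition_matrix
from .tracks_io import GeneModel, UDomain

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------


@dataclass
class MarkEmission:
    """Log-normal read-density emission: density = location * exp(scale * Z).

    ``location`` is the median density in reads/kb; ``scale`` the log-space
    standard deviation.  Zero scale is the degenerate point mass at
    ``location``.
    """

    location: float
    scale: float

    @property
    def mean(self) -> float:
        return self.location * float(np.exp(self.scale**2 / 2.0))


@dataclass
class MrtEmission:
    """Beta-distributed MRT with the given mean and concentration."""

    mean: float
    concentration: float = 60.0

    @property
    def alpha(self) -> float:
        return self.mean * self.concentration

    @property
    def beta(self) -> float:
        return (1.0 - self.mean) * self.concentration


@dataclass
class UDomainParams:
    """Replication U-domain layout parameters.

    Domains cover ``coverage_fraction`` of each chromosome in expectation;
    lengths are log-normal (median ``length_median_mb``) clipped to
    [``min_mb``, ``max_mb``].  Inside a domain, windows are assigned states
    by distance to the nearer border: ``border_layers`` gives the state and
    width (in windows) of each successive layer, and windows deeper than all
    layers take ``center_state``.  MRT rises parabolically from
    ``mrt_border`` at the edges to ``mrt_center`` at the domain center.
    """

    coverage_fraction: float = 0.5
    length_median_mb: float = 1.0
    length_sigma: float = 0.45
    min_mb: float = 0.3
    max_mb: float = 3.0
    border_layers: tuple[tuple[str, int], ...] = (("C1", 1), ("C2", 2), ("C3", 2))
    center_state: str = "C4"
    mrt_border: float = 0.15
    mrt_center: float = 0.85
    mrt_noise: float = 0.03


@dataclass
class GeneParams:
    """Per-state gene emission: promoter density, length and expression."""

    density_per_mb: float
    length_median_kb: float
    length_sigma: float
    expressed_fraction: float
    expr_log10_mean: float = 1.0
    expr_log10_sd: float = 0.6
    silent_log10_mean: float = -1.5
    silent_log10_sd: float = 0.4


@dataclass
class SeqParams:
    """Per-state sequence composition targets for the dinucleotide model."""

    gc: float
    cpg_oe: float

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"GC fraction must lie in (0, 1), got {self.gc}")
        if self.cpg_oe < 0:
            raise ValueError("CpG o/e target must be non-negative")


@dataclass
class SyntheticSpec:
    n_chromosomes: int = 4
    windows_per_chromosome: int = 5000
    window_size: int = 100_000
    transition_matrix: np.ndarray = field(
        default_factory=renormalized_transition_matrix
    )
    mark_emissions: dict[str, dict[str, MarkEmission]] = field(default_factory=dict)
    mrt_emissions: dict[str, MrtEmission] = field(default_factory=dict)
    udomain_params: UDomainParams = field(default_factory=UDomainParams)
    gene_params: dict[str, GeneParams] = field(default_factory=dict)
    seq_params: dict[str, SeqParams] = field(default_factory=dict)
    #: bases of sequence emitted per window (a representative subsequence;
    #: full window size would be needlessly slow for composition statistics)
    bases_per_window: int = 10_000
    cgi_probability: float = 0.7
    cgi_length: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        self.transition_matrix = validate_stochastic(np.asarray(self.transition_matrix, float))
        if self.mrt_emissions:
            means = [self.mrt_emissions[s].mean for s in ("C1", "C2", "C3", "C4")]
            if not all(a < b for a, b in zip(means[:-1], means[1:])):
                raise ValueError("MRT emission means must increase strictly from C1 to C4")

    @property
    def n_windows(self) -> int:
        return self.n_chromosomes * self.windows_per_chromosome


def default_spec(**overrides) -> SyntheticSpec:
    """The default study configuration for the synthetic K562-like epigenome.

    Mark emissions: background median 0.5 reads/kb (log-sd 0.5) with the
    signature marks of each state at 8x background (plus a secondary
    signature at 4x for C2 and C4); C3 carries no signature.  MRT means
    0.20 / 0.45 / 0.65 / 0.85 for C1..C4 (D at 0.55).  Gene densities follow
    the published per-state promoter densities; composition targets follow
    the published C4 GC content, with the other states ordered as observed.
    """
    bg = 0.5
    marks: dict[str, dict[str, MarkEmission]] = {}
    active = ("H3K4me3", "H3K27ac", "H3K36me3", "H3K79me2", "RNAPII")
    # fold change over background per state; active marks are depleted (not
    # merely background) in the silent states, as in real per-state boxplots
    signatures: dict[str, dict[str, float]] = {
        "C1": {**{m: 8 for m in active}, "H2AZ": 4, "CTCF": 2,
               "H3K27me3": 0.5, "H3K9me3": 0.5},
        "C2": {"H3K27me3": 8, "Sin3A": 4, "H4K20me1": 2,
               **{m: 0.5 for m in active}, "H3K9me3": 0.5},
        "C3": {**{m: 0.5 for m in active}, "H3K27me3": 0.5, "H3K9me3": 0.5,
               "H2AZ": 0.5, "Sin3A": 0.5, "CBX3": 0.5},
        "C4": {"H3K9me3": 8, "CBX3": 4, "H3K9me1": 2,
               **{m: 0.5 for m in active}, "H3K27me3": 0.5},
    }
    for state in ("C1", "C2", "C3", "C4"):
        marks[state] = {
            m: MarkEmission(bg * signatures[state].get(m, 1), 0.5) for m in K562_MARKS
        }
    spec = SyntheticSpec(
        mark_emissions=marks,
        mrt_emissions={
            "C1": MrtEmission(0.20),
            "C2": MrtEmission(0.45),
            "C3": MrtEmission(0.65),
            "C4": MrtEmission(0.85),
            "D": MrtEmission(0.55),
        },
        gene_params={
            "C1": GeneParams(19.1, 19.0, 1.27, 0.75),
            "C2": GeneParams(7.7, 19.0, 1.51, 0.30),
            "C3": GeneParams(4.1, 17.8, 1.76, 0.20),
            "C4": GeneParams(1.8, 26.1, 1.80, 0.10),
            "D": GeneParams(8.0, 20.0, 1.50, 0.40),
        },
        seq_params={
            "C1": SeqParams(0.458, 0.40),
            "C2": SeqParams(0.455, 0.32),
            "C3": SeqParams(0.380, 0.24),
            "C4": SeqParams(0.367, 0.19),
            "D": SeqParams(0.410, 0.30),
        },
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass
class SyntheticGenome:
    spec: SyntheticSpec
    seed: int
    grid: WindowGrid
    true_states: np.ndarray              # per-window label in {C1..C4, D}
    mark_matrix: np.ndarray              # windows x marks, reads/kb
    mark_names: list[str]
    mrt: np.ndarray
    udomains: list[UDomain] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    sequences: list[str] | None = None   # per-window nucleotide strings
    cgi_masks: list[list[tuple[int, int]]] | None = None  # window-relative

    def __post_init__(self) -> None:
        n = len(self.grid)
        for name, arr in (("true_states", self.true_states), ("mrt", self.mrt)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} windows")
        if self.mark_matrix.shape[0] != n:
            raise ValueError("mark_matrix row count disagrees with the grid")
        bad = set(np.asarray(self.true_states).astype(str)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")


# ---------------------------------------------------------------------------
# state sequence
# ---------------------------------------------------------------------------


def make_grid(spec: SyntheticSpec) -> WindowGrid:
    sizes = {
        f"chr{i + 1}": spec.windows_per_chromosome * spec.window_size
        for i in range(spec.n_chromosomes)
    }
    return WindowGrid.from_chrom_sizes(sizes, spec.window_size)


def sample_state_sequence(spec: SyntheticSpec, seed: int | None = None) -> np.ndarray:
    """Per-window state labels: independent Markov chains per chromosome,
    each started from the stationary distribution of the transition matrix."""
    if spec.windows_per_chromosome < 2:
        raise ValueError("need at least 2 windows per chromosome")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    P = spec.transition_matrix
    parts = [
        sample_markov_sequence(P, spec.windows_per_chromosome, rng)
        for _ in range(spec.n_chromosomes)
    ]
    codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
    return np.array([STATES[c] for c in codes], dtype=object)


# ---------------------------------------------------------------------------
# mark emissions
# ---------------------------------------------------------------------------


def _emission_for(spec: SyntheticSpec, state: str, mark: str) -> MarkEmission:
    try:
        return spec.mark_emissions[state][mark]
    except KeyError as exc:
        raise ValueError(f"no emission parameters for (state={state}, mark={mark})") from exc


def emit_mark_profiles(
    states: np.ndarray,
    spec: SyntheticSpec,
    seed: int | np.random.Generator = 0,
    quantize: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """State-conditional log-normal mark densities (reads/kb).

    With ``quantize`` (the default) densities are rounded to whole read
    counts per window so that a written fixture round-trips exactly.
    Unclassified (D) windows draw, per window, a random pair of states and
    emit from the log-space midpoint of their parameters, which places them
    between clusters.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    states = np.asarray(states, dtype=object).astype(str)
    mark_names = sorted({m for d in spec.mark_emissions.values() for m in d})
    n = len(states)
    out = np.zeros((n, len(mark_names)))
    class_states = [s for s in STATES if s != "D" and s in spec.mark_emissions]
    # per-window (location, scale) in log space, then one vectorized draw
    mu = np.empty((n, len(mark_names)))
    sig = np.empty((n, len(mark_names)))
    is_d = states == "D"
    for j, mark in enumerate(mark_names):
        locs = {}
        for s in set(states[~is_d]):
            em = _emission_for(spec, s, mark)
            locs[s] = (np.log(em.location), em.scale)
        for s, (m_, s_) in locs.items():
            sel = states == s
            mu[sel, j] = m_
            sig[sel, j] = s_
    if is_d.any():
        if not class_states:
            raise ValueError("D-window mixture needs emission parameters for C1..C4")
        pair_a = rng.integers(0, len(class_states), size=is_d.sum())
        shift = 1 + rng.integers(0, max(len(class_states) - 1, 1), size=is_d.sum())
        pair_b = (pair_a + shift) % len(class_states)
        w = rng.uniform(0.3, 0.7, size=is_d.sum())
        for j, mark in enumerate(mark_names):
            ems = [_emission_for(spec, s, mark) for s in class_states]
            la = np.log([ems[a].location for a in pair_a])
            lb = np.log([ems[b].location for b in pair_b])
            sa = np.array([ems[a].scale for a in pair_a])
            sb = np.array([ems[b].scale for b in pair_b])
            mu[is_d, j] = w * la + (1 - w) * lb
            sig[is_d, j] = (sa + sb) / 2.0
    out = np.exp(mu + sig * rng.standard_normal((n, len(mark_names))))
    if quantize:
        kb = spec.window_size / 1000.0
        out = np.round(out * kb) / kb
    return out, mark_names


def between_state_separation(matrix: np.ndarray, states: np.ndarray) -> float:
    """Between-state variance of per-state mark means over the pooled variance.

    Close to 0 when emissions do not depend on state.
    """
    states = np.asarray(states, dtype=object).astype(str)
    total_var = matrix.var(axis=0).mean()
    if total_var == 0:
        return 0.0
    grand = matrix.mean(axis=0)
    between = np.mean(
        [
            ((matrix[states == s].mean(axis=0) - grand) ** 2).mean()
            for s in np.unique(states)
        ]
    )
    return float(between / total_var)


# ---------------------------------------------------------------------------
# MRT emissions and U-domain genomes
# ---------------------------------------------------------------------------


def emit_mrt(
    states: np.ndarray, spec: SyntheticSpec, seed: int | np.random.Generator = 0
) -> np.ndarray:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    states = np.asarray(states, dtype=object).astype(str)
    mrt = np.empty(len(states))
    for s in np.unique(states):
        em = spec.mrt_emissions[s]
        sel = states == s
        mrt[sel] = rng.beta(em.alpha, em.beta, size=sel.sum())
    return mrt


def _layout_domain(n_windows: int, params: UDomainParams) -> list[str]:
    """States of a domain's windows: border layers inward, center state beyond."""
    states = []
    for i in range(n_windows):
        depth = min(i, n_windows - 1 - i)
        cum = 0
        state = params.center_state
        for name, width in params.border_layers:
            cum += width
            if depth < cum:
                state = name
                break
        states.append(state)
    return states


def _place_domains(
    n_windows: int, window_size: int, params: UDomainParams, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Alternating gap/domain placement achieving the target coverage fraction."""
    f = params.coverage_fraction
    if f <= 0:
        return []
    mean_dom_w = params.length_median_mb * 1e6 * np.exp(params.length_sigma**2 / 2) / window_size
    mean_gap_w = max(mean_dom_w * (1 - f) / f, 1.0)
    domains: list[tuple[int, int]] = []
    pos = int(rng.geometric(1.0 / mean_gap_w))
    while pos < n_windows:
        mb = params.length_median_mb * np.exp(params.length_sigma * rng.standard_normal())
        mb = float(np.clip(mb, params.min_mb, params.max_mb))
        d = max(int(round(mb * 1e6 / window_size)), 1)
        if d < 3:
            log.warning("skipping U-domain of %d windows (< 3)", d)
        else:
            d = min(d, n_windows - pos)
            if d >= 3:
                domains.append((pos, pos + d))
        pos += d + int(rng.geometric(1.0 / mean_gap_w))
    return domains


def generate_udomain_genome(
    spec: SyntheticSpec,
    seed: int | None = None,
    with_genes: bool = True,
    with_sequence: bool = True,
) -> SyntheticGenome:
    """Full synthetic genome with U-shaped replication domains.

    U-domains tile ``coverage_fraction`` of each chromosome.  Inside each
    domain, states follow the border-to-center C1 -> C2 -> C3 -> C4 layout
    and MRT rises parabolically from border to center; outside, states come
    from the Markov chain with state-conditional Beta MRT.
    """
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(5)]
    grid = make_grid(spec)
    n_per = spec.windows_per_chromosome
    labels = np.empty(len(grid), dtype=object)
    mrt = np.empty(len(grid))
    udomains: list[UDomain] = []
    rng_state, rng_mrt = rngs[0], rngs[1]
    for ci, (chrom, sl) in enumerate(grid.chrom_slices().items()):
        chain = sample_markov_sequence(spec.transition_matrix, n_per, rng_state)
        chrom_labels = np.array([STATES[c] for c in chain], dtype=object)
        chrom_mrt = np.empty(n_per)
        for s in np.unique(chrom_labels.astype(str)):
            em = spec.mrt_emissions[s]
            sel = chrom_labels.astype(str) == s
            chrom_mrt[sel] = rng_mrt.beta(em.alpha, em.beta, size=sel.sum())
        p = spec.udomain_params
        for a, b in _place_domains(n_per, spec.window_size, p, rng_state):
            chrom_labels[a:b] = _layout_domain(b - a, p)
            x = (np.arange(a, b) + 0.5 - a) / (b - a)
            u = p.mrt_border + (p.mrt_center - p.mrt_border) * 4.0 * x * (1.0 - x)
            noise = p.mrt_noise * rng_mrt.standard_normal(b - a)
            chrom_mrt[a:b] = np.clip(u + noise, 0.0, 1.0)
            udomains.append(
                UDomain(chrom, a * spec.window_size, b * spec.window_size)
            )
        labels[sl] = chrom_labels
        mrt[sl] = chrom_mrt
    mark_matrix, mark_names = emit_mark_profiles(labels, spec, rngs[2])
    genes: list[GeneModel] = []
    sequences = cgi_masks = None
    if with_genes:
        genes = emit_genes(labels, spec, grid, rngs[3])
    if with_sequence:
        sequences, cgi_masks = emit_sequence(labels, spec, grid, genes, rngs[4])
    return SyntheticGenome(
        spec, seed, grid, labels, mark_matrix, mark_names, mrt, udomains,
        genes, sequences, cgi_masks,
    )


def generate_genome(spec: SyntheticSpec, seed: int | None = None, **kw) -> SyntheticGenome:
    """Pure-Markov genome (no U-domains): the zero-coverage special case."""
    spec = replace(spec, udomain_params=replace(spec.udomain_params, coverage_fraction=0.0))
    return generate_udomain_genome(spec, seed, **kw)


# ---------------------------------------------------------------------------
# genes and sequence
# ---------------------------------------------------------------------------


def emit_genes(
    states: np.ndarray,
    spec: SyntheticSpec,
    grid: WindowGrid,
    seed: int | np.random.Generator = 0,
) -> list[GeneModel]:
    """Poisson promoter counts per window at the state's density, log-normal
    gene lengths, and RPKM drawn expressed/silent per the state's fraction."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    states = np.asarray(states, dtype=object).astype(str)
    genes: list[GeneModel] = []
    win_mb = grid.window_size / 1e6
    chrom_extent = {
        c: int(grid.starts[sl].max()) + grid.window_size
        for c, sl in grid.chrom_slices().items()
    }
    gi = 0
    for i in range(len(grid)):
        gp = spec.gene_params[states[i]]
        n = rng.poisson(gp.density_per_mb * win_mb)
        for _ in range(n):
            tss = int(grid.starts[i] + rng.integers(0, grid.window_size))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(gp.length_median_kb * 1000 * np.exp(gp.length_sigma * rng.standard_normal()))
            length = int(np.clip(length, 500, 1_000_000))
            chrom = str(grid.chroms[i])
            if strand == "+":
                start, end = tss, min(tss + length, chrom_extent[chrom])
            else:
                start, end = max(tss + 1 - length, 0), tss + 1
            exons = _random_exons(start, end, rng)
            if rng.random() < gp.expressed_fraction:
                rpkm = float(10 ** rng.normal(gp.expr_log10_mean, gp.expr_log10_sd))
            else:
                rpkm = float(10 ** rng.normal(gp.silent_log10_mean, gp.silent_log10_sd))
            genes.append(GeneModel(chrom, start, end, strand, exons, name=f"g{gi}", rpkm=rpkm))
            gi += 1
    return genes


def _random_exons(start: int, end: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    glen = end - start
    n_ex = 1 + min(int(rng.poisson(1.5)), 4)
    if glen < 2 * n_ex * 50:
        return [(start, end)]
    # alternate exon/intron segments; first and last segments are exons so the
    # TSS coincides with the start of the first exon
    n_seg = 2 * n_ex - 1
    props = rng.dirichlet(np.ones(n_seg))
    sizes = np.maximum((props * glen).astype(int), 1)
    sizes[-1] = glen - sizes[:-1].sum()
    if sizes[-1] < 1:
        return [(start, end)]
    bounds = start + np.concatenate(([0], np.cumsum(sizes)))
    return [(int(bounds[k]), int(bounds[k + 1])) for k in range(0, n_seg, 2)]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _dinucleotide_rows(gc: float, oe: float) -> np.ndarray:
    """First-order nucleotide transition matrix hitting GC and CpG o/e targets.

    Only the C->G probability is suppressed (factor ``oe``); the deficit is
    redistributed so the stationary base composition stays (A,C,G,T) =
    ((1-gc)/2, gc/2, gc/2, (1-gc)/2) and the expected CpG o/e equals ``oe``.
    """
    p_c = p_g = gc / 2.0
    p_a = p_t = (1.0 - gc) / 2.0
    delta = p_c * p_g * (1.0 - oe) / (1.0 - p_c)
    base = np.array([p_a, p_c, p_g, p_t])
    rows = np.tile(base, (4, 1))
    # rows for prev in {A, G, T}: boost G, shave A and T equally
    for r in (0, 2, 3):
        rows[r] = [p_a - delta / 2, p_c, p_g + delta, p_t - delta / 2]
    # row for prev = C: suppress G, return the mass to A and T
    back = (1.0 - oe) * p_g / 2.0
    rows[1] = [p_a + back, p_c, oe * p_g, p_t + back]
    if (rows < 0).any():
        raise ValueError(f"infeasible composition targets gc={gc}, cpg_oe={oe}")
    return rows


def emit_sequence(
    states: np.ndarray,
    spec: SyntheticSpec,
    grid: WindowGrid,
    genes: list[GeneModel],
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[list[tuple[int, int]]]]:
    """Per-window sequences from the state's dinucleotide model, plus CpG-island
    mask intervals (window-relative) placed at a fraction of gene promoters."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    states = np.asarray(states, dtype=object).astype(str)
    L = spec.bases_per_window
    n = len(states)
    idx_matrix = np.empty((n, L), dtype=np.uint8)
    for s in np.unique(states):
        sel = np.flatnonzero(states == s)
        sp = spec.seq_params[s]
        rows = _dinucleotide_rows(sp.gc, sp.cpg_oe)
        cum = np.cumsum(rows, axis=1)
        u0 = rng.random(len(sel))
        start_cum = np.cumsum([0.5 - sp.gc / 2, sp.gc / 2, sp.gc / 2, 0.5 - sp.gc / 2])
        cur = (start_cum[None, :3] < u0[:, None]).sum(axis=1).astype(np.uint8)
        idx_matrix[sel, 0] = cur
        us = rng.random((len(sel), L - 1))
        for t in range(1, L):
            c = cum[cur]
            cur = (c[:, :3] < us[:, t - 1][:, None]).sum(axis=1).astype(np.uint8)
            idx_matrix[sel, t] = cur
    sequences = [
        _BASES[idx_matrix[i]].tobytes().decode("ascii") for i in range(n)
    ]
    # CpG islands at a fraction of promoters, in window-relative coordinates
    cgi_masks: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    scale = L / grid.window_size
    for g in genes:
        if rng.random() >= spec.cgi_probability:
            continue
        w = grid.window_index(g.chrom, np.array([g.tss]))[0]
        if w < 0:
            continue
        rel = int((g.tss - grid.starts[w]) * scale)
        cgi_len = max(int(spec.cgi_length * scale), 10)
        a = min(rel, max(L - cgi_len, 0))
        cgi_masks[w].append((a, min(a + cgi_len, L)))
    return sequences, cgi_masks


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------


def write_fixture(genome: SyntheticGenome, directory) -> None:
    """Write the genome as standard track files.

    Per mark: a broadPeak file (one enriched interval per nonzero window) and
    a BED of point reads placed evenly inside the window so that recomputed
    densities equal the emitted matrix exactly.  Plus the MRT table, U-domain
    BED, BED12 gene models with an RPKM table, per-window FASTA with a
    CpG-island BED (coordinates relative to each window record), and the true
    state labels for provenance.
    """
    import pandas as pd

    os.makedirs(directory, exist_ok=True)
    grid = genome.grid
    kb = grid.window_size / 1000.0
    counts = np.round(genome.mark_matrix * kb).astype(np.int64)
    if not np.allclose(counts / kb, genome.mark_matrix, atol=1e-9):
        log.warning("mark densities are not on the 1-read grid; fixture will quantize them")
    for j, mark in enumerate(genome.mark_names):
        nz = np.flatnonzero(counts[:, j] > 0)
        peaks = pd.DataFrame(
            {"chrom": grid.chroms[nz], "start": grid.starts[nz], "end": grid.ends[nz]}
        )
        tracks_io.write_broadpeak(peaks, os.path.join(directory, f"{mark}.broadPeak"))
        with open(os.path.join(directory, f"{mark}.reads.bed"), "w") as fh:
            for i in nz:
                c = counts[i, j]
                pos = grid.starts[i] + ((np.arange(c) + 0.5) * grid.window_size / c).astype(int)
                for p in pos:
                    fh.write(f"{grid.chroms[i]}\t{p}\t{p + 1}\n")
    tracks_io.write_mrt_table(grid, genome.mrt, os.path.join(directory, "mrt.tsv"))
    import pandas as pd  # noqa: F811

    ud = pd.DataFrame(
        [(d.chrom, d.start, d.end) for d in genome.udomains],
        columns=["chrom", "start", "end"],
    )
    tracks_io.write_bed3(ud, os.path.join(directory, "udomains.bed"))
    tracks_io.write_gene_annotation(genome.genes, os.path.join(directory, "genes.bed12"))
    tracks_io.write_rpkm_table(genome.genes, os.path.join(directory, "rpkm.tsv"))
    if genome.sequences is not None:
        _write_fasta(genome, os.path.join(directory, "sequence.fasta"))
        with open(os.path.join(directory, "cgi.bed"), "w") as fh:
            for i, ivs in enumerate(genome.cgi_masks or []):
                rec = f"{grid.chroms[i]}:{grid.starts[i]}-{grid.ends[i]}"
                for a, b in ivs:
                    fh.write(f"{rec}\t{a}\t{b}\n")
    with open(os.path.join(directory, "true_states.tsv"), "w") as fh:
        for i in range(len(grid)):
            fh.write(
                f"{grid.chroms[i]}\t{grid.starts[i]}\t{grid.ends[i]}\t{genome.true_states[i]}\n"
            )
    with open(os.path.join(directory, "provenance.json"), "w") as fh:
        json.dump(
            {
                "seed": genome.seed,
                "n_chromosomes": genome.spec.n_chromosomes,
                "windows_per_chromosome": genome.spec.windows_per_chromosome,
                "window_size": genome.spec.window_size,
                "bases_per_window": genome.spec.bases_per_window,
                "marks": genome.mark_names,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def _write_fasta(genome: SyntheticGenome, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    grid = genome.grid
    records = [
        SeqRecord(
            Seq(genome.sequences[i]),
            id=f"{grid.chroms[i]}:{grid.starts[i]}-{grid.ends[i]}",
            description="",
        )
        for i in range(len(grid))
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fixture(directory) -> dict:
    """Read a written fixture back through the standard track readers.

    Returns a dict with the grid, recomputed mark density matrix, MRT,
    U-domains, genes (with RPKM attached), sequences/CGI masks if present,
    and the true state labels.
    """
    import pandas as pd

    states_path = os.path.join(directory, "true_states.tsv")
    df = pd.read_csv(states_path, sep="\t", header=None, names=["chrom", "start", "end", "state"])
    with open(os.path.join(directory, "provenance.json")) as fh:
        prov = json.load(fh)
    window_size = int(prov["window_size"])
    grid = WindowGrid(
        df["chrom"].to_numpy(dtype=object), df["start"].to_numpy(), window_size
    )
    peak_files = {
        os.path.basename(p)[: -len(".broadPeak")]: p
        for p in sorted(glob.glob(os.path.join(directory, "*.broadPeak")))
    }
    read_files = {m: os.path.join(directory, f"{m}.reads.bed") for m in peak_files}
    matrix, marks = tracks_io.profile_matrix(read_files, peak_files, grid)
    mrt, mask = tracks_io.read_mrt_table(os.path.join(directory, "mrt.tsv"), grid)
    grid.mrt_defined = mask
    udomains = tracks_io.read_udomains(os.path.join(directory, "udomains.bed"))
    genes = tracks_io.read_gene_annotation(os.path.join(directory, "genes.bed12"))
    rpkm = tracks_io.read_rpkm_table(os.path.join(directory, "rpkm.tsv"))
    for g in genes:
        g.rpkm = rpkm.get(g.name, float("nan"))
    out = {
        "grid": grid,
        "mark_matrix": matrix,
        "mark_names": marks,
        "mrt": mrt,
        "udomains": udomains,
        "genes": genes,
        "true_states": df["state"].to_numpy(dtype=object),
    }
    fasta = os.path.join(directory, "sequence.fasta")
    if os.path.exists(fasta):
        from Bio import SeqIO

        recs = {r.id: str(r.seq) for r in SeqIO.parse(fasta, "fasta")}
        ids = [f"{grid.chroms[i]}:{grid.starts[i]}-{grid.ends[i]}" for i in range(len(grid))]
        out["sequences"] = [recs[i] for i in ids]
        cgi: list[list[tuple[int, int]]] = [[] for _ in range(len(grid))]
        cgi_path = os.path.join(directory, "cgi.bed")
        if os.path.exists(cgi_path) and os.path.getsize(cgi_path):
            cdf = pd.read_csv(cgi_path, sep="\t", header=None, names=["rec", "start", "end"])
            pos = {rid: i for i, rid in enumerate(ids)}
            for r in cdf.itertuples():
                cgi[pos[r.rec]].append((int(r.start), int(r.end)))
        out["cgi_masks"] = cgi
    return out
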