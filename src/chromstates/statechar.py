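"""Per-state characterization: replication timing, genes, expression,
sequence composition, and term enrichment.

Genes are attached to the chromatin state of the window containing their
promoter (TSS); genes whose promoter falls in an unclassified window are
excluded from state-level gene statistics.  Sequence composition uses GC
content on the native sequence and the CpG observed/expected ratio after
masking annotated CpG islands; CpG o/e is a standard sequence proxy for DNA
methylation (lower o/e, higher methylation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grid import WindowGrid
from .tracks_io import GeneModel

log = logging.getLogger(__name__)

STATE_ORDER = ("C1", "C2", "C3", "C4")


# ---------------------------------------------------------------------------
# replication timing
# ---------------------------------------------------------------------------


def mrt_by_state(
    mrt: np.ndarray, labels: np.ndarray, states: tuple[str, ...] = STATE_ORDER
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-state MRT summaries and pairwise two-sided Wilcoxon rank-sum tests.

    Returns ``(summary, tests)``.  ``summary`` has quartiles and means per
    state; ``tests`` one row per state pair with the rank-sum statistic W (sum
    of ranks of the first sample in the pooled ranking) and the normal-
    approximation p-value with tie correction.  States with fewer than two
    windows are excluded from testing.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    mrt = np.asarray(mrt, dtype=float)
    ok = np.isfinite(mrt)
    samples = {s: mrt[ok & (labels == s)] for s in states if (ok & (labels == s)).any()}
    rows = []
    for s, x in samples.items():
        q1, q2, q3 = np.percentile(x, [25, 50, 75])
        rows.append({"state": s, "n": len(x), "mean": x.mean(), "q1": q1, "median": q2, "q3": q3})
    summary = pd.DataFrame(rows)
    testable = [s for s, x in samples.items() if len(x) >= 2]
    dropped = sorted(set(samples) - set(testable))
    if dropped:
        log.info("states excluded from rank-sum tests (<2 windows): %s", dropped)
    trows = []
    for i, s1 in enumerate(testable):
        for s2 in testable[i + 1:]:
            x, y = samples[s1], samples[s2]
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            W = float(res.statistic + len(x) * (len(x) + 1) / 2.0)  # U -> rank sum
            trows.append({"state_a": s1, "state_b": s2, "rank_sum": W, "p": float(res.pvalue)})
    return summary, pd.DataFrame(trows)


def mrt_ecdf(mrt: np.ndarray, labels: np.ndarray, state: str) -> tuple[np.ndarray, np.ndarray]:
    """Empirical c.d.f. support and values for one state's MRT sample."""
    x = np.sort(np.asarray(mrt, float)[np.asarray(labels).astype(str) == state])
    return x, np.arange(1, len(x) + 1) / len(x)


# ---------------------------------------------------------------------------
# gene content (per-state gene table)
# ---------------------------------------------------------------------------


def assign_genes_to_states(
    genes: list[GeneModel], labels: np.ndarray, grid: WindowGrid
) -> pd.Series:
    """State of the window containing each gene's promoter ('D' or None if outside)."""
    out = {}
    labels = np.asarray(labels, dtype=object)
    for g in genes:
        idx = grid.window_index(g.chrom, np.array([g.tss]))[0]
        if idx < 0:
            log.info("gene %s TSS outside the window grid; excluded", g.name or g.tss)
            out[id(g)] = None
        else:
            out[id(g)] = str(labels[idx])
    return pd.Series(out)


def gene_state_table(
    genes: list[GeneModel],
    labels: np.ndarray,
    grid: WindowGrid,
    states: tuple[str, ...] = STATE_ORDER,
) -> pd.DataFrame:
    """Per-state gene content table.

    Columns: gene fraction (% of genes classified into the four states), gene
    density (promoters per Mb of state territory), median and mean gene
    length (kb), and gene coverage (% of state bp covered by gene bodies).
    """
    gene_states = assign_genes_to_states(genes, labels, grid)
    by_state: dict[str, list[GeneModel]] = {s: [] for s in states}
    for g in genes:
        st = gene_states[id(g)]
        if st in by_state:
            by_state[st].append(g)
    n_classified = sum(len(v) for v in by_state.values())
    labels = np.asarray(labels, dtype=object).astype(str)
    slices = grid.chrom_slices()
    rows = []
    for s in states:
        gs = by_state[s]
        state_windows = labels == s
        territory_bp = state_windows.sum() * grid.window_size
        lengths_kb = np.array([(g.end - g.start) / 1000.0 for g in gs])
        # coverage: union of gene bodies intersected with the state's windows
        covered = 0
        for chrom, sl in slices.items():
            w_starts = grid.starts[sl][state_windows[sl]]
            if len(w_starts) == 0:
                continue
            from .tracks_io import merge_intervals

            bodies = merge_intervals([(g.start, g.end) for g in genes if g.chrom == chrom])
            bs = np.array([x for x, _ in bodies], dtype=np.int64)
            be = np.array([y for _, y in bodies], dtype=np.int64)
            for ws in w_starts:
                we = ws + grid.window_size
                o = np.minimum(be, we) - np.maximum(bs, ws)
                covered += int(o[o > 0].sum())
        rows.append(
            {
                "state": s,
                "n_genes": len(gs),
                "gene_fraction_pct": 100.0 * len(gs) / n_classified if n_classified else 0.0,
                "gene_density_per_mb": len(gs) / (territory_bp / 1e6) if territory_bp else 0.0,
                "median_length_kb": float(np.median(lengths_kb)) if len(gs) else 0.0,
                "mean_length_kb": float(lengths_kb.mean()) if len(gs) else 0.0,
                "gene_coverage_pct": 100.0 * covered / territory_bp if territory_bp else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def expression_by_state(
    genes: list[GeneModel],
    labels: np.ndarray,
    grid: WindowGrid,
    states: tuple[str, ...] = STATE_ORDER,
    bin_width: float = 0.05,
    zero_floor: float = -3.0,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], pd.DataFrame]:
    """Per-state expression c.d.f.s and promoter density vs log10(RPKM).

    Zero-RPKM genes are placed at ``zero_floor`` (log10 units) for the c.d.f.
    only.  The density table bins expressed genes into [m*w, (m+1)*w) bins of
    width ``bin_width`` in log10(RPKM).
    """
    gene_states = assign_genes_to_states(genes, labels, grid)
    labels_str = np.asarray(labels, dtype=object).astype(str)
    cdfs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for s in states:
        gs = [g for g in genes if gene_states[id(g)] == s and np.isfinite(g.rpkm)]
        territory_mb = (labels_str == s).sum() * grid.window_size / 1e6
        vals = np.array([g.rpkm for g in gs])
        logv = np.where(vals > 0, np.log10(np.maximum(vals, 1e-300)), zero_floor)
        x = np.sort(logv)
        cdfs[s] = (x, np.arange(1, len(x) + 1) / len(x) if len(x) else np.array([]))
        expressed = logv[vals > 0]
        if len(expressed):
            b = np.floor(expressed / bin_width).astype(int)
            for m in range(b.min(), b.max() + 1):
                cnt = int((b == m).sum())
                if cnt:
                    rows.append(
                        {
                            "state": s,
                            "bin_left": m * bin_width,
                            "n_genes": cnt,
                            "promoter_density_per_mb": cnt / territory_mb if territory_mb else 0.0,
                        }
                    )
    return cdfs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence composition
# ---------------------------------------------------------------------------


@dataclass
class CompositionRecord:
    n_c: int
    n_g: int
    n_cg: int
    L: int       # non-masked A/C/G/T nucleotides
    l: int       # number of unmasked runs (masked-gap count + 1 for interior gaps)
    gc: float
    cpg_oe: float


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); N and other characters are excluded from both counts."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def cpg_oe(sequence: str, cgi_mask: list[tuple[int, int]] | None = None) -> CompositionRecord:
    """CpG observed/expected ratio with CpG islands masked.

    Counts C, G and CG dinucleotides over the unmasked runs of the sequence
    (CG pairs spanning a mask boundary are not counted).  With L unmasked
    nucleotides split into l runs, the number of dinucleotide sites is L - l
    and

        CpG o/e = (N_CG / (L - l)) / ((N_C / L) * (N_G / L)).
    """
    s = sequence.upper()
    mask = np.zeros(len(s), dtype=bool)
    for a, b in cgi_mask or []:
        if a < 0 or b > len(s):
            raise ValueError(f"mask interval ({a},{b}) outside sequence bounds")
        mask[a:b] = True
    arr = np.frombuffer(s.encode(), dtype="S1")
    mask |= ~np.isin(arr, [b"A", b"C", b"G", b"T"])  # N and gaps behave as masked
    keep = ~mask
    runs: list[str] = []
    i = 0
    n = len(s)
    while i < n:
        if keep[i]:
            j = i
            while j < n and keep[j]:
                j += 1
            runs.append(s[i:j])
            i = j
        else:
            i += 1
    n_c = sum(r.count("C") for r in runs)
    n_g = sum(r.count("G") for r in runs)
    n_cg = sum(r.count("CG") for r in runs)
    L = sum(len(r) for r in runs)
    l = len(runs)
    sites = L - l
    if sites <= 0 or n_c == 0 or n_g == 0:
        oe = float("nan") if sites <= 0 else 0.0
        if sites <= 0:
            log.info("composition undefined: no dinucleotide sites after masking")
    else:
        oe = (n_cg / sites) / ((n_c / L) * (n_g / L))
    return CompositionRecord(n_c, n_g, n_cg, L, l, gc_content(sequence) if L else float("nan"), oe)


def composition_by_state(
    sequences: list[str],
    cgi_masks: list[list[tuple[int, int]]],
    labels: np.ndarray,
    states: tuple[str, ...] = STATE_ORDER,
) -> pd.DataFrame:
    """Pooled per-state GC content and CpG o/e over per-window sequences."""
    labels = np.asarray(labels, dtype=object).astype(str)
    rows = []
    for s in states:
        idx = np.flatnonzero(labels == s)
        if idx.size == 0:
            continue
        gc_num = gc_den = 0
        n_c = n_g = n_cg = L = l = 0
        for i in idx:
            seq = sequences[i]
            up = seq.upper()
            g = up.count("G") + up.count("C")
            a = up.count("A") + up.count("T")
            gc_num += g
            gc_den += g + a
            rec = cpg_oe(seq, cgi_masks[i] if cgi_masks else None)
            n_c += rec.n_c
            n_g += rec.n_g
            n_cg += rec.n_cg
            L += rec.L
            l += rec.l
        sites = L - l
        oe = (n_cg / sites) / ((n_c / L) * (n_g / L)) if sites > 0 and n_c and n_g else float("nan")
        rows.append(
            {"state": s, "n_windows": len(idx), "gc": gc_num / gc_den if gc_den else float("nan"),
             "cpg_oe": oe}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------


def term_enrichment(
    gene_states: dict[str, str],
    gene_terms: dict[str, set[str]],
    states: tuple[str, ...] = STATE_ORDER,
    fdr: float = 0.20,
) -> pd.DataFrame:
    """Fisher's exact test of term enrichment per (state, term).

    For each state and annotation term the 2x2 table counts classified genes
    by state membership and term membership.  Two-sided p-values are
    corrected with Benjamini-Hochberg at the given FDR; the odds ratio gives
    the direction (>1 enrichment, <1 depletion).
    """
    genes = [g for g, s in gene_states.items() if s in states]
    terms = sorted({t for g in genes for t in gene_terms.get(g, ())})
    rows = []
    for s in states:
        in_state = {g for g in genes if gene_states[g] == s}
        for t in terms:
            with_t = {g for g in genes if t in gene_terms.get(g, ())}
            if not with_t:
                continue
            a = len(in_state & with_t)
            b = len(in_state) - a
            c = len(with_t) - a
            d = len(genes) - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"state": s, "term": t, "in_state_with_term": a, "in_state_without": b,
                 "out_state_with_term": c, "out_state_without": d,
                 "odds_ratio": float(odds), "p": float(p)}
            )
    df = pd.DataFrame(rows)
    if len(df):
        reject, q, _, _ = multipletests(df["p"], alpha=fdr, method="fdr_bh")
        df["q"] = q
        df["significant"] = reject
    return df
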