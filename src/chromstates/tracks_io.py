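"""Readers/writers for genomic track formats and per-window profile computation.

Formats handled: ENCODE broadPeak (enriched ChIP-seq intervals), BED3 read
positions and U-domain coordinates, BED12 gene models, and tab-separated
mean-replication-timing (MRT) and RPKM tables.  All coordinates are 0-based
half-open, matching the BED convention.

The central computation is :func:`compute_density_profile`: the read density
of one antibody in a window is the number of reads in the window that fall
inside significantly enriched intervals, normalized by the window length
(reported here in reads per kb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import WindowGrid

log = logging.getLogger(__name__)

BROADPEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
]


class ParseError(ValueError):
    pass


@dataclass
class UDomain:
    """A replication-timing U-domain: MRT early at both borders, late at center."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"U-domain end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A (possibly merged) gene with its exon structure and expression.

    ``rpkm`` is reads per kilobase of exon model per million mapped reads;
    ``exon_length`` is the length of the union of exons in bp.
    """

    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    name: str = ""
    rpkm: float = float("nan")

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon ({s},{e}) outside gene [{self.start},{self.end})")

    @property
    def tss(self) -> int:
        """Promoter position: gene start on '+', gene end - 1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in merge_intervals(self.exons))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_broadpeak(path) -> pd.DataFrame:
    """Read a broadPeak (or any >=3 column BED-like) file of enriched intervals."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if start > end:
                raise ParseError(f"{path}:{ln}: start {start} > end {end}")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_reads_bed(path) -> pd.DataFrame:
    """Read sequencing read positions from BED; interval reads use their midpoint."""
    df = read_broadpeak(path)
    df["pos"] = (df["start"] + df["end"]) // 2
    return df[["chrom", "pos"]]


def read_mrt_table(path, grid: WindowGrid) -> tuple[np.ndarray, np.ndarray]:
    """Read a (chrom, start, MRT) table onto ``grid``.

    Returns ``(mrt, mask)``: per-window MRT (NaN where missing) and a boolean
    mask of windows covered by the table.  MRT must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "mrt"], comment="#")
    if len(df) and ((df["mrt"] < 0) | (df["mrt"] > 1)).any():
        bad = df[(df["mrt"] < 0) | (df["mrt"] > 1)].iloc[0]
        raise ValueError(f"MRT value {bad['mrt']} outside [0,1] at {bad['chrom']}:{bad['start']}")
    mrt = np.full(len(grid), np.nan)
    mask = np.zeros(len(grid), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = grid.window_index(str(chrom), sub["start"].to_numpy())
        ok = idx >= 0
        mrt[idx[ok]] = sub["mrt"].to_numpy()[ok]
        mask[idx[ok]] = True
    return mrt, mask


def read_udomains(path) -> list[UDomain]:
    """Read U-domains from BED3; overlapping domains on a chromosome are rejected."""
    df = read_broadpeak(path)
    domains = [UDomain(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]
    by_chrom: dict[str, list[UDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, ds in by_chrom.items():
        ds.sort(key=lambda d: d.start)
        for a, b in zip(ds[:-1], ds[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping U-domains on {chrom}: {a} and {b}")
    return domains


def read_gene_annotation(path) -> list[GeneModel]:
    """Read gene models from BED12 (chrom, start, end, name, score, strand,
    thickStart, thickEnd, rgb, blockCount, blockSizes, blockStarts)."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ParseError(f"{path}:{ln}: expected 12 BED12 columns")
            start, end = int(p[1]), int(p[2])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(p[0], start, end, p[5], exons, name=p[3]))
    return genes


def read_rpkm_table(path) -> dict[str, float]:
    """Read a two-column (gene name, RPKM) tab-separated table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "rpkm"], comment="#")
    return dict(zip(df["name"].astype(str), df["rpkm"].astype(float)))


# ---------------------------------------------------------------------------
# writers (used by the synthetic-fixture round trip and the CLI)
# ---------------------------------------------------------------------------


def write_broadpeak(df: pd.DataFrame, path) -> None:
    """Write enriched intervals as 9-column broadPeak."""
    with open(path, "w") as fh:
        for i, r in enumerate(df.itertuples()):
            fh.write(
                f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\tpeak{i}\t0\t.\t0\t-1\t-1\n"
            )


def write_bed3(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in df.itertuples():
            fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\n")


def write_mrt_table(grid: WindowGrid, mrt: np.ndarray, path) -> None:
    """Write (chrom, start, MRT) rows for windows where MRT is defined."""
    with open(path, "w") as fh:
        for i in range(len(grid)):
            if grid.mrt_defined[i] and np.isfinite(mrt[i]):
                fh.write(f"{grid.chroms[i]}\t{int(grid.starts[i])}\t{mrt[i]:.6f}\n")


def write_gene_annotation(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = merge_intervals(g.exons)
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s - g.start) for s, _ in exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


def write_rpkm_table(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            if np.isfinite(g.rpkm):
                fh.write(f"{g.name}\t{g.rpkm:.6g}\n")


# ---------------------------------------------------------------------------
# profile computation
# ---------------------------------------------------------------------------


def compute_density_profile(
    reads: pd.DataFrame, intervals: pd.DataFrame, grid: WindowGrid
) -> np.ndarray:
    """Per-window read density (reads/kb) restricted to enriched intervals.

    ``reads`` has columns (chrom, pos); ``intervals`` has (chrom, start, end).
    A read contributes to a window iff its position lies in the window and
    inside some enriched interval.  Reads on chromosomes absent from the grid
    are ignored (a summary is logged).
    """
    counts = np.zeros(len(grid), dtype=np.int64)
    slices = grid.chrom_slices()
    ivs_by_chrom = {str(c): sub for c, sub in intervals.groupby("chrom", sort=False)}
    skipped = 0
    for chrom, sub in reads.groupby("chrom", sort=False):
        chrom = str(chrom)
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if chrom not in slices:
            skipped += len(pos)
            continue
        ivs = ivs_by_chrom.get(chrom)
        if ivs is None or len(ivs) == 0:
            continue
        merged = merge_intervals(list(zip(ivs["start"], ivs["end"])))
        istarts = np.array([s for s, _ in merged], dtype=np.int64)
        iends = np.array([e for _, e in merged], dtype=np.int64)
        j = np.searchsorted(istarts, pos, side="right") - 1
        inside = (j >= 0) & (pos < iends[np.clip(j, 0, None)])
        widx = grid.window_index(chrom, pos[inside])
        widx = widx[widx >= 0]
        np.add.at(counts, widx, 1)
    if skipped:
        log.warning("%d reads on chromosomes absent from the grid were ignored", skipped)
    return counts / (grid.window_size / 1000.0)


def profile_matrix(
    read_files: dict[str, object], peak_files: dict[str, object], grid: WindowGrid
) -> tuple[np.ndarray, list[str]]:
    """Build the windows x marks density matrix from per-mark read/peak files."""
    marks = sorted(read_files)
    if sorted(peak_files) != marks:
        raise ValueError("read and peak file sets must name the same marks")
    cols = []
    for mark in marks:
        reads = read_reads_bed(read_files[mark])
        peaks = read_broadpeak(peak_files[mark])
        cols.append(compute_density_profile(reads, peaks, grid))
    return np.column_stack(cols) if cols else np.zeros((len(grid), 0)), marks


# ---------------------------------------------------------------------------
# gene utilities
# ---------------------------------------------------------------------------


def merge_overlapping_genes(genes: list[GeneModel]) -> list[GeneModel]:
    """Merge overlapping same-strand genes into one spanning gene.

    Merged coordinates are the union of the member coordinates and the merged
    exon set is the union of member exons.  Overlap chains merge transitively.
    Genes on opposite strands never merge.  Idempotent.
    """
    out: list[GeneModel] = []
    keyed: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        keyed.setdefault((g.chrom, g.strand), []).append(g)
    for (chrom, strand), gs in keyed.items():
        gs = sorted(gs, key=lambda g: (g.start, g.end))
        group = [gs[0]]
        for g in gs[1:]:
            if g.start < max(m.end for m in group):
                group.append(g)
            else:
                out.append(_merge_group(group))
                group = [g]
        out.append(_merge_group(group))
    out.sort(key=lambda g: (g.chrom, g.start, g.end))
    return out


def _merge_group(group: list[GeneModel]) -> GeneModel:
    if len(group) == 1:
        return group[0]
    g0 = group[0]
    exons = merge_intervals([iv for g in group for iv in g.exons])
    name = "|".join(dict.fromkeys(g.name for g in group if g.name))
    return GeneModel(
        g0.chrom,
        min(g.start for g in group),
        max(g.end for g in group),
        g0.strand,
        exons,
        name=name,
    )


def compute_rpkm(C: float, N: float, L: float) -> float:
    """Reads per kilobase of exon model per million mapped reads.

    ``C``: mappable reads falling in the gene's exon union; ``N``: total
    mappable reads in the experiment; ``L``: total exon length in bp.
    """
    if N <= 0 or L <= 0:
        raise ValueError("RPKM requires N > 0 and L > 0")
    return C / ((N / 1e6) * (L / 1e3))
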