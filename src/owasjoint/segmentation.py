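"""Regulatory regions around gene TSSs, tiled into candidate segments.

A regulatory region is the +/- ``window`` bp interval (default 100 kb)
around each transcription start site.  Overlapping gene windows are merged
before tiling so that each SNP is tested exactly once; gene attribution is
recovered afterwards by intersecting segments with each gene's own window.
Segments are the unit of association testing (default 5 kb tiles).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import HarmonizedVariant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneTss:
    gene_id: str
    gene_name: str
    chrom: str
    tss: int  # 1-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"{self.gene_id}: tss must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class Region:
    """A merged regulatory interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    gene_ids: set[str] = field(default_factory=set)


@dataclass
class Segment:
    segment_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    snp_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    gene_ids: set[str] = field(default_factory=set)

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


def read_tss_table(path: str | Path) -> list[GeneTss]:
    """Read a 4-column TSS table: chrom, tss, strand, gene (header optional)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.iloc[0, 1] is not None and not str(df.iloc[0, 1]).isdigit():
        df = df.iloc[1:]  # header row
    genes = []
    for _, row in df.iterrows():
        genes.append(
            GeneTss(
                gene_id=str(row[3]),
                gene_name=str(row[3]),
                chrom=str(row[0]),
                tss=int(row[1]),
                strand=str(row[2]),
            )
        )
    return genes


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_tss_gtf(path: str | Path) -> list[GeneTss]:
    """Extract one TSS per gene from a GTF: the 5' end of the first
    transcript (strand-aware; lowest start for +, highest end for -)."""
    best: dict[str, GeneTss] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "transcript":
                continue
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                continue
            strand = parts[6]
            tss = int(parts[3]) if strand == "+" else int(parts[4])
            cand = GeneTss(
                gene_id=gene_id,
                gene_name=attrs.get("gene_name", gene_id),
                chrom=parts[0],
                tss=tss,
                strand=strand,
            )
            prev = best.get(gene_id)
            if prev is None:
                best[gene_id] = cand
            elif (strand == "+" and tss < prev.tss) or (strand == "-" and tss > prev.tss):
                best[gene_id] = cand
    return list(best.values())


def build_regulatory_regions(
    genes: Sequence[GeneTss], window: int = 100_000
) -> dict[str, list[Region]]:
    """Merge the per-gene +/- window intervals into disjoint regions per
    chromosome; each region remembers its contributing genes."""
    if not genes:
        raise ValueError("empty gene list")
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        start = max(1, g.tss - window)
        end = g.tss + window
        by_chrom.setdefault(g.chrom, []).append((start, end, g.gene_id))
    regions: dict[str, list[Region]] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        merged: list[Region] = []
        for start, end, gid in ivals:
            if merged and start <= merged[-1].end + 1:
                merged[-1].end = max(merged[-1].end, end)
                merged[-1].gene_ids.add(gid)
            else:
                merged.append(Region(chrom, start, end, {gid}))
        regions[chrom] = merged
    return regions


def tile_segments(
    regions: dict[str, list[Region]],
    mode: str = "by_length",
    value: int = 5000,
    variants: Sequence[HarmonizedVariant] | None = None,
) -> list[Segment]:
    """Tile merged regions into candidate segments.

    ``by_length``: consecutive ``value``-bp windows anchored at each region
    start (last window may be shorter).  ``by_snp_count``: consecutive runs
    of ``value`` harmonized SNPs, the segment spanning their positions.
    """
    if mode not in ("by_length", "by_snp_count"):
        raise ValueError(f"unknown tiling mode {mode!r}")
    if value < 1:
        raise ValueError("tiling value must be >= 1")
    segments: list[Segment] = []
    if mode == "by_length":
        for chrom in sorted(regions):
            for region in regions[chrom]:
                start = region.start
                while start <= region.end:
                    end = min(start + value - 1, region.end)
                    segments.append(
                        Segment(f"{chrom}:{start}-{end}", chrom, start, end, gene_ids=set(region.gene_ids))
                    )
                    start = end + 1
    else:
        if variants is None:
            raise ValueError("by_snp_count tiling requires the harmonized variants")
        for chrom in sorted(regions):
            positions = np.array([v.pos for v in variants if v.chrom == chrom], dtype=int)
            positions.sort()
            for region in regions[chrom]:
                inside = positions[(positions >= region.start) & (positions <= region.end)]
                for i in range(0, len(inside), value):
                    run = inside[i : i + value]
                    start, end = int(run[0]), int(run[-1])
                    segments.append(
                        Segment(f"{chrom}:{start}-{end}", chrom, start, end, gene_ids=set(region.gene_ids))
                    )
    return segments


def assign_snps(
    segments: list[Segment],
    variants: Sequence[HarmonizedVariant],
    min_snps: int = 1,
    drop_empty: bool = True,
) -> list[Segment]:
    """Fill each segment's SNP index set from the sorted harmonized table.

    Each variant lands in at most one segment (the tiling is a partition of
    the merged regions); segments with fewer than ``min_snps`` variants are
    dropped.  Requires variants sorted by (chrom, pos).
    """
    keys = [(v.chrom, v.pos) for v in variants]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (chrom, pos)")
    for seg in segments:
        seg.snp_indices = np.array([], dtype=int)
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    n_unassigned = 0
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        idx = np.array([i for i, v in enumerate(variants) if v.chrom == chrom], dtype=int)
        if len(idx) == 0:
            continue
        pos = np.array([variants[i].pos for i in idx])
        which = np.searchsorted(starts, pos, side="right") - 1
        ok = (which >= 0) & (pos <= ends[np.clip(which, 0, None)])
        n_unassigned += int((~ok).sum())
        for s_i in np.unique(which[ok]):
            segs[s_i].snp_indices = idx[ok & (which == s_i)]
    n_unassigned += sum(
        1 for v in variants if v.chrom not in by_chrom
    )
    if drop_empty:
        kept = [s for s in segments if s.n_snps >= min_snps]
    else:
        kept = [s for s in segments if s.n_snps >= min_snps or s.n_snps == 0]
    logger.info(
        "assigned SNPs to %d/%d segments (min_snps=%d); %d variants outside regions",
        len(kept), len(segments), min_snps, n_unassigned,
    )
    return kept


def map_segments_to_genes(
    segments: Sequence[Segment],
    genes: Sequence[GeneTss],
    window: int = 100_000,
) -> dict[str, list[str]]:
    """Gene -> segment_ids: every segment overlapping the gene's own
    (unmerged) +/- window interval."""
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    mapping: dict[str, list[str]] = {}
    for g in genes:
        lo, hi = max(1, g.tss - window), g.tss + window
        hits = [
            s.segment_id
            for s in by_chrom.get(g.chrom, [])
            if s.start <= hi and s.end >= lo
        ]
        mapping[g.gene_id] = sorted(hits)
    return mapping


def write_segments_bed(segments: Iterable[Segment], path: str | Path) -> None:
    """BED6 on disk (0-based half-open per the BED convention)."""
    rows = [
        (s.chrom, s.start - 1, s.end, s.segment_id, 0, ".")
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
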