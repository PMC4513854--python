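"""TSS-relative annotation of peaks and feature-enrichment statistics.

Peaks are annotated by their summit (a point, so the nine feature
categories are mutually exclusive): inside a transcript the summit is a
5' UTR, 3' UTR, exon or intron position; outside, it falls in the
proximal (0-1 kb) or distal (1-3 kb) promoter upstream of a TSS, the
proximal/distal downstream windows past the transcript end, or distal
intergenic space. Enrichment over a matched random control (intervals
centred on sampled input-tag positions, inheriting real peak widths) is
reported as per-category log2 ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .formats import GenomicInterval, GeneModel, Tag


class FeatureCategory(str, Enum):
    DISTAL_PROMOTER = "distal_promoter"
    PROXIMAL_PROMOTER = "proximal_promoter"
    UTR5 = "utr5"
    EXON = "exon"
    INTRON = "intron"
    UTR3 = "utr3"
    PROXIMAL_DOWNSTREAM = "proximal_downstream"
    DISTAL_DOWNSTREAM = "distal_downstream"
    DISTAL_INTERGENIC = "distal_intergenic"


PROXIMAL_BP = 1_000
DISTAL_BP = 3_000

# per-category sentinels for enrichment ratios
INF = float("inf")
UNDEFINED = float("nan")


@dataclass
class FeatureDistribution:
    """Counts and percentages per feature category."""

    counts: dict[FeatureCategory, int]
    total: int

    @classmethod
    def from_categories(cls, categories: Sequence[FeatureCategory]) -> "FeatureDistribution":
        counts = {c: 0 for c in FeatureCategory}
        for cat in categories:
            counts[cat] += 1
        return cls(counts, len(categories))

    @property
    def percentages(self) -> dict[FeatureCategory, float]:
        if self.total == 0:
            return {c: 0.0 for c in FeatureCategory}
        return {c: 100.0 * n / self.total for c, n in self.counts.items()}


class GeneIndex:
    """Per-chromosome transcript interval trees and sorted TSS arrays."""

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("gene list must be non-empty")
        self.genes = list(genes)
        self.trees: dict[str, IntervalTree] = {}
        tss_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for gi, g in enumerate(self.genes):
            self.trees.setdefault(g.chrom, IntervalTree()).addi(
                g.tx_start, g.tx_end, gi
            )
            tss_by_chrom.setdefault(g.chrom, []).append((g.tss, gi))
        self.tss_pos: dict[str, np.ndarray] = {}
        self.tss_gene: dict[str, np.ndarray] = {}
        for chrom, pairs in tss_by_chrom.items():
            pairs.sort()
            self.tss_pos[chrom] = np.array([p for p, _ in pairs])
            self.tss_gene[chrom] = np.array([gi for _, gi in pairs])

    def nearest_tss(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        """Gene with the nearest TSS and the signed gene-oriented distance
        (negative = upstream of the TSS)."""
        if chrom not in self.tss_pos:
            return None
        arr = self.tss_pos[chrom]
        i = np.searchsorted(arr, pos)
        best: tuple[int, int] | None = None  # (|dist|, gene idx)
        for j in (i - 1, i):
            if 0 <= j < arr.size:
                d = abs(pos - int(arr[j]))
                if best is None or d < best[0]:
                    best = (d, int(self.tss_gene[chrom][j]))
        if best is None:
            return None
        gene = self.genes[best[1]]
        signed = (pos - gene.tss) if gene.strand == "+" else (gene.tss - pos)
        return gene, signed


def _signed_tss_distance(gene: GeneModel, pos: int) -> int:
    return (pos - gene.tss) if gene.strand == "+" else (gene.tss - pos)


def tss_distances(
    peaks: Sequence,
    genes: Sequence[GeneModel],
    bin_width: int = 50,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Signed summit-to-nearest-TSS distances and their histogram.

    Distances are in transcript orientation (negative = upstream). The
    histogram uses bins aligned so that ``[0, bin_width)`` contains 0;
    returns ``(distances, (bin_edges, counts))``.
    """
    index = GeneIndex(genes)
    dists: list[int] = []
    for p in peaks:
        hit = index.nearest_tss(p.interval.chrom, p.summit)
        if hit is not None:
            dists.append(hit[1])
    arr = np.array(dists, dtype=np.int64)
    if arr.size == 0:
        return arr, (np.array([0, bin_width]), np.zeros(1, dtype=np.int64))
    lo = math.floor(arr.min() / bin_width) * bin_width
    hi = (math.floor(arr.max() / bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + 1, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    return arr, (edges, counts)


def _category_in_transcript(gene: GeneModel, pos: int) -> FeatureCategory:
    in_exon = any(e.start <= pos < e.end for e in gene.exons)
    if not in_exon:
        return FeatureCategory.INTRON
    if gene.cds_start is None:
        return FeatureCategory.EXON
    if gene.strand == "+":
        if pos < gene.cds_start:
            return FeatureCategory.UTR5
        if pos >= gene.cds_end:
            return FeatureCategory.UTR3
    else:
        if pos >= gene.cds_end:
            return FeatureCategory.UTR5
        if pos < gene.cds_start:
            return FeatureCategory.UTR3
    return FeatureCategory.EXON


def classify_location(
    peak,
    genes: Sequence[GeneModel] | GeneIndex,
    downstream_of: str = "tx_end",
) -> FeatureCategory:
    """Feature category of one peak's summit (see module docstring).

    ``downstream_of`` selects how the downstream windows are anchored:
    ``"tx_end"`` (default) measures from the transcript end, the reading
    that keeps the nine categories disjoint; ``"tss"`` anchors them at
    the TSS for a literal reading of the category names.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if isinstance(peak, GenomicInterval):
        # a bare interval (e.g. a random control) is classified by midpoint
        chrom, pos = peak.chrom, (peak.start + peak.end) // 2
    else:
        chrom, pos = peak.interval.chrom, peak.summit

    inside: list[tuple[int, GeneModel]] = []
    if chrom in index.trees:
        for iv in index.trees[chrom].at(pos):
            g = index.genes[iv.data]
            inside.append((abs(_signed_tss_distance(g, pos)), g))
    if inside:
        inside.sort(key=lambda t: t[0])
        return _category_in_transcript(inside[0][1], pos)

    # outside every transcript: windows keyed on TSS (promoter) and on the
    # transcript end (downstream); nearest anchor wins
    candidates: list[tuple[int, FeatureCategory]] = []
    for g in index.genes:
        if g.chrom != chrom:
            continue
        d_tss = _signed_tss_distance(g, pos)
        if -PROXIMAL_BP <= d_tss < 0:
            candidates.append((abs(d_tss), FeatureCategory.PROXIMAL_PROMOTER))
        elif -DISTAL_BP <= d_tss < -PROXIMAL_BP:
            candidates.append((abs(d_tss), FeatureCategory.DISTAL_PROMOTER))
        if downstream_of == "tx_end":
            d_end = (pos - g.tes) if g.strand == "+" else (g.tes - pos)
        else:
            d_end = d_tss
        if 0 < d_end <= PROXIMAL_BP:
            candidates.append((abs(d_end), FeatureCategory.PROXIMAL_DOWNSTREAM))
        elif PROXIMAL_BP < d_end <= DISTAL_BP:
            candidates.append((abs(d_end), FeatureCategory.DISTAL_DOWNSTREAM))
    if candidates:
        candidates.sort(key=lambda t: t[0])
        return candidates[0][1]
    return FeatureCategory.DISTAL_INTERGENIC


def classify_locations(
    peaks: Sequence,
    genes: Sequence[GeneModel],
    downstream_of: str = "tx_end",
) -> list[FeatureCategory]:
    index = GeneIndex(genes)
    return [classify_location(p, index, downstream_of) for p in peaks]


def random_control(
    input_tags: Sequence[Tag],
    peaks: Sequence,
    n: int,
    seed: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Random genomic locations generated by sampling input-tag positions.

    Each control interval is centred on a uniformly sampled (without
    replacement) input-tag 5' position and inherits the width of a
    randomly paired real peak; intervals are clipped to chromosome
    bounds when lengths are given.
    """
    if n > len(input_tags):
        raise ValueError(f"n={n} exceeds {len(input_tags)} available input tags")
    if not peaks:
        raise ValueError("need at least one real peak to donate widths")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(input_tags), size=n, replace=False)
    widths = np.array(
        [p.interval.width if hasattr(p, "interval") else p.width for p in peaks]
    )
    paired = rng.choice(widths, size=n, replace=True)
    out: list[GenomicInterval] = []
    for i, w in zip(picks, paired):
        t = input_tags[i]
        w = int(w)
        start = t.pos - w // 2
        end = start + w
        if start < 0:
            start, end = 0, w
        if chrom_lengths is not None:
            length = chrom_lengths[t.chrom]
            if end > length:
                end = length
                start = max(0, end - w)
        out.append(GenomicInterval(t.chrom, start, end))
    return out


def enrichment_log2(
    peaks_dist: FeatureDistribution,
    control_dist: FeatureDistribution,
) -> dict[FeatureCategory, float]:
    """Per-category log2(peak% / control%).

    A category present in peaks but absent from the control maps to
    +inf; a category absent from both maps to NaN.
    """
    if set(peaks_dist.counts) != set(control_dist.counts):
        raise ValueError("category sets differ")
    ppct, cpct = peaks_dist.percentages, control_dist.percentages
    out: dict[FeatureCategory, float] = {}
    for cat in FeatureCategory:
        p, c = ppct[cat], cpct[cat]
        if p == 0 and c == 0:
            out[cat] = UNDEFINED
        elif c == 0:
            out[cat] = INF
        elif p == 0:
            out[cat] = -INF
        else:
            out[cat] = math.log2(p / c)
    return out


def repeat_overlap(
    peaks: Sequence,
    repeat_track: Sequence[GenomicInterval],
) -> tuple[int, int]:
    """(peaks overlapping >= 1 repeat interval by >= 1 bp, total peaks)."""
    trees: dict[str, IntervalTree] = {}
    for r in repeat_track:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    n = 0
    for p in peaks:
        iv = p.interval if hasattr(p, "interval") else p
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlap(iv.start, iv.end):
            n += 1
    return n, len(peaks)
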