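"""Two-factor co-occupancy statistics.

Given peaks for factor A and tag tracks for factors A and B, this module
builds the per-peak tag-count scatter (one point per A peak, regardless
of whether a B peak was called there; B-only locations never enter),
fits per-motif-class regressions, and computes promoter-fraction and
cross-dataset conservation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .formats import GeneModel, Tag
from .motifs import MotifClass
from .signal_map import count_tags_in_regions


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_a_with_b: int
    n_b_with_a: int


@dataclass(frozen=True)
class ScatterPoint:
    peak_name: str
    tags_a: int
    tags_b: int
    motif_class: MotifClass

    def __post_init__(self) -> None:
        if self.tags_a < 0 or self.tags_b < 0:
            raise ValueError("tag counts must be >= 0")


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float
    n: int


def _interval_of(p):
    return p.interval if hasattr(p, "interval") else p


def _trees(peaks: Sequence) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        iv = _interval_of(p)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _count_with_partner(peaks: Sequence, trees: Mapping[str, IntervalTree]) -> int:
    n = 0
    for p in peaks:
        iv = _interval_of(p)
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlap(iv.start, iv.end):
            n += 1
    return n


def overlap(peaks_a: Sequence, peaks_b: Sequence) -> OverlapResult:
    """Count peaks in each set with >= 1 bp overlap in the other set.

    Each peak is counted once no matter how many partners it overlaps.
    """
    trees_a, trees_b = _trees(peaks_a), _trees(peaks_b)
    return OverlapResult(
        n_a=len(peaks_a),
        n_b=len(peaks_b),
        n_a_with_b=_count_with_partner(peaks_a, trees_b),
        n_b_with_a=_count_with_partner(peaks_b, trees_a),
    )


def scatter_table(
    peaks_a: Sequence,
    tags_a: Sequence[Tag],
    tags_b: Sequence[Tag],
    classes: Mapping[str, MotifClass],
    frag_len: int = 150,
    per_million: bool = False,
) -> list[ScatterPoint]:
    """One scatter point per factor-A peak: A and B tag counts in the
    peak region plus the peak's motif class.

    Counts are raw fragment-overlap tag numbers; ``per_million`` rescales
    both to tags-per-million for unequal sequencing depths.
    """
    missing = [p.name for p in peaks_a if p.name not in classes]
    if missing:
        raise ValueError(f"peaks missing a motif class: {missing[:5]}")
    regions = [p.interval for p in peaks_a]
    counts_a = count_tags_in_regions(tags_a, regions, frag_len)
    counts_b = count_tags_in_regions(tags_b, regions, frag_len)
    if per_million:
        counts_a = np.rint(counts_a * 1e6 / max(len(tags_a), 1)).astype(int)
        counts_b = np.rint(counts_b * 1e6 / max(len(tags_b), 1)).astype(int)
    return [
        ScatterPoint(p.name, int(a), int(b), classes[p.name])
        for p, a, b in zip(peaks_a, counts_a, counts_b)
    ]


def class_regression(
    points: Sequence[ScatterPoint],
    motif_class: MotifClass | None = None,
) -> RegressionFit | None:
    """OLS of factor-A counts on factor-B counts for one motif class.

    Returns None (undefined fit) with fewer than 2 points or zero
    variance in the B counts.
    """
    sub = [
        pt for pt in points
        if motif_class is None or pt.motif_class == motif_class
    ]
    if len(sub) < 2:
        return None
    x = np.array([pt.tags_b for pt in sub], dtype=float)
    y = np.array([pt.tags_a for pt in sub], dtype=float)
    if np.ptp(x) == 0:
        return None
    fit = stats.linregress(x, y)
    return RegressionFit(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue), len(sub))


def promoter_fraction(
    peaks: Sequence,
    genes: Sequence[GeneModel],
    window: int = 3_000,
) -> float:
    """Fraction of peaks whose summit lies within ± window of any TSS.

    NaN for an empty peak list.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if not peaks:
        return float("nan")
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    sorted_tss = {c: np.sort(v) for c, v in tss_by_chrom.items()}
    n_in = 0
    for p in peaks:
        arr = sorted_tss.get(p.interval.chrom)
        if arr is None:
            continue
        i = np.searchsorted(arr, p.summit)
        for j in (i - 1, i):
            if 0 <= j < arr.size and abs(p.summit - int(arr[j])) <= window:
                n_in += 1
                break
    return n_in / len(peaks)


def conservation_fraction(
    peaks: Sequence,
    other_peak_sets: Sequence[Sequence],
    n_sample: int = 100,
    seed: int = 0,
    min_overlap_fraction: float = 0.0,
) -> tuple[int, int]:
    """Sample ``n_sample`` peaks and count those with overlapping peaks
    in EVERY provided set.

    Overlap means >= 1 bp by default; ``min_overlap_fraction`` demands
    that at least that fraction of the sampled peak be covered by a
    single partner for stricter readings of "precisely overlapping".
    """
    if not other_peak_sets:
        raise ValueError("need at least one other peak set")
    if n_sample > len(peaks):
        raise ValueError(f"n_sample={n_sample} exceeds {len(peaks)} peaks")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(peaks), size=n_sample, replace=False)
    all_trees = [_trees(s) for s in other_peak_sets]
    k = 0
    for i in picks:
        iv = _interval_of(peaks[i])
        ok = True
        for trees in all_trees:
            tree = trees.get(iv.chrom)
            hits = tree.overlap(iv.start, iv.end) if tree is not None else set()
            if min_overlap_fraction > 0:
                need = min_overlap_fraction * iv.width
                hits = {
                    h for h in hits
                    if min(h.end, iv.end) - max(h.begin, iv.start) >= need
                }
            if not hits:
                ok = False
                break
        if ok:
            k += 1
    return k, n_sample
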