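"""Binned genomic signal maps from aligned tags.

Each tag is extended in silico at its 3' end into a fixed-length fragment
(150 bp by default, the size-selected library's average) and assigned to
every fixed-width bin (32 nt by default) the fragment overlaps. The
resulting per-chromosome histograms are the "signal maps" consumed by the
peak caller; they double as coverage surrogates because bin sums track
per-base coverage exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import GenomicInterval, Tag, read_bedgraph, write_bedgraph

DEFAULT_FRAG_LEN = 150
DEFAULT_BIN_WIDTH = 32


def deduplicate(tags: Sequence[Tag]) -> list[Tag]:
    """Drop duplicate tags, keeping the first occurrence of each
    (chrom, pos, strand) triple in input order."""
    seen: set[Tag] = set()
    out: list[Tag] = []
    for t in tags:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


def downsample(tags: Sequence[Tag], n: int, seed: int) -> list[Tag]:
    """Uniform random subset of exactly ``n`` tags, without replacement.

    Matches the depth-matching step applied to over-sequenced input
    libraries before peak calling. Output preserves input order.
    """
    if n > len(tags):
        raise ValueError(f"cannot downsample {len(tags)} tags to {n}")
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(tags), size=n, replace=False)
    keep.sort()
    return [tags[i] for i in keep]


def fragment_interval(tag: Tag, frag_len: int, chrom_length: int | None = None) -> tuple[int, int]:
    """Half-open genomic extent of a tag's 3'-extended fragment.

    Plus-strand fragments run [pos, pos+frag_len); minus-strand fragments
    [pos-frag_len+1, pos+1). Clipped to [0, chrom_length) when a length is
    given.
    """
    if tag.strand == "+":
        start, end = tag.pos, tag.pos + frag_len
    else:
        start, end = tag.pos - frag_len + 1, tag.pos + 1
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


@dataclass
class SignalMap:
    """Per-chromosome fragment counts in fixed-width bins."""

    bin_width: int
    frag_len: int
    chrom_lengths: dict[str, int]
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    n_tags: int = 0

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            n_bins = -(-length // self.bin_width)
            if chrom not in self.counts:
                self.counts[chrom] = np.zeros(n_bins, dtype=np.int64)
            elif len(self.counts[chrom]) != n_bins:
                raise ValueError(
                    f"{chrom}: expected {n_bins} bins, got {len(self.counts[chrom])}"
                )

    @property
    def total_bin_count(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))

    @property
    def genome_bins(self) -> int:
        return int(sum(arr.size for arr in self.counts.values()))

    def add(self, other: "SignalMap") -> "SignalMap":
        if other.bin_width != self.bin_width or other.chrom_lengths != self.chrom_lengths:
            raise ValueError("maps not compatible")
        out = SignalMap(self.bin_width, self.frag_len, dict(self.chrom_lengths))
        for chrom in self.counts:
            out.counts[chrom] = self.counts[chrom] + other.counts[chrom]
        out.n_tags = self.n_tags + other.n_tags
        return out

    def to_bedgraph(self, path: str | Path) -> None:
        write_bedgraph(
            path,
            self.counts,
            self.bin_width,
            self.chrom_lengths,
            metadata={"frag_len": self.frag_len, "n_tags": self.n_tags},
        )

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "SignalMap":
        counts, bin_width, chrom_lengths, meta = read_bedgraph(path)
        sm = cls(
            bin_width,
            int(meta.get("frag_len", DEFAULT_FRAG_LEN)),
            chrom_lengths,
            counts,
        )
        sm.n_tags = int(meta.get("n_tags", 0))
        return sm


def build_signal_map(
    tags: Iterable[Tag],
    chrom_lengths: Mapping[str, int],
    frag_len: int = DEFAULT_FRAG_LEN,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> SignalMap:
    """Bin 3'-extended fragments into a :class:`SignalMap`.

    Every bin a fragment overlaps is incremented by 1; fragments are
    clipped at chromosome bounds. A tag whose 5' base lies outside its
    chromosome is an error.
    """
    sm = SignalMap(bin_width, frag_len, dict(chrom_lengths))
    # group per chromosome, then turn contiguous bin ranges into a
    # +1/-1 difference array and cumsum — O(tags + bins)
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    n = 0
    for t in tags:
        n += 1
        length = chrom_lengths.get(t.chrom)
        if length is None:
            raise ValueError(f"tag on unknown chromosome: {t}")
        if t.pos >= length:
            raise ValueError(f"tag beyond chromosome end: {t}")
        by_chrom[t.chrom].append(fragment_interval(t, frag_len, length))
    for chrom, frags in by_chrom.items():
        if not frags:
            continue
        arr = np.asarray(frags)
        first_bin = arr[:, 0] // bin_width
        last_bin = (arr[:, 1] - 1) // bin_width
        n_bins = sm.counts[chrom].size
        diff = np.zeros(n_bins + 1, dtype=np.int64)
        np.add.at(diff, first_bin, 1)
        np.add.at(diff, last_bin + 1, -1)
        sm.counts[chrom] += np.cumsum(diff[:-1])
    sm.n_tags = n
    return sm


def count_tags_in_region(
    tags: Sequence[Tag],
    region: GenomicInterval,
    frag_len: int = DEFAULT_FRAG_LEN,
    five_prime_only: bool = False,
) -> int:
    """Number of tags whose extended fragment overlaps ``region`` by >= 1 bp.

    With ``five_prime_only`` a tag counts only if its 5' base itself lies
    in the region (sensitivity-analysis mode).
    """
    return int(
        count_tags_in_regions(tags, [region], frag_len, five_prime_only)[0]
    )


def count_tags_in_regions(
    tags: Sequence[Tag],
    regions: Sequence[GenomicInterval],
    frag_len: int = DEFAULT_FRAG_LEN,
    five_prime_only: bool = False,
) -> np.ndarray:
    """Vectorised :func:`count_tags_in_region` over many regions."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in tags:
        if five_prime_only:
            iv = (t.pos, t.pos + 1)
        else:
            iv = fragment_interval(t, frag_len)
        by_chrom.setdefault(t.chrom, []).append(iv)
    for chrom, frags in by_chrom.items():
        arr = np.asarray(frags)
        starts[chrom] = np.sort(arr[:, 0])
        ends[chrom] = np.sort(arr[:, 1])
    out = np.zeros(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        if r.chrom not in starts:
            continue
        # fragment [s, e) overlaps [r.start, r.end) iff s < r.end and e > r.start
        n_start_ok = np.searchsorted(starts[r.chrom], r.end, side="left")
        n_end_bad = np.searchsorted(ends[r.chrom], r.start, side="right")
        out[i] = n_start_ok - n_end_bad
    return out
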