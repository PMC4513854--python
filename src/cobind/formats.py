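"""Readers/writers for the plain-text formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). The only
deviation worth remembering is the tag convention: a tag records the 5'
base of an aligned read, so a minus-strand BED record with interval
``[start, end)`` becomes a tag at ``end - 1``.

Formats handled here: FASTA (genome), BED6 (tags), BED3 (repeat track),
genePred/refFlat-style TSV (gene models) and bedGraph (signal maps).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq


class FormatError(ValueError):
    """A file does not conform to the expected plain-text format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class Tag:
    """One uniquely aligned read reduced to its 5' position and strand."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"tag position must be >= 0, got {self.pos}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"tag strand must be + or -, got {self.strand!r}")


@dataclass
class GeneModel:
    """One transcript model in the refFlat/genePred shape.

    ``cds_start``/``cds_end`` are None for non-coding transcripts. The TSS
    is strand-aware: tx_start for +, tx_end - 1 for -.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None
    cds_end: int | None
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"bad transcript bounds for {self.name}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"partial CDS bounds for {self.name}")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
                raise ValueError(f"CDS outside transcript for {self.name}")
        prev_end = None
        for ex in self.exons:
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(f"exon outside transcript for {self.name}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons unsorted or overlapping for {self.name}")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """Transcript end, strand-aware (last transcribed base)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_FASTA_ALPHABET = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: upper-case sequence}``.

    Names are taken up to the first whitespace; duplicate names, an empty
    file, content before the first header, or non-ACGTN characters raise
    :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: not a FASTA file (no leading '>')")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has non-ACGTN characters {sorted(bad)}"
            )
        out[rec.id] = seq
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_tags_bed(path: str | Path) -> list[Tag]:
    """Read aligned tags from BED6.

    Plus-strand tags sit at BED start; minus-strand tags at BED end - 1
    (the 5' base of the read).
    """
    tags: list[Tag] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            pos = start if strand == "+" else end - 1
            tags.append(Tag(chrom, pos, strand))
    return tags


def write_tags_bed(path: str | Path, tags: Iterable[Tag], read_len: int = 50) -> None:
    """Write tags as BED6, reconstructing read intervals of ``read_len``."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            if t.strand == "+":
                start, end = t.pos, t.pos + read_len
            else:
                start, end = max(0, t.pos - read_len + 1), t.pos + 1
            fh.write(f"{t.chrom}\t{start}\t{end}\tt{i}\t0\t{t.strand}\n")


def read_bed3(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3 track (e.g. repeat mask) into intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED3 needs 3 columns")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed3(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# gene table (refFlat / genePred style)
# ---------------------------------------------------------------------------

_GENE_COLUMNS = (
    "name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds"
)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read transcript models from a genePred-style TSV.

    Columns: name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds (comma-separated). cdsStart == cdsEnd
    marks a non-coding transcript. Records violating the model invariants
    are rejected with their line number.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"{path}:{lineno}: need 10 columns ({_GENE_COLUMNS})"
                )
            name, chrom, strand = fields[0], fields[1], fields[2]
            try:
                tx_start, tx_end = int(fields[3]), int(fields[4])
                cds_start, cds_end = int(fields[5]), int(fields[6])
                n_exons = int(fields[7])
                starts = [int(x) for x in fields[8].rstrip(",").split(",") if x]
                ends = [int(x) for x in fields[9].rstrip(",").split(",") if x]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if len(starts) != n_exons or len(ends) != n_exons:
                raise FormatError(f"{path}:{lineno}: exonCount mismatch")
            cds: tuple[int | None, int | None]
            cds = (None, None) if cds_start == cds_end else (cds_start, cds_end)
            try:
                exons = [
                    GenomicInterval(chrom, s, e, strand)
                    for s, e in zip(starts, ends)
                ]
                genes.append(
                    GeneModel(name, chrom, strand, tx_start, tx_end, cds[0], cds[1], exons)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cs = g.cds_start if g.cds_start is not None else g.tx_start
            ce = g.cds_end if g.cds_end is not None else g.tx_start
            starts = ",".join(str(e.start) for e in g.exons) + ","
            ends = ",".join(str(e.end) for e in g.exons) + ","
            fh.write(
                f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                f"\t{cs}\t{ce}\t{len(g.exons)}\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph (signal maps)
# ---------------------------------------------------------------------------

def write_bedgraph(
    path: str | Path,
    counts: Mapping[str, np.ndarray],
    bin_width: int,
    chrom_lengths: Mapping[str, int],
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write per-bin counts as bedGraph, one line per run of equal bins.

    Header comments carry bin width, chromosome lengths and any metadata so
    the reader reconstructs bin arrays exactly.
    """
    with open(path, "w") as fh:
        fh.write("track type=bedGraph\n")
        fh.write(f"#bin_width={bin_width}\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"#chrom_length\t{chrom}\t{length}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"#{key}={value}\n")
        for chrom, arr in counts.items():
            length = chrom_lengths[chrom]
            arr = np.asarray(arr)
            if arr.size == 0:
                continue
            # runs of equal counts
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for b0, b1 in zip(starts, ends):
                value = arr[b0]
                if value == 0:
                    continue
                fh.write(
                    f"{chrom}\t{b0 * bin_width}\t{min(b1 * bin_width, length)}\t{int(value)}\n"
                )


def read_bedgraph(
    path: str | Path,
) -> tuple[dict[str, np.ndarray], int, dict[str, int], dict[str, str]]:
    """Read a bedGraph written by :func:`write_bedgraph`.

    Returns (counts per chrom, bin_width, chrom lengths, metadata).
    """
    bin_width: int | None = None
    chrom_lengths: dict[str, int] = {}
    metadata: dict[str, str] = {}
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("track"):
                continue
            if line.startswith("#chrom_length"):
                _, chrom, length = line.split("\t")
                chrom_lengths[chrom] = int(length)
            elif line.startswith("#") and "=" in line:
                key, value = line[1:].split("=", 1)
                if key == "bin_width":
                    bin_width = int(value)
                else:
                    metadata[key] = value
            else:
                chrom, start, end, value = line.split("\t")
                rows.append((chrom, int(start), int(end), int(value)))
    if bin_width is None:
        raise FormatError(f"{path}: missing #bin_width header")
    counts = {
        chrom: np.zeros(-(-length // bin_width), dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    for chrom, start, end, value in rows:
        b0 = start // bin_width
        b1 = -(-end // bin_width)
        counts[chrom][b0:b1] = value
    return counts, bin_width, chrom_lengths, metadata


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def translate_dna(seq: str) -> str:
    """Translate a coding DNA string with the standard genetic code.

    One letter per codon, stop codons rendered as ``*``. The length must be
    a multiple of 3 and the alphabet strictly ACGT.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters {sorted(bad)}")
    return str(Seq(seq).translate())


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]
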