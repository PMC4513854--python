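"""Toy genome and ChIP/input tag simulator with a ground-truth table.

The generator emulates the statistical structure the co-occupancy
analysis assumes: a background genome of i.i.d. bases; gene models whose
proximal promoters carry a planted CCAAT-box (Motif 1) instance bound by
BOTH factors; isolated SOX-consensus (Motif 2) and dimeric inverted-
repeat (Motif 3) sites away from promoters, bound by factor A only; a
repeat track of random intervals; ChIP tags drawn as 150-bp fragments
jittered around site centres mixed with uniform background; and an input
library of pure background at more than twice the ChIP depth.

Every planted site lands in the returned truth table with exact
coordinates, class, bound factors and relative strength, so downstream
stages can be scored against ground truth. Identical seeds reproduce
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import (
    GenomicInterval,
    GeneModel,
    Tag,
    reverse_complement,
    write_bed3,
    write_fasta,
    write_gene_table,
    write_tags_bed,
)
from .motifs import (
    MOTIF1,
    MOTIF2,
    DimericMotif,
    consensus_instance,
)

FACTOR_A = "factorA"   # SOX9-like: binds all planted sites
FACTOR_B = "factorB"   # NF-Y-like: binds CCAAT (M1) sites only


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the toy dataset.

    Defaults follow the sequencing design the analysis assumes: 150-bp
    size-selected fragments, 50-nt reads, input depth more than twice the
    ChIP depth, and the promoter CCAAT box placed 106 bp upstream of the
    TSS. The toy scale (one 2-Mb chromosome, 60 genes, 40k ChIP tags,
    100k input tags) runs in seconds on one CPU.
    """

    genome_length: int = 2_000_000
    n_chroms: int = 1
    gc: float = 0.41
    n_genes: int = 60
    n_ccaat_promoters: int = 30
    n_sox_sites: int = 15
    n_dimeric_sites: int = 15
    frag_len: int = 150
    read_len: int = 50
    n_chip_tags: int = 40_000
    n_input_tags: int = 100_000
    enrichment: float = 0.5
    jitter_sd: float = 30.0
    site_offset_upstream: int = 106
    strength_sigma: float = 0.75   # lognormal sd of site strengths
    repeat_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_chroms", "n_genes", "n_ccaat_promoters",
                     "n_sox_sites", "n_dimeric_sites", "frag_len", "read_len",
                     "n_chip_tags", "n_input_tags"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.gc <= 1):
            raise ValueError("gc must be in [0, 1]")
        if not (0 <= self.enrichment <= 1):
            raise ValueError("enrichment must be in [0, 1]")
        if self.n_ccaat_promoters > self.n_genes:
            raise ValueError("n_ccaat_promoters cannot exceed n_genes")


@dataclass(frozen=True)
class TruthSite:
    """One planted motif instance and its generating role."""

    interval: GenomicInterval
    motif_class: str               # M1 | M2 | M3
    bound_by: frozenset[str]
    strength: float

    def __post_init__(self) -> None:
        if self.motif_class not in {"M1", "M2", "M3"}:
            raise ValueError(f"bad motif_class {self.motif_class!r}")
        if self.motif_class == "M1" and self.bound_by != {FACTOR_A, FACTOR_B}:
            raise ValueError("M1 sites must be bound by both factors")
        if self.motif_class in {"M2", "M3"} and self.bound_by != {FACTOR_A}:
            raise ValueError("M2/M3 sites must be bound by factor A only")

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    repeats: list[GenomicInterval]
    truth_sites: list[TruthSite]


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def generate_genome(config: SimulationConfig) -> SyntheticDataset:
    """Build the toy genome, gene models, repeat track and truth table.

    Genes are laid out non-overlapping on alternating strands; each of
    the first ``n_ccaat_promoters`` genes receives a Motif-1 instance
    whose interval ends ``site_offset_upstream`` bp upstream of its TSS.
    Motif-2 sites are exact consensus heptamers and Motif-3 sites are
    half-site + 4-bp spacer + inverted half, both planted in intergenic
    background away from promoters. Site strengths are lognormal.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    chroms = _chrom_names(cfg.n_chroms)
    per_chrom = cfg.genome_length // cfg.n_chroms
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {
        c: bases[rng.choice(4, size=per_chrom, p=p)] for c in chroms
    }

    # --- genes: equal-width non-overlapping slots, one gene per slot ---
    genes: list[GeneModel] = []
    n_total_sites = cfg.n_genes + cfg.n_sox_sites + cfg.n_dimeric_sites
    slot = per_chrom * cfg.n_chroms // max(n_total_sites, 1)
    if slot < 12_000:
        raise ValueError(
            "genome too small to place requested genes/sites without overlap"
        )
    # assign slots sequentially along chromosomes
    slot_list: list[tuple[str, int]] = []
    per_chrom_slots = n_total_sites // cfg.n_chroms + (n_total_sites % cfg.n_chroms > 0)
    i = 0
    for c in chroms:
        for k in range(per_chrom_slots):
            if i >= n_total_sites:
                break
            slot_list.append((c, k * (per_chrom // per_chrom_slots)))
            i += 1
    slot_width = per_chrom // max(per_chrom_slots, 1)
    order = rng.permutation(n_total_sites)
    gene_slots = [slot_list[j] for j in order[: cfg.n_genes]]
    sox_slots = [slot_list[j] for j in order[cfg.n_genes : cfg.n_genes + cfg.n_sox_sites]]
    dim_slots = [slot_list[j] for j in order[cfg.n_genes + cfg.n_sox_sites :]]

    truth: list[TruthSite] = []
    strengths = np.exp(rng.normal(0.0, cfg.strength_sigma, size=n_total_sites))

    for gi, (chrom, slot_start) in enumerate(gene_slots):
        strand = "+" if rng.random() < 0.5 else "-"
        tx_len = int(rng.integers(3_000, min(8_000, slot_width - 4_000)))
        margin = 3_500  # room for promoter windows inside the slot
        tx_start = slot_start + margin
        tx_end = tx_start + tx_len
        # 3 exons: first and last 300 bp, middle 200 bp
        e1 = GenomicInterval(chrom, tx_start, tx_start + 300, strand)
        mid = tx_start + tx_len // 2
        e2 = GenomicInterval(chrom, mid, mid + 200, strand)
        e3 = GenomicInterval(chrom, tx_end - 300, tx_end, strand)
        cds_start, cds_end = tx_start + 150, tx_end - 150
        gene = GeneModel(
            f"gene_{gi + 1:03d}", chrom, strand, tx_start, tx_end,
            cds_start, cds_end, [e1, e2, e3],
        )
        genes.append(gene)
        if gi < cfg.n_ccaat_promoters:
            inst = consensus_instance(MOTIF1, rng)
            w = len(inst)
            if strand == "+":
                # instance interval ends site_offset_upstream bp upstream of TSS
                end = gene.tss - cfg.site_offset_upstream
                start = end - w
                planted = inst
            else:
                start = gene.tss + cfg.site_offset_upstream + 1
                end = start + w
                planted = reverse_complement(inst)
            seqs[chrom][start:end] = np.frombuffer(planted.encode(), dtype=np.uint8)
            truth.append(
                TruthSite(
                    GenomicInterval(chrom, start, end, strand),
                    "M1",
                    frozenset({FACTOR_A, FACTOR_B}),
                    float(strengths[gi]),
                )
            )

    for k, (chrom, slot_start) in enumerate(sox_slots):
        inst = consensus_instance(MOTIF2, rng)
        start = slot_start + slot_width // 2
        end = start + len(inst)
        seqs[chrom][start:end] = np.frombuffer(inst.encode(), dtype=np.uint8)
        truth.append(
            TruthSite(
                GenomicInterval(chrom, start, end, "+"),
                "M2",
                frozenset({FACTOR_A}),
                float(strengths[cfg.n_genes + k]),
            )
        )

    dimer = DimericMotif()
    for k, (chrom, slot_start) in enumerate(dim_slots):
        inst = dimer.instance(rng, spacer=4)
        start = slot_start + slot_width // 2
        end = start + len(inst)
        seqs[chrom][start:end] = np.frombuffer(inst.encode(), dtype=np.uint8)
        truth.append(
            TruthSite(
                GenomicInterval(chrom, start, end, "+"),
                "M3",
                frozenset({FACTOR_A}),
                float(strengths[cfg.n_genes + cfg.n_sox_sites + k]),
            )
        )

    # --- repeat track: random intervals covering ~repeat_fraction ---
    repeats: list[GenomicInterval] = []
    if cfg.repeat_fraction > 0:
        target = cfg.repeat_fraction * per_chrom
        for chrom in chroms:
            covered = 0.0
            spans: list[tuple[int, int]] = []
            while covered < target:
                length = int(rng.integers(200, 2_000))
                start = int(rng.integers(0, per_chrom - length))
                spans.append((start, start + length))
                covered += length
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            repeats += [GenomicInterval(chrom, s, e) for s, e in merged]

    genome = {c: seqs[c].tobytes().decode() for c in chroms}
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    truth.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return SyntheticDataset(cfg, genome, genes, repeats, truth)


def simulate_tags(
    dataset: SyntheticDataset,
    factor: str,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> list[Tag]:
    """Draw tags for one track: ``factorA``, ``factorB`` or ``input``.

    ChIP tracks mix site-derived fragments (a fraction ``enrichment`` of
    the tags, choosing a bound site proportionally to strength, centre
    jittered with normal noise) with uniform background; the input track
    is pure background at its own depth. The tag is the fragment's 5'
    end on a uniformly chosen strand.
    """
    cfg = config or dataset.config
    if seed is None:
        seed = cfg.seed + {"factorA": 1, "factorB": 2, "input": 3}.get(factor, 9)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chroms = list(dataset.genome)
    lengths = {c: len(s) for c, s in dataset.genome.items()}

    if factor == "input":
        n_site, n_bg = 0, cfg.n_input_tags
        sites: list[TruthSite] = []
    elif factor in (FACTOR_A, FACTOR_B):
        sites = [s for s in dataset.truth_sites if factor in s.bound_by]
        if not sites:
            raise ValueError(f"no sites bound by {factor}")
        n_site = int(round(cfg.enrichment * cfg.n_chip_tags))
        n_bg = cfg.n_chip_tags - n_site
    else:
        raise ValueError(f"unknown factor {factor!r}")

    tags: list[Tag] = []
    if n_site:
        weights = np.array([s.strength for s in sites])
        weights = weights / weights.sum()
        choice = rng.choice(len(sites), size=n_site, p=weights)
        jitter = rng.normal(0.0, cfg.jitter_sd, size=n_site)
        strands = rng.random(n_site) < 0.5
        half = cfg.frag_len // 2
        for idx, dz, plus in zip(choice, jitter, strands):
            site = sites[idx]
            length = lengths[site.interval.chrom]
            center = int(round(site.center + dz))
            center = min(max(center, half), length - (cfg.frag_len - half) - 1)
            left = center - half
            right = left + cfg.frag_len
            if plus:
                tags.append(Tag(site.interval.chrom, left, "+"))
            else:
                tags.append(Tag(site.interval.chrom, right - 1, "-"))
    if n_bg:
        total = sum(lengths.values())
        probs = np.array([lengths[c] / total for c in chroms])
        chrom_idx = rng.choice(len(chroms), size=n_bg, p=probs)
        strands = rng.random(n_bg) < 0.5
        for ci, plus in zip(chrom_idx, strands):
            chrom = chroms[ci]
            pos = int(rng.integers(0, lengths[chrom]))
            tags.append(Tag(chrom, pos, "+" if plus else "-"))
    return tags


# ---------------------------------------------------------------------------
# truth table and dataset io
# ---------------------------------------------------------------------------

def write_truth_table(path: str | Path, sites: Sequence[TruthSite]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tmotif_class\tbound_by\tstrength\n")
        for s in sites:
            bound = ",".join(sorted(s.bound_by))
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                f"\t{s.interval.strand}\t{s.motif_class}\t{bound}\t{s.strength:.6f}\n"
            )


def read_truth_table(path: str | Path) -> list[TruthSite]:
    sites: list[TruthSite] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, start, end, strand, cls, bound, strength = line.rstrip("\n").split("\t")
            sites.append(
                TruthSite(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    cls,
                    frozenset(bound.split(",")),
                    float(strength),
                )
            )
    return sites


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write FASTA, gene table, repeat BED, tag BEDs, truth table and a
    JSON run manifest. Returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    paths = {
        "genome": str(outdir / "genome.fa"),
        "genes": str(outdir / "genes.txt"),
        "repeats": str(outdir / "repeats.bed"),
        "truth": str(outdir / "truth_sites.tsv"),
        "tags_factorA": str(outdir / "tags_factorA.bed"),
        "tags_factorB": str(outdir / "tags_factorB.bed"),
        "tags_input": str(outdir / "tags_input.bed"),
    }
    write_fasta(paths["genome"], dataset.genome)
    write_gene_table(paths["genes"], dataset.genes)
    write_bed3(paths["repeats"], dataset.repeats)
    write_truth_table(paths["truth"], dataset.truth_sites)
    for factor in (FACTOR_A, FACTOR_B, "input"):
        tags = simulate_tags(dataset, factor)
        write_tags_bed(paths[f"tags_{factor}"], tags, read_len=cfg.read_len)
    manifest = {"config": asdict(cfg), "paths": paths}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
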