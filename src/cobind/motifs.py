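"""Motif models and scanners for CCAAT-box and SOX9-consensus sites.

Three motif models drive the peak classification:

* Motif 1 — the NF-Y CCAAT box with its preferred flanks, IUPAC
  ``AGCCAATSR`` (core ``CCAAT``; ``ATTGG`` on the opposite strand).
* Motif 2 — the classical SOX9 HMG-box consensus heptamer, IUPAC
  ``WWCAAWG``.
* Motif 3 — a dimeric SOX9 site: the heptamer and its inverted repeat
  separated by a short spacer (canonically 4 bp; 2-14 bp in the
  exploratory mode).

Scanning comes in two flavours: exact IUPAC consensus matching, and
log-odds PWM scanning with exact p-values computed by dynamic programming
over the discretised score distribution (the p-value semantics FIMO
defines). Sequence windows containing N never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import GenomicInterval, reverse_complement

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# score discretisation granularity for the PWM p-value DP, in bits
SCORE_GRANULARITY = 1e-3


def _encode(seq: str) -> np.ndarray:
    """Map ACGTN (upper-case) to 0..4; anything else is an error."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(128, 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    enc = lut[arr]
    if (enc == 255).any():
        bad = sorted(set(chr(b) for b in arr[enc == 255]))
        raise ValueError(f"sequence has non-ACGTN characters {bad}")
    return enc


# ---------------------------------------------------------------------------
# consensus motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusMotif:
    """IUPAC consensus pattern matched exactly (N in the sequence never
    matches any code)."""

    iupac: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty consensus")
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC codes {sorted(bad)}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    @property
    def width(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "ConsensusMotif":
        rc = self.iupac.translate(_IUPAC_COMPLEMENT)[::-1]
        return ConsensusMotif(rc, name=self.name + "_rc" if self.name else "")

    def masks(self) -> np.ndarray:
        """(width, 5) boolean allow-matrix over A,C,G,T,N."""
        m = np.zeros((self.width, 5), dtype=bool)
        for j, code in enumerate(self.iupac):
            for base in IUPAC_CODES[code]:
                m[j, _BASE_INDEX[base]] = True
        return m


# the models used throughout the analysis
MOTIF1 = ConsensusMotif("AGCCAATSR", name="motif1")
MOTIF1_CORE = ConsensusMotif("CCAAT", name="ccaat_core")
MOTIF2 = ConsensusMotif("WWCAAWG", name="motif2")


@dataclass(frozen=True)
class MotifHit:
    """One match: half-open interval within the scanned sequence, strand,
    score (log2 odds for PWM hits, 1.0 for exact consensus matches),
    spacer (dimeric hits only) and the matched sequence as written in the
    forward genome."""

    interval: GenomicInterval
    strand: str
    score: float
    matched: str
    spacer: int | None = None


def _match_positions(enc: np.ndarray, motif: ConsensusMotif) -> np.ndarray:
    w = motif.width
    if enc.size < w:
        return np.empty(0, dtype=np.int64)
    masks = motif.masks()
    n_pos = enc.size - w + 1
    ok = np.ones(n_pos, dtype=bool)
    for j in range(w):
        ok &= masks[j][enc[j : j + n_pos]]
    return np.flatnonzero(ok)


def scan_consensus(
    seq: str,
    motif: ConsensusMotif,
    both_strands: bool = True,
    chrom: str = "seq",
) -> list[MotifHit]:
    """All exact IUPAC matches of ``motif`` in ``seq``.

    A minus-strand hit at ``[i, i+w)`` means the reverse complement of
    that window matches the pattern. Hits are sorted by position, plus
    strand first on ties.
    """
    seq = seq.upper()
    enc = _encode(seq)
    hits: list[tuple[int, str]] = [(int(i), "+") for i in _match_positions(enc, motif)]
    if both_strands:
        rc = motif.reverse_complement()
        hits += [(int(i), "-") for i in _match_positions(enc, rc)]
    hits.sort(key=lambda h: (h[0], h[1]))
    w = motif.width
    return [
        MotifHit(GenomicInterval(chrom, i, i + w), s, 1.0, seq[i : i + w])
        for i, s in hits
    ]


# ---------------------------------------------------------------------------
# position weight matrices
# ---------------------------------------------------------------------------

@dataclass
class PositionWeightMatrix:
    """Column-stochastic base probabilities plus a background model."""

    probs: np.ndarray                     # (width, 4) over A,C,G,T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = ""
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 4) log2(p / background); zero probabilities map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.probs[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            name=self.name + "_rc" if self.name else "",
        )

    def score(self, word: str) -> float:
        """Log2-odds score of one width-length word."""
        lo = self.log_odds()
        enc = _encode(word)
        if enc.size != self.width or (enc == 4).any():
            raise ValueError("word must be ACGT of PWM width")
        return float(lo[np.arange(self.width), enc].sum())


def build_pwm_from_consensus(
    motif: ConsensusMotif,
    certainty: float = 0.9,
    background: Sequence[float] | None = None,
) -> PositionWeightMatrix:
    """Turn an IUPAC consensus into a PWM.

    At each position the bases allowed by the code share ``certainty``
    equally; disallowed bases share the remaining mass. Columns allowing
    all four bases are uniform.
    """
    if not (0.25 <= certainty <= 1.0):
        raise ValueError("certainty must be in [0.25, 1]")
    masks = motif.masks()[:, :4]
    probs = np.zeros((motif.width, 4))
    for j in range(motif.width):
        k = int(masks[j].sum())
        if k == 4:
            probs[j] = 0.25
        else:
            probs[j, masks[j]] = certainty / k
            probs[j, ~masks[j]] = (1.0 - certainty) / (4 - k)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PositionWeightMatrix(probs, bg, name=motif.name)


def _integer_scores(pwm: PositionWeightMatrix,
                    granularity: float) -> np.ndarray:
    """(width, 4) per-position scores as integer multiples of granularity.

    -inf (zero probability) is mapped to a sentinel far below any
    achievable total so such words can never reach a finite threshold.
    """
    lo = pwm.log_odds()
    finite = lo[np.isfinite(lo)]
    floor = (finite.min() if finite.size else 0.0) - 100.0
    lo = np.where(np.isfinite(lo), lo, floor * pwm.width)
    return np.rint(lo / granularity).astype(np.int64)


def score_distribution(
    pwm: PositionWeightMatrix,
    granularity: float = SCORE_GRANULARITY,
) -> tuple[int, np.ndarray]:
    """Exact null distribution of the discretised word score.

    Returns ``(offset, probs)`` where ``probs[k]`` is the probability that
    a background-distributed random word scores ``(offset + k) *
    granularity``. Computed by dynamic programming: one convolution per
    PWM column over the 4 bases.
    """
    si = _integer_scores(pwm, granularity)
    bg = pwm.background
    offset = 0
    dist = np.ones(1)
    for j in range(pwm.width):
        col = si[j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(dist.size + (hi - lo), dtype=float)
        for b in range(4):
            if bg[b] > 0:
                shift = int(col[b]) - lo
                new[shift : shift + dist.size] += dist * bg[b]
        dist = new
        offset += lo
    return offset, dist


def pwm_pvalue(
    pwm: PositionWeightMatrix,
    score_threshold: float,
    granularity: float = SCORE_GRANULARITY,
) -> float:
    """P(random background word scores >= threshold), exact for the
    discretised scores."""
    offset, dist = score_distribution(pwm, granularity)
    t = int(np.rint(score_threshold / granularity))
    k0 = max(t - offset, 0)
    if k0 >= dist.size:
        return 0.0
    return float(dist[k0:].sum())


def score_threshold_for_pvalue(
    pwm: PositionWeightMatrix,
    p_threshold: float,
    granularity: float = SCORE_GRANULARITY,
) -> int:
    """Smallest integer score t (in granularity units) with
    P(score >= t) <= p_threshold."""
    offset, dist = score_distribution(pwm, granularity)
    sf = np.cumsum(dist[::-1])[::-1]
    idx = np.flatnonzero(sf <= p_threshold)
    if idx.size == 0:
        return offset + dist.size  # unattainable
    return offset + int(idx[0])


def scan_pwm(
    seq: str,
    pwm: PositionWeightMatrix,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
    chrom: str = "seq",
    granularity: float = SCORE_GRANULARITY,
) -> list[MotifHit]:
    """Log-odds PWM scan reporting every window whose score p-value is at
    most ``p_threshold`` (1e-4 by default, the FIMO default). Windows
    containing N are skipped."""
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    seq = seq.upper()
    enc = _encode(seq)
    w = pwm.width
    if enc.size < w:
        return []
    n_pos = enc.size - w + 1
    has_n = np.zeros(n_pos, dtype=bool)
    is_n = enc == 4
    for j in range(w):
        has_n |= is_n[j : j + n_pos]
    safe = np.where(is_n, 0, enc)

    hits: list[tuple[int, str, float]] = []
    matrices = [("+", pwm)]
    if both_strands:
        matrices.append(("-", pwm.reverse_complement()))
    for strand, mat in matrices:
        si = _integer_scores(mat, granularity)
        t = score_threshold_for_pvalue(mat, p_threshold, granularity)
        total = np.zeros(n_pos, dtype=np.int64)
        for j in range(w):
            total += si[j][safe[j : j + n_pos]]
        ok = (total >= t) & ~has_n
        for i in np.flatnonzero(ok):
            hits.append((int(i), strand, float(total[i]) * granularity))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [
        MotifHit(GenomicInterval(chrom, i, i + w), s, score, seq[i : i + w])
        for i, s, score in hits
    ]


# ---------------------------------------------------------------------------
# dimeric (inverted repeat) motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimericMotif:
    """Half-site consensus plus its inverted repeat across a spacer."""

    half: ConsensusMotif = MOTIF2
    spacer_min: int = 4
    spacer_max: int = 4
    name: str = "motif3"

    def __post_init__(self) -> None:
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("require 0 <= spacer_min <= spacer_max")

    def instance(self, rng: np.random.Generator, spacer: int = 4) -> str:
        """One concrete site: a random realisation of the half-site, a
        random spacer, and the half's reverse complement."""
        half = consensus_instance(self.half, rng)
        spacer_seq = "".join(rng.choice(list("ACGT"), size=spacer))
        return half + spacer_seq + reverse_complement(half)


def consensus_instance(motif: ConsensusMotif, rng: np.random.Generator) -> str:
    """One random concrete realisation of an IUPAC consensus."""
    return "".join(rng.choice(list(IUPAC_CODES[c])) for c in motif.iupac)


def scan_dimeric(
    seq: str,
    motif: DimericMotif,
    chrom: str = "seq",
) -> list[MotifHit]:
    """Find half-site / spacer / inverted-half arrangements.

    A plus-strand hit has the half-site forward at position i and its
    reverse complement at ``i + half_width + s``; a minus-strand hit is
    the mirrored arrangement. Every spacer s in the configured range is
    tried and recorded; overlapping hits are all reported.
    """
    seq = seq.upper()
    enc = _encode(seq)
    w = motif.half.width
    fwd = set(int(i) for i in _match_positions(enc, motif.half))
    rev = set(int(i) for i in _match_positions(enc, motif.half.reverse_complement()))
    hits: list[MotifHit] = []
    for i, partner_set, strand in (
        [(i, rev, "+") for i in sorted(fwd)] + [(i, fwd, "-") for i in sorted(rev)]
    ):
        for s in range(motif.spacer_min, motif.spacer_max + 1):
            j = i + w + s
            if j in partner_set:
                end = j + w
                hits.append(
                    MotifHit(
                        GenomicInterval(chrom, i, end),
                        strand,
                        1.0,
                        seq[i:end],
                        spacer=s,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.strand, h.spacer))
    return hits


# ---------------------------------------------------------------------------
# summit windows and peak classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummitWindow:
    peak_name: str
    interval: GenomicInterval
    sequence: str
    clipped: bool


def extract_summit_windows(
    peaks: Sequence,
    genome: Mapping[str, str],
    half_width: int = 25,
    top_n: int | None = None,
) -> list[SummitWindow]:
    """Sequences around peak summits: ``[summit - h, summit + h)``.

    With ``top_n``, peaks are first ranked by tag count (descending; ties
    by p-value then coordinate) and the strongest ``top_n`` taken —
    mirrors selecting the strongest peaks for motif discovery. Windows
    are clipped at chromosome edges and flagged when clipped.
    """
    ranked = list(peaks)
    if top_n is not None:
        ranked.sort(
            key=lambda p: (-p.tag_count, p.p_value, p.interval.chrom, p.interval.start)
        )
        ranked = ranked[:top_n]
    out: list[SummitWindow] = []
    for p in ranked:
        chrom = p.interval.chrom
        length = len(genome[chrom])
        start = max(0, p.summit - half_width)
        end = min(length, p.summit + half_width)
        clipped = (start != p.summit - half_width) or (end != p.summit + half_width)
        out.append(
            SummitWindow(p.name, GenomicInterval(chrom, start, end),
                         genome[chrom][start:end], clipped)
        )
    return out


class MotifClass(str, Enum):
    M1_ONLY = "M1_ONLY"
    M1_AND_SOX = "M1_AND_SOX"
    SOX_ONLY = "SOX_ONLY"
    NONE = "NONE"


def classify_peaks(
    peaks: Sequence,
    genome: Mapping[str, str],
    motif1: ConsensusMotif = MOTIF1,
    motif2: ConsensusMotif = MOTIF2,
    motif3: DimericMotif | None = None,
    summit_window: int | None = None,
) -> dict[str, MotifClass]:
    """Four-way motif classification of peaks.

    Each peak's full interval sequence (or a ±``summit_window`` bp window
    when given) is scanned for the CCAAT-box motif (M1) and the SOX
    consensus motifs (M2 monomeric, M3 dimeric): M1 alone → M1_ONLY, M1
    plus either SOX motif → M1_AND_SOX, SOX motifs alone → SOX_ONLY,
    neither → NONE.
    """
    m3 = motif3 or DimericMotif()
    out: dict[str, MotifClass] = {}
    for p in peaks:
        chrom = p.interval.chrom
        if summit_window is not None:
            start = max(0, p.summit - summit_window)
            end = min(len(genome[chrom]), p.summit + summit_window)
        else:
            start, end = p.interval.start, p.interval.end
        seq = genome[chrom][start:end]
        has_m1 = bool(scan_consensus(seq, motif1))
        has_sox = bool(scan_consensus(seq, motif2)) or bool(scan_dimeric(seq, m3))
        if has_m1 and has_sox:
            cls = MotifClass.M1_AND_SOX
        elif has_m1:
            cls = MotifClass.M1_ONLY
        elif has_sox:
            cls = MotifClass.SOX_ONLY
        else:
            cls = MotifClass.NONE
        out[p.name] = cls
    return out


# ---------------------------------------------------------------------------
# MEME minimal format io
# ---------------------------------------------------------------------------

def write_meme(path: str | Path, pwms: Sequence[PositionWeightMatrix]) -> None:
    """Write PWMs in MEME minimal motif format (version 4)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name or 'motif'}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + "  ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PositionWeightMatrix]:
    """Read PWMs from MEME minimal motif format."""
    pwms: list[PositionWeightMatrix] = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else ""
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for k in range(w):
                rows.append([float(x) for x in lines[i + 1 + k].split()])
            pwms.append(
                PositionWeightMatrix(np.array(rows), background.copy(), name=name)
            )
            i += 1 + w
            continue
        i += 1
    return pwms
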