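import itertools
import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cobind.formats import GenomicInterval, reverse_complement
from cobind.motifs import (
    IUPAC_CODES,
    MOTIF1,
    MOTIF1_CORE,
    MOTIF2,
    ConsensusMotif,
    DimericMotif,
    MotifClass,
    PositionWeightMatrix,
    build_pwm_from_consensus,
    classify_peaks,
    consensus_instance,
    extract_summit_windows,
    pwm_pvalue,
    read_meme,
    scan_consensus,
    scan_dimeric,
    scan_pwm,
    write_meme,
    SCORE_GRANULARITY,
)
from cobind.peak_calling import Peak

WT_OLIGO = "TCCCGCCTCCCTAACCTGATTGGTTTATTCAAACAAACC"
MUT_OLIGO = "TCCCGCCTCCCTAACCTGTTTGGTTTATTCAAACAAACC"

dna = st.text(alphabet="ACGTN", min_size=0, max_size=200)


def regex_oracle(seq, motif):
    """Naive regex-based consensus scan: overlapping matches, both strands."""
    def pat(iupac):
        return "".join("[" + IUPAC_CODES[c] + "]" for c in iupac)

    hits = []
    for m in re.finditer(f"(?=({pat(motif.iupac)}))", seq):
        hits.append((m.start(), "+"))
    rc = motif.reverse_complement()
    for m in re.finditer(f"(?=({pat(rc.iupac)}))", seq):
        hits.append((m.start(), "-"))
    return sorted(hits)


class TestScanConsensus:
    def test_direct_instance_of_sox_consensus(self):
        (hit,) = scan_consensus("AACAATG", MOTIF2)
        assert (hit.interval.start, hit.strand) == (0, "+")

    def test_ccaat_core_in_wild_type_promoter_oligo(self):
        """The CCAAT box sits on the minus strand (ATTGG) at 18-22."""
        (hit,) = scan_consensus(WT_OLIGO, MOTIF1_CORE)
        assert (hit.interval.start, hit.interval.end, hit.strand) == (18, 23, "-")
        assert hit.matched == "ATTGG"

    def test_single_point_mutation_abolishes_the_site(self):
        assert scan_consensus(MUT_OLIGO, MOTIF1_CORE) == []

    def test_n_in_sequence_never_matches(self):
        assert scan_consensus("CCNAT" * 4, MOTIF1_CORE) == []

    def test_invalid_iupac_code_rejected(self):
        with pytest.raises(ValueError):
            ConsensusMotif("CCAXT")

    def test_hits_sorted_position_then_plus_first(self):
        hits = scan_consensus("AATTAATT", ConsensusMotif("AATT"))
        keys = [(h.interval.start, h.strand) for h in hits]
        assert keys == sorted(keys)

    @given(dna)
    def test_equals_regex_oracle(self, seq):
        for motif in (MOTIF1_CORE, MOTIF2):
            got = [(h.interval.start, h.strand) for h in scan_consensus(seq, motif)]
            assert got == regex_oracle(seq, motif)

    @given(dna)
    def test_reverse_complement_symmetry(self, seq):
        fwd = scan_consensus(seq, MOTIF2)
        rev = scan_consensus(reverse_complement(seq), MOTIF2)
        mirrored = sorted(
            (len(seq) - h.interval.end, {"+": "-", "-": "+"}[h.strand]) for h in rev
        )
        assert mirrored == sorted((h.interval.start, h.strand) for h in fwd)


class TestBuildPwm:
    def test_certain_single_base(self):
        pwm = build_pwm_from_consensus(ConsensusMotif("A"), certainty=1.0)
        assert np.allclose(pwm.probs[0], [1, 0, 0, 0])

    def test_degenerate_w_column(self):
        pwm = build_pwm_from_consensus(ConsensusMotif("W"), certainty=0.9)
        assert np.allclose(pwm.probs[0], [0.45, 0.05, 0.05, 0.45])

    def test_n_column_uniform(self):
        pwm = build_pwm_from_consensus(ConsensusMotif("N"), certainty=0.7)
        assert np.allclose(pwm.probs[0], [0.25] * 4)

    def test_columns_stochastic(self):
        pwm = build_pwm_from_consensus(MOTIF1, certainty=0.85)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)


def brute_force_pvalue(pwm, threshold, granularity=SCORE_GRANULARITY):
    """Oracle: enumerate all 4^w words over the background distribution,
    discretising per-position scores the same way the DP does."""
    lo = np.log2(pwm.probs) - np.log2(pwm.background)
    si = np.rint(lo / granularity)
    t = int(np.rint(threshold / granularity))
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.width):
        score = sum(si[j, b] for j, b in enumerate(word))
        if score >= t:
            total += np.prod([pwm.background[b] for b in word])
    return total


class TestPwmPvalue:
    def test_width_one_closed_form(self):
        pwm = PositionWeightMatrix(np.array([[1.0, 0, 0, 0]]))
        assert pwm_pvalue(pwm, 2.0) == pytest.approx(0.25)

    def test_uniform_pwm_threshold_zero(self):
        pwm = PositionWeightMatrix(np.full((3, 4), 0.25))
        assert pwm_pvalue(pwm, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("iupac", ["CCAAT", "WWCAAW", "ASGT"])
    def test_matches_brute_force_enumeration(self, iupac):
        pwm = build_pwm_from_consensus(ConsensusMotif(iupac), certainty=0.9)
        exact_word_score = pwm.score("".join(IUPAC_CODES[c][0] for c in iupac))
        for thr in (exact_word_score, exact_word_score / 2, 0.0):
            assert pwm_pvalue(pwm, thr) == pytest.approx(
                brute_force_pvalue(pwm, thr), abs=1e-6
            )


class TestScanPwm:
    @pytest.fixture
    def pwm(self):
        return build_pwm_from_consensus(MOTIF2, certainty=0.9)

    def test_planted_consensus_found_in_background(self, rng):
        # the 9-bp CCAAT-box motif: its exact match is rare enough in the
        # null to clear the default 1e-4 p-value threshold (a 7-bp
        # degenerate heptamer is not, and correctly yields no hits there)
        pwm9 = build_pwm_from_consensus(MOTIF1, certainty=0.9)
        bg = "".join(rng.choice(list("ACGT"), size=500))
        seq = bg[:200] + "AGCCAATCA" + bg[200:]
        hits = scan_pwm(seq, pwm9)
        assert any(h.interval.start == 200 and h.strand == "+" for h in hits)

    def test_threshold_one_hits_every_clean_position(self, pwm):
        seq = "ACGTACGTACGTACG"
        hits = scan_pwm(seq, pwm, p_threshold=1.0)
        n_pos = len(seq) - pwm.width + 1
        assert len(hits) == 2 * n_pos

    def test_windows_with_n_skipped(self, pwm):
        hits = scan_pwm("AACANTGAACAATG", pwm, p_threshold=1.0)
        assert all("N" not in h.matched for h in hits)

    def test_background_hit_rate_is_poissonian(self, rng):
        """On i.i.d. background the hit count should match 2 * p * positions
        within 4 sigma."""
        pwm = build_pwm_from_consensus(MOTIF1, certainty=0.9)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        p = 1e-3
        hits = scan_pwm(seq, pwm, p_threshold=p)
        # the discrete threshold acts at its own attained p-value, which is
        # the proper expectation for the count
        from cobind.motifs import score_threshold_for_pvalue, score_distribution

        t = score_threshold_for_pvalue(pwm, p)
        offset, dist = score_distribution(pwm)
        attained = dist[t - offset:].sum()
        expect = 2 * attained * (len(seq) - pwm.width + 1)
        assert abs(len(hits) - expect) < 4 * np.sqrt(expect)


class TestScanDimeric:
    def test_inverted_repeat_with_canonical_spacer(self):
        site = "AACAATG" + "GGGG" + "CATTGTT"
        hits = scan_dimeric(site, DimericMotif(spacer_min=2, spacer_max=14))
        assert any(h.spacer == 4 and h.interval.start == 0 for h in hits)

    def test_spacer_outside_range_not_found(self):
        site = "AACAATG" + "G" * 15 + "CATTGTT"
        assert scan_dimeric(site, DimericMotif(spacer_min=2, spacer_max=14)) == []

    def test_half_site_alone_no_hit(self):
        assert scan_dimeric("AACAATG", DimericMotif(spacer_min=2, spacer_max=14)) == []

    def test_instance_constructor_roundtrip(self, rng):
        m = DimericMotif()
        for _ in range(20):
            site = m.instance(rng, spacer=4)
            assert any(h.spacer == 4 for h in scan_dimeric(site, m))


def _peak(chrom, start, end, name):
    return Peak(GenomicInterval(chrom, start, end), summit=(start + end) // 2,
                tag_count=10, fold_enrichment=5.0, p_value=1e-9, name=name)


class TestSummitWindows:
    def test_default_50bp_window(self):
        genome = {"chr1": "A" * 2000}
        (w,) = extract_summit_windows([_peak("chr1", 900, 1100, "p1")], genome)
        assert (w.interval.start, w.interval.end) == (975, 1025)
        assert len(w.sequence) == 50 and not w.clipped

    def test_clipped_at_chromosome_edge(self):
        genome = {"chr1": "A" * 2000}
        p = Peak(GenomicInterval("chr1", 0, 64), summit=10, tag_count=5,
                 fold_enrichment=5.0, p_value=1e-9, name="p")
        (w,) = extract_summit_windows([p], genome)
        assert (w.interval.start, w.interval.end) == (0, 35)
        assert w.clipped and len(w.sequence) == 35

    def test_top_n_selects_highest_tag_counts(self):
        genome = {"chr1": "A" * 5000}
        peaks = [_peak("chr1", i * 500, i * 500 + 200, f"p{i}") for i in range(5)]
        for i, p in enumerate(peaks):
            p.tag_count = i * 10
        top = extract_summit_windows(peaks, genome, top_n=3)
        assert [w.peak_name for w in top] == ["p4", "p3", "p2"]


class TestClassifyPeaks:
    def _genome_with(self, insert):
        rng = np.random.default_rng(0)
        bg = "".join(rng.choice(list("AC"), size=400))  # AC background: no motifs
        return {"chr1": bg[:200] + insert + bg[200:]}

    def test_ccaat_only_peak(self):
        genome = self._genome_with("AGCCAATGG")
        cls = classify_peaks([_peak("chr1", 150, 300, "p")], genome)
        assert cls["p"] == MotifClass.M1_ONLY

    def test_ccaat_plus_sox_consensus(self):
        genome = self._genome_with("AGCCAATGG" + "TTTT" + "AACAATG")
        cls = classify_peaks([_peak("chr1", 150, 300, "p")], genome)
        assert cls["p"] == MotifClass.M1_AND_SOX

    def test_sox_only_and_none(self):
        genome = self._genome_with("AACAATG")
        peaks = [_peak("chr1", 150, 300, "sox"), _peak("chr1", 300, 400, "bg")]
        cls = classify_peaks(peaks, genome)
        assert cls["sox"] == MotifClass.SOX_ONLY
        assert cls["bg"] == MotifClass.NONE

    def test_dimeric_site_counts_as_sox(self, rng):
        site = DimericMotif().instance(rng, spacer=4)
        genome = self._genome_with(site)
        cls = classify_peaks([_peak("chr1", 150, 300, "p")], genome,
                             motif2=ConsensusMotif("GGGGGGG"))  # disable monomer
        assert cls["p"] == MotifClass.SOX_ONLY


def test_meme_roundtrip(tmp_path):
    pwms = [
        build_pwm_from_consensus(MOTIF1, certainty=0.9),
        build_pwm_from_consensus(MOTIF2, certainty=0.8),
    ]
    path = tmp_path / "motifs.meme"
    write_meme(path, pwms)
    back = read_meme(path)
    assert len(back) == 2
    for a, b in zip(pwms, back):
        assert a.name == b.name
        assert np.allclose(a.probs, b.probs, atol=1e-6)
        assert np.allclose(a.background, b.background, atol=1e-5)


def test_consensus_instance_always_matches(rng):
    for motif in (MOTIF1, MOTIF2):
        for _ in range(20):
            inst = consensus_instance(motif, rng)
            assert any(
                h.interval.start == 0 and h.strand == "+"
                for h in scan_consensus(inst, motif)
            )
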