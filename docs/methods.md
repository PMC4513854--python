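# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the simulator does and does not
emulate.

## Tag processing and signal maps

A *tag* is one uniquely aligned read reduced to (chromosome, 5′ base,
strand); minus-strand BED records map to `end − 1`. Processing follows
the standard single-end ChIP-seq recipe: exact duplicates (same
position and strand) are removed keeping first occurrences; when the
input library is deeper than the ChIP library it is downsampled to the
ChIP depth by uniform sampling without replacement; each tag is then
extended at its 3′ end to a 150-bp fragment (the average size-selected
library fragment) and assigned to every 32-nt bin the fragment
overlaps.

Choices the binning makes:

* A fragment increments **every** bin it overlaps, not just its
  midpoint bin. This makes bin sums a true per-base-coverage surrogate,
  which is verified against a brute-force coverage oracle in the tests.
* Fragments are clipped at chromosome edges; the clipped length is what
  enters coverage conservation checks.
* Region tag counts use fragment overlap (≥ 1 bp) by default, matching
  the signal-map semantics; a `five_prime_only` flag switches to
  counting raw 5′ positions for sensitivity analysis.

## Peak calling

The caller is a deliberately transparent local-Poisson model, not a
reimplementation of any published tool: no fragment-shift estimation
and no model building, because the simulator emits pre-extended
fragments and the rest of the pipeline needs an oracle-testable stage.

Per bin, the background rate is

λ = max(genome-wide input rate, input rate in each of 1 kb / 5 kb /
10 kb windows centred on the bin, rescaled to one bin).

The genome-wide floor prevents zero-λ divisions in input deserts. A bin
is significant when the Poisson upper tail P(X ≥ count | λ) ≤ 10⁻⁷
(the study-standard cutoff) **and** count/λ ≥ `min_fold`. Significant
bins within `merge_gap` (default 1, i.e. adjacent) merge into one peak;
the summit is the centre of the maximum-count bin (leftmost on ties),
the peak p-value is the minimum bin p-value (clamped into (0, 1] at the
smallest positive double), and fold enrichment is the maximum bin-level
count/λ.

`min_fold` defaults to 5 rather than the mfold = 16 sometimes used for
peak-model building elsewhere: mfold governs candidate selection for
model building in that context, not final filtering, and 16 as a hard
final filter would be far stricter than the behaviour it is usually
taken from. Passing `PeakCallConfig(min_fold=16)` restores the stricter
setting.

Peak tag counts are exact fragment-overlap recounts when the caller is
given the ChIP tags; otherwise they are estimated from bin sums divided
by the expected bins per fragment ((frag_len + bin_width − 1) /
bin_width).

The empirical FDR swaps treatment and control and re-calls: FDR =
swapped-peak count / real-peak count, defined as 0 when both are zero
and +∞ (with a warning) when only the real count is zero.

## Annotation

Peaks are classified by their **summit**, a point, which keeps the nine
categories mutually exclusive. Inside a transcript the precedence is
5′ UTR > 3′ UTR > exon > intron, with UTRs defined from the CDS bounds
(non-coding transcripts contribute only exon/intron). Outside all
transcripts: 0–1 kb upstream of a TSS is proximal promoter, 1–3 kb
distal promoter; 0–1 kb and 1–3 kb past the **transcript end** are
proximal/distal downstream; everything else is distal intergenic.
Among several qualifying transcripts the nearest TSS wins.

Anchoring the downstream windows at the transcript end is a deliberate
reading: anchoring them at the TSS would place them inside the gene
body where they would collide with the exon/intron categories. The
literal TSS-anchored reading is available via
`classify_location(..., downstream_of="tss")`.

TSS distances are signed in transcript orientation (negative =
upstream) and measured to the nearest TSS over all transcripts;
histograms use bins aligned so `[0, bin_width)` contains zero.

The random-location control samples input-tag 5′ positions uniformly
without replacement — inheriting whatever accessibility bias the input
has, which is the point — and gives each control interval the width of
a randomly drawn real peak (with replacement), clipped to chromosome
bounds. Enrichment is log₂(peak% / control%) per category with ±∞/NaN
sentinels for empty categories.

## Motif models and scanning

Three motif models:

* **Motif 1** (CCAAT box): IUPAC `AGCCAATSR` — the CCAAT core with its
  preferred 5′ AG and 3′ C/G-A/G flanks. The exact column frequencies
  of the underlying discovery logo are not numerically published, so a
  consensus-derived model is used; a `CCAAT`-core-only motif is also
  provided.
* **Motif 2** (SOX consensus): IUPAC `WWCAAWG`.
* **Motif 3** (dimeric site): Motif 2 and its reverse complement as an
  inverted repeat across a spacer, canonically 4 bp. The classifier
  fixes the spacer at 4; a 2–14 bp (or any) range is an exploratory
  scanning mode.

Consensus scanning is exact IUPAC matching on both strands (a minus
hit at `[i, i+w)` means the reverse complement of that window matches);
`N` in the sequence never matches any code. The implementation is a
vectorised position-mask conjunction, tested against an independent
regex oracle.

PWMs built from a consensus give the allowed bases at each position an
equal share of `certainty` (default 0.9) and the disallowed bases the
remainder; all-base columns are uniform. PWM scanning scores windows by
log₂(p/background) and converts the score threshold to/from p-values
through the exact null distribution of the discretised score, computed
by dynamic programming (one convolution per column over the four
bases). Scores are discretised at 10⁻³ bits; the DP is exact for the
discretised scores, and brute-force enumeration over all 4^w words
agrees to 10⁻⁶ for widths ≤ 6. The scanning p-threshold defaults to
10⁻⁴ (the FIMO default). Note a consequence faithful to those
semantics: a short degenerate motif such as the 7-bp `WWCAAWG` cannot
attain p ≤ 10⁻⁴ at all (its best word has p ≈ 9.8 × 10⁻⁴), so PWM
scanning at the default threshold reports nothing for it; consensus
scanning, or the 9-bp Motif 1, is the appropriate instrument there.

Peak classification scans each peak's full interval sequence (a
summit-window mode exists behind a flag): M1 present alone →
`M1_ONLY`; M1 plus Motif 2 and/or 3 → `M1_AND_SOX`; only SOX motifs →
`SOX_ONLY`; neither → `NONE`. Because a chance `WWCAAWG` occurs about
once per 1.3 kb per strand in realistic background, a few-hundred-bp
CCAAT peak quite often genuinely contains a SOX heptamer and is then
correctly `M1_AND_SOX`; validation against planted truth therefore
checks that the planted motif's *family* is detected, not exact 4-way
equality.

## Co-occupancy statistics

The scatter has one point per factor-A peak — locations with only a
factor-B peak are excluded by construction — with both factors' tag
counts measured on the same peak interval. Counts are raw tag numbers
(a per-million flag exists for unequal depths). Per-class fits are
unweighted OLS of A counts on B counts with Pearson r; classes with
fewer than two points or zero B-count variance return an undefined-fit
sentinel (None).

Peak-set overlap counts each peak once regardless of partner
multiplicity, at ≥ 1 bp. Conservation sampling draws `n_sample` peaks
without replacement and counts those with an overlapping peak in
*every* comparison set; "precisely overlapping" is operationalised as
≥ 1 bp, with a minimum-overlap-fraction option for stricter readings.
The promoter fraction is the share of summits within ±3 kb of any TSS.

## qPCR arithmetic

Percent input adjusts the input Ct for the dilution
(−log₂(1/fraction) cycles) and converts the Ct difference to a
fraction: `100 · 2^(adjusted_input − Ct_IP)`. Replicate SD propagates
through the exponent by the first-order delta method
(sd ≈ ln 2 · percent · √(sd²_in/n_in + sd²_ip/n_ip)). The quantity is
invariant under adding a constant to both Ct means.

Relative expression uses the Livak convention: ΔCt = Ct_target −
Ct_reference per condition, ΔΔCt = ΔCt_treated − ΔCt_control, fold =
`2^(−ΔΔCt)` — the sign is chosen so that a lower target Ct (more
transcript) in the treated condition gives fold > 1; the convention is
stated because the exponent's sign is written inconsistently across the
literature and flipping it inverts every fold change.

The t-test is the classic pooled-variance unpaired Student's test
(Welch by flag), two-sided, with stars at 0.05/0.01/0.001.

## The simulator

The generator reproduces the statistical structure the analysis
assumes, at a scale where every stage runs in seconds on one CPU:

* one 2-Mb chromosome of i.i.d. bases at GC 0.41 (human-like);
* 60 genes in non-overlapping slots, three exons each, coding bounds
  150 bp inside the transcript; 30 promoters receive a concrete Motif-1
  instance ending 106 bp upstream of the TSS, bound by **both**
  factors; 15 exact Motif-2 heptamers and 15 Motif-3 dimers (4-bp
  spacer) are planted in intergenic background, bound by factor A only;
* site strengths are lognormal(0, 0.75). The spread matters: it is the
  affinity variation across sites that makes both factors' tag counts
  co-vary at shared sites and produces the high M1-class correlation;
  with constant strengths the counts would differ only by sampling
  noise and carry no correlation signal;
* ChIP tracks draw a fraction `enrichment` (default 0.5) of their
  40,000 tags from sites (site chosen ∝ strength, fragment centre
  jittered with normal sd 30 bp, strand uniform — no strand-asymmetry
  model, since the pipeline extends tags rather than modelling
  bimodality) and the rest uniformly; the input track is 100,000
  background-only tags (> 2× ChIP depth, so the depth-matching
  downsampling step is always exercised);
* a repeat track of random 200–2,000 bp intervals covering ~10% of the
  genome; a truth table records every planted site's exact coordinates,
  class, bound factors and strength.

What it does **not** emulate — and what passing tests therefore do not
show about real data: mappability and alignment artefacts, GC bias,
PCR duplicates beyond exact-duplicate injection, copy-number variation,
nucleosome structure, strand-shift geometry, overlapping genes and
alternative TSSs, and any realistic motif false-positive landscape
beyond i.i.d. background. The fraction of peaks with no motif at all is
not fixed by the generator's defaults; it emerges from background peaks
and is configurable by adding unbound enrichment only indirectly
(`enrichment=0` runs are used as the null).

## Determinism and problem sizes

Every random step takes an explicit seed (numpy `SeedSequence`);
per-track simulation seeds are derived from the configuration seed by
fixed offsets, and reruns are byte-identical file-for-file. The test
suite validates oracles on ≤ 100-kb sequences, enumeration on PWM
widths ≤ 6, and recovery statistics on the 2-Mb default simulation
(single seeds where one suffices, seeds 1–5 where run-to-run stability
is the claim); these sizes were chosen so the full suite completes in
well under a minute while every assertion still has statistical power.

## Known limitations

* The caller's λ is estimated from the observed input without
  uncertainty propagation; at very low input depth the p-values are
  anti-conservative.
* Peak boundaries are bin-quantised (32 nt); summit resolution is half
  a bin.
* The PWM p-value DP assumes an i.i.d. background; no Markov
  background model.
* The annotation scheme assumes transcripts do not overlap; with
  overlapping isoforms the nearest-TSS tie-break decides.
* `2^(−ΔΔCt)` assumes perfect amplification efficiency (no
  efficiency-corrected Pfaffl model, no standard curves).
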