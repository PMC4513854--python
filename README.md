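# cobind

Analysis toolkit for studying how two transcription factors co-occupy
the same genomic sites, built around the kind of question raised by
SOX9/NF-Y co-binding in colorectal cancer cells: one factor (NF-Y)
binds the CCAAT box, the other (SOX9) has its own HMG-box consensus,
yet a large share of the second factor's ChIP-seq peaks sit exactly on
CCAAT promoters. `cobind` implements the full desk side of such a
study — from aligned tags to the statistics that distinguish genuine
co-occupancy from coincidental peak overlap — plus a simulator that
plants known binding sites so every stage can be validated against
ground truth.

## What it computes

* **Signal maps** — tags are reduced to their 5′ position and strand,
  deduplicated, depth-matched, extended in silico at the 3′ end to the
  150-bp library fragment size, and binned into 32-nt histograms.
* **Peak calling** — a transparent local-Poisson caller: per bin,
  λ = max(genome-wide input rate, input rate in 1/5/10-kb local
  windows); a bin is enriched when P(X ≥ count | λ) ≤ 10⁻⁷ and
  count/λ ≥ 5. The empirical FDR is the peak count after swapping
  treatment and control, divided by the real peak count.
* **Annotation** — summit distance to the nearest TSS (signed, in
  transcript orientation), a nine-category feature classification
  (promoter/UTR/exon/intron/downstream/intergenic), log₂ enrichment
  against a random control sampled from input-tag positions, and
  repeat-track overlap counts.
* **Motifs** — exact IUPAC consensus scanning (CCAAT box `AGCCAATSR`,
  SOX consensus `WWCAAWG`), log-odds PWM scanning with exact p-values
  by dynamic programming over the discretised score distribution (the
  p-value FIMO defines), a dimeric inverted-repeat scanner with a
  configurable spacer range (canonical 4 bp), ±25 bp summit-window
  extraction, and four-way peak classification (M1 only / M1+SOX /
  SOX only / none).
* **Co-occupancy** — per-peak tag counts for both factors with
  per-motif-class OLS regressions (Pearson r), peak-set overlap,
  promoter fraction within ±3 kb of a TSS, and cross-dataset
  conservation of sampled peaks.
* **qPCR arithmetic** — percent input
  (`100·2^(Ct_input − log2(1/fraction) − Ct_IP)`), fold over a
  gene-desert control, relative expression by `2^(−ΔΔCt)`, and the
  pooled-variance unpaired t-test with `*`/`**`/`***` stars.
* **Simulator** — a 2-Mb toy genome with gene models, CCAAT boxes
  planted 106 bp upstream of TSSs (bound by both factors), isolated
  monomeric and dimeric SOX sites (bound by one), lognormal site
  strengths, Gaussian fragment jitter, uniform background, and an
  input track at >2× ChIP depth — with a truth table of every planted
  site.

## Worked example

```bash
python examples/01_simulate_and_call_peaks.py
```

```
planted sites : 60
called peaks  : 60
sensitivity   : 1.00   (planted sites covered by a peak)
empirical FDR : 0.0000 (peaks surviving a treatment/control swap)
```

Every planted site is recovered and a treatment/control swap calls no
peaks. Continuing with `examples/04_cooccupancy.py`:

```
class          n    slope       r
M1_ONLY       24    0.418   0.998
M1_AND_SOX     6    0.392   0.982
SOX_ONLY      30   39.660   0.317
```

Factor-B tag counts track factor-A tag counts almost perfectly at
CCAAT (M1) peaks — both factors load onto the same sites, so site
strength drives both signals — while SOX-only peaks show no such
relationship. That contrast between per-class correlations is the
co-occupancy signature.

The other examples cover feature annotation against the random control
(`02`), motif scanning on the wild-type/mutant promoter oligos and peak
classification (`03`), and qPCR quantification (`05`). A thin CLI wraps
the same pipeline for shell use:

```bash
cobind run-all --outdir out --seed 1
cobind qpcr --table ct.tsv --input-fraction 0.01
```

## Layout

```
src/cobind/        formats, synthetic_data, signal_map, peak_calling,
                   annotation, motifs, cooccupancy, qpcr, pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite with brute-force oracles and
                   planted-truth recovery checks
docs/methods.md    models, parameters, numerical choices, limitations
```
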