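"""Stage orchestration: simulate → signal → callpeaks → annotate →
scanmotifs → cooccupancy, with a JSON run manifest.

Every stage reads and writes plain-text files (FASTA, BED, bedGraph,
TSV, JSON), so any contiguous suffix of the pipeline can start from
files produced elsewhere. Seeds are explicit per stage; rerunning with
the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .annotation import (
    FeatureDistribution,
    classify_locations,
    enrichment_log2,
    random_control,
    repeat_overlap,
    tss_distances,
)
from .cooccupancy import class_regression, promoter_fraction, scatter_table
from .formats import (
    read_bed3,
    read_fasta,
    read_gene_table,
    read_tags_bed,
)
from .motifs import MotifClass, classify_peaks, extract_summit_windows
from .peak_calling import (
    PeakCallConfig,
    call_peaks,
    empirical_fdr,
    read_peaks_bed,
    write_peaks_bed,
)
from .signal_map import build_signal_map, deduplicate, downsample
from .synthetic_data import SimulationConfig, generate_genome, write_dataset

log = logging.getLogger("cobind")

STAGES = ("simulate", "signal", "callpeaks", "annotate", "scanmotifs", "cooccupancy")


class PipelineError(RuntimeError):
    pass


def _require(manifest: dict, key: str, stage: str) -> str:
    path = manifest.get("paths", {}).get(key)
    if path is None or not Path(path).exists():
        raise PipelineError(f"stage {stage!r} needs missing input {key!r}")
    return path


def _prep_maps(outdir: Path, manifest: dict, seed: int) -> tuple[dict, dict]:
    """Dedupe, depth-match and bin the factor-A and input tracks."""
    genome = read_fasta(_require(manifest, "genome", "signal"))
    lengths = {c: len(s) for c, s in genome.items()}
    maps = {}
    chip = deduplicate(read_tags_bed(_require(manifest, "tags_factorA", "signal")))
    inp = deduplicate(read_tags_bed(_require(manifest, "tags_input", "signal")))
    if len(inp) > len(chip):
        inp = downsample(inp, len(chip), seed)
    maps["chip"] = build_signal_map(chip, lengths)
    maps["input"] = build_signal_map(inp, lengths)
    tags = {"chip": chip, "input": inp}
    for name, sm in maps.items():
        path = outdir / f"signal_{name}.bedgraph"
        sm.to_bedgraph(path)
        manifest["paths"][f"signal_{name}"] = str(path)
    return maps, tags


def run_pipeline(
    config: dict | None = None,
    stages: Sequence[str] = STAGES,
    outdir: str | Path = "cobind_out",
    seed: int = 0,
) -> dict:
    """Run the requested stages and return the run manifest.

    ``config`` may carry ``simulation`` (SimulationConfig fields),
    ``peak_calling`` (PeakCallConfig fields) and ``paths`` (pre-existing
    inputs for suffix runs) blocks.
    """
    config = config or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineError(f"unknown stages {bad}")
    stages = [s for s in STAGES if s in stages]

    sim_cfg = SimulationConfig(**{**config.get("simulation", {}), "seed": seed})
    pc_cfg = PeakCallConfig(**config.get("peak_calling", {}))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
        "config": {"simulation": asdict(sim_cfg), "peak_calling": asdict(pc_cfg)},
        "paths": dict(config.get("paths", {})),
    }

    state: dict = {}
    for stage in stages:
        t0 = time.time()
        if stage == "simulate":
            dataset = generate_genome(sim_cfg)
            ds_manifest = write_dataset(dataset, outdir)
            manifest["paths"].update(ds_manifest["paths"])
        elif stage == "signal":
            maps, tags = _prep_maps(outdir, manifest, seed)
            state["maps"], state["tags"] = maps, tags
        elif stage == "callpeaks":
            if "maps" not in state:
                maps, tags = _prep_maps(outdir, manifest, seed)
                state["maps"], state["tags"] = maps, tags
            peaks = call_peaks(state["maps"]["chip"], state["maps"]["input"],
                               pc_cfg, chip_tags=state["tags"]["chip"])
            fdr = empirical_fdr(state["maps"]["chip"], state["maps"]["input"], pc_cfg)
            path = outdir / "peaks.bed"
            write_peaks_bed(path, peaks)
            manifest["paths"]["peaks"] = str(path)
            manifest["empirical_fdr"] = fdr
            manifest["n_peaks"] = len(peaks)
            state["peaks"] = peaks
        elif stage == "annotate":
            peaks = state.get("peaks") or read_peaks_bed(
                _require(manifest, "peaks", stage)
            )
            state["peaks"] = peaks
            genes = read_gene_table(_require(manifest, "genes", stage))
            genome = read_fasta(_require(manifest, "genome", stage))
            lengths = {c: len(s) for c, s in genome.items()}
            cats = classify_locations(peaks, genes)
            dists, _hist = tss_distances(peaks, genes)
            peak_dist = FeatureDistribution.from_categories(cats)
            input_tags = read_tags_bed(_require(manifest, "tags_input", stage))
            controls = random_control(input_tags, peaks, len(peaks), seed, lengths)
            ctrl_cats = classify_locations(controls, genes)
            ctrl_dist = FeatureDistribution.from_categories(ctrl_cats)
            log2 = enrichment_log2(peak_dist, ctrl_dist)
            table = pd.DataFrame(
                {
                    "category": [c.value for c in peak_dist.counts],
                    "peak_count": list(peak_dist.counts.values()),
                    "peak_pct": [peak_dist.percentages[c] for c in peak_dist.counts],
                    "control_count": list(ctrl_dist.counts.values()),
                    "control_pct": [ctrl_dist.percentages[c] for c in ctrl_dist.counts],
                    "log2_enrichment": [log2[c] for c in peak_dist.counts],
                }
            )
            table.to_csv(outdir / "feature_enrichment.tsv", sep="\t", index=False)
            manifest["paths"]["feature_enrichment"] = str(outdir / "feature_enrichment.tsv")
            ann = pd.DataFrame(
                {
                    "peak": [p.name for p in peaks],
                    "category": [c.value for c in cats],
                    "tss_distance": dists,
                }
            )
            ann.to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False)
            manifest["paths"]["peak_annotation"] = str(outdir / "peak_annotation.tsv")
            if manifest["paths"].get("repeats"):
                repeats = read_bed3(manifest["paths"]["repeats"])
                n_rep, n_tot = repeat_overlap(peaks, repeats)
                n_rep_c, _ = repeat_overlap(controls, repeats)
                manifest["repeat_overlap"] = {
                    "peaks": n_rep, "control": n_rep_c, "total": n_tot,
                }
        elif stage == "scanmotifs":
            peaks = state.get("peaks") or read_peaks_bed(
                _require(manifest, "peaks", stage)
            )
            state["peaks"] = peaks
            genome = read_fasta(_require(manifest, "genome", stage))
            windows = extract_summit_windows(peaks, genome, top_n=min(1200, len(peaks)))
            classes = classify_peaks(peaks, genome)
            state["classes"] = classes
            df = pd.DataFrame(
                {
                    "peak": [p.name for p in peaks],
                    "motif_class": [classes[p.name].value for p in peaks],
                }
            )
            df.to_csv(outdir / "motif_classes.tsv", sep="\t", index=False)
            manifest["paths"]["motif_classes"] = str(outdir / "motif_classes.tsv")
            with open(outdir / "summit_windows.fa", "w") as fh:
                for w in windows:
                    fh.write(f">{w.peak_name}\n{w.sequence}\n")
            manifest["paths"]["summit_windows"] = str(outdir / "summit_windows.fa")
        elif stage == "cooccupancy":
            peaks = state.get("peaks") or read_peaks_bed(
                _require(manifest, "peaks", stage)
            )
            classes = state.get("classes")
            if classes is None:
                df = pd.read_csv(_require(manifest, "motif_classes", stage), sep="\t")
                classes = {
                    r.peak: MotifClass(r.motif_class) for r in df.itertuples()
                }
            tags_a = read_tags_bed(_require(manifest, "tags_factorA", stage))
            tags_b = read_tags_bed(_require(manifest, "tags_factorB", stage))
            genes = read_gene_table(_require(manifest, "genes", stage))
            points = scatter_table(peaks, tags_a, tags_b, classes)
            df = pd.DataFrame(
                {
                    "peak": [pt.peak_name for pt in points],
                    "tags_a": [pt.tags_a for pt in points],
                    "tags_b": [pt.tags_b for pt in points],
                    "motif_class": [pt.motif_class.value for pt in points],
                }
            )
            df.to_csv(outdir / "scatter.tsv", sep="\t", index=False)
            manifest["paths"]["scatter"] = str(outdir / "scatter.tsv")
            fits = {}
            for cls in MotifClass:
                fit = class_regression(points, cls)
                fits[cls.value] = asdict(fit) if fit is not None else None
            manifest["regressions"] = fits
            manifest["promoter_fraction_3kb"] = promoter_fraction(peaks, genes)
        log.info("stage %s done in %.2fs", stage, time.time() - t0)

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
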