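"""Shared helper for the example scripts: tags → maps → peaks."""

from cobind import (
    build_signal_map,
    call_peaks,
    deduplicate,
    downsample,
    simulate_tags,
)


def toy_peaks(dataset, seed: int = 1):
    """Run the standard tag-processing chain on a simulated dataset and
    return (peaks, chromosome lengths)."""
    lengths = {c: len(s) for c, s in dataset.genome.items()}
    chip = deduplicate(simulate_tags(dataset, "factorA"))
    inp = deduplicate(simulate_tags(dataset, "input"))
    inp = downsample(inp, len(chip), seed)
    peaks = call_peaks(
        build_signal_map(chip, lengths),
        build_signal_map(inp, lengths),
        chip_tags=chip,
    )
    return peaks, lengths
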