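import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cobind.peak_calling import call_peaks
from cobind.signal_map import build_signal_map, deduplicate, downsample
from cobind.synthetic_data import (
    FACTOR_A,
    FACTOR_B,
    SimulationConfig,
    generate_genome,
    simulate_tags,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def simulated_run(seed: int, **overrides):
    """Generate one toy dataset and run tags → maps → peaks.

    Returns a dict with the dataset, per-track tags, depth-matched signal
    maps and called peaks. Used by tests that need several independent
    seeds; the session fixtures below cache the seed-1 run.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    ds = generate_genome(cfg)
    lengths = {c: len(s) for c, s in ds.genome.items()}
    tags_a = simulate_tags(ds, FACTOR_A)
    tags_b = simulate_tags(ds, FACTOR_B) if cfg.n_ccaat_promoters else []
    tags_input = simulate_tags(ds, "input")
    chip = deduplicate(tags_a)
    inp = deduplicate(tags_input)
    if len(inp) > len(chip):
        inp = downsample(inp, len(chip), seed)
    chip_map = build_signal_map(chip, lengths)
    input_map = build_signal_map(inp, lengths)
    peaks = call_peaks(chip_map, input_map, chip_tags=chip)
    return {
        "config": cfg,
        "dataset": ds,
        "lengths": lengths,
        "tags_a": tags_a,
        "tags_b": tags_b,
        "tags_input": tags_input,
        "chip_map": chip_map,
        "input_map": input_map,
        "peaks": peaks,
    }


@pytest.fixture(scope="session")
def toy():
    """Default toy simulation at seed 1, shared across the suite."""
    return simulated_run(1)


@pytest.fixture(scope="session")
def toy_dataset(toy):
    return toy["dataset"]


@pytest.fixture(scope="session")
def toy_peaks(toy):
    return toy["peaks"]


@pytest.fixture
def rng():
    return np.random.default_rng(1)
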