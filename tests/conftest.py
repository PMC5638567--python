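import numpy as np
import pytest

import taqase as tq
from taqase.pipeline import PipelineConfig, analyze_plate


@pytest.fixture(scope="session")
def reference_df():
    return tq.load_reference_standards()


@pytest.fixture(scope="session")
def cdna_points():
    return tq.reference_standard_points("cDNA")


@pytest.fixture(scope="session")
def gdna_points():
    return tq.reference_standard_points("gDNA")


def make_curve(y0=0.1, a=3.0, b=20.0, c=1.5, n_cycles=46, noise_sd=0.0,
               seed=0, channel="FAM", well="w1"):
    """Generate a curve exactly on the 4-parameter logistic (plus optional noise)."""
    t = np.arange(1, n_cycles + 1)
    y = tq.logistic4(t, y0, a, b, c)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, size=len(t))
    return tq.FluorescenceCurve(well, channel, t, y)


def run_simulated_plate(design, seed, noise_sd=0.005, config=None):
    """Simulate a plate and run the full in-memory analysis."""
    base = tq.ReactionSimConfig(true_x=0.5, noise_sd=noise_sd)
    plate = tq.simulate_plate(design, base_config=base, seed=seed)
    return plate, analyze_plate(plate.curves, plate.sample_entries(),
                                config or PipelineConfig())
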