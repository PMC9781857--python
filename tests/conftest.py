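import numpy as np
import pandas as pd
import pytest

from fgng.pipeline import PipelineOptions, estimate_frames
from fgng.simulate import SimulationConfig, simulate_cohort

#: one RNG root for every stochastic test in the suite
SUITE_SEED = 2022


def estimate_cohort(config: SimulationConfig, options: PipelineOptions | None = None) -> pd.DataFrame:
    """Simulate one cohort and run the full estimation path over it in memory.

    Returns the per-sample results joined with the simulated truth.
    """
    bundle = simulate_cohort(config)
    results, _ = estimate_frames(
        bundle.design,
        bundle.intensities,
        bundle.bodywater,
        bundle.standard_curve,
        options or PipelineOptions(),
    )
    return results.merge(bundle.truth, on="sample_id", validate="one_to_one")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture()
def noise_free_config() -> SimulationConfig:
    return SimulationConfig(seed=SUITE_SEED, intensity_noise_cv=0.0, reading_noise_sd=0.0)
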