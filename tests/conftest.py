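import numpy as np
import pytest

import fibroquant as fq
from fibroquant import PipelineConfig, pipeline


@pytest.fixture(scope="session")
def synth_config() -> PipelineConfig:
    """Pipeline configuration matched to the 1 um/px synthetic renders."""
    return PipelineConfig(pixel_size_um=1.0)


@pytest.fixture(scope="session")
def mash_sample():
    return fq.render_sample(fq.MASH_PRESET, 11)


@pytest.fixture(scope="session")
def lean_sample():
    return fq.render_sample(fq.LEAN_PRESET, 11)


@pytest.fixture(scope="session")
def small_cohort(synth_config):
    """A quantified 3 LEAN + 3 MASH cohort shared across scoring tests."""
    samples = fq.make_cohort(3, base_seed=3)
    measurements, _ = pipeline.quantify_cohort(samples, synth_config)
    table = pipeline.cohort_qft_table(measurements)
    return samples, measurements, table


def bar_mask(length: int = 50, width: int = 5, pad: int = 5) -> np.ndarray:
    """Axis-aligned bar fixture used by graph and morphometry tests."""
    mask = np.zeros((width + 2 * pad, length + 2 * pad), dtype=bool)
    mask[pad : pad + width, pad : pad + length] = True
    return mask
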