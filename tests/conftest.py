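import numpy as np
import pytest

from strokevol import PhantomSpec, generate_phantom

PAPER_ECHO_TIMES = np.arange(18.0, 217.0, 18.0)


@pytest.fixture(scope="session")
def echo_times():
    """The 12-echo CPMG train: TE 18..216 ms, 18 ms spacing."""
    return PAPER_ECHO_TIMES.copy()


@pytest.fixture(scope="session")
def small_phantom():
    """One noiseless 64-matrix phantom with its ground truth (read-only)."""
    spec = PhantomSpec(matrix=64, noise_model="none", seed=11)
    image, truth = generate_phantom(spec)
    return spec, image, truth
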