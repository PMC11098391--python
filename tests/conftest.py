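import numpy as np
import pytest

from ogttkit import AckermanParams, simulate_ackerman_curve


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def sample_interior_params(rng, n):
    """Typical-curve parameters well inside the fitting box."""
    return [
        AckermanParams(
            y_F=rng.uniform(0.80, 1.20),
            A=rng.uniform(0.4, 1.8),
            k=rng.uniform(0.6, 2.8),
            omega=rng.uniform(1.2, 4.2),
        )
        for _ in range(n)
    ]


def zero_noise_curve(params, pid="sim"):
    return simulate_ackerman_curve(params, 0.0, 0, participant_id=pid)
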