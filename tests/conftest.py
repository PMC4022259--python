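import numpy as np
import pytest

from dissolvekit import NoiseSpec, generate_batch, predict_kp

TIMES = np.array([10.0, 15.0, 20.0, 30.0, 45.0, 60.0])


@pytest.fixture
def times():
    return TIMES.copy()


@pytest.fixture
def kp_curve(times):
    """Noise-free power-law release curve, k=5, n=0.43."""
    return predict_kp(times, 5.0, 0.43)


@pytest.fixture
def ref_batch(times):
    return generate_batch(
        "korsmeyer_peppas", (12.0, 0.35), times, n_units=12,
        noise=NoiseSpec(within_unit_sd=3.0, between_unit_sd=2.0, seed=101),
        label="reference",
    )


@pytest.fixture
def test_batch(times):
    return generate_batch(
        "korsmeyer_peppas", (9.0, 0.42), times, n_units=12,
        noise=NoiseSpec(within_unit_sd=3.0, between_unit_sd=2.0, seed=202),
        label="test",
    )


def batch_csv(batch) -> str:
    """Render a batch in the CSV dialect load_batch reads."""
    return batch.to_frame().rename_axis("unit").to_csv()
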