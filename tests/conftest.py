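import dataclasses

import pytest

import papwv


@pytest.fixture
def ht_exact():
    """High-temporal preset without pixel quantization (exact areas)."""
    return dataclasses.replace(papwv.HIGH_TEMPORAL, quantize_area=False)


@pytest.fixture
def hs_exact():
    return dataclasses.replace(papwv.HIGH_SPATIAL, quantize_area=False)


@pytest.fixture
def dense_exact():
    """1 ms sampling, no quantization: near-continuous reference curves."""
    return dataclasses.replace(
        papwv.HIGH_TEMPORAL, temporal_resolution=1.0, n_phases=900,
        quantize_area=False,
    )


@pytest.fixture
def clean_truth():
    """Noise-free, reflection-free subject at the default operating point."""
    return papwv.SyntheticTruth(true_pwv=2.5)
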