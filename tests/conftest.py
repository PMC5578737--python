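import numpy as np
import pytest

from tim23ephys import Protocol, RecordingMeta, default_model


@pytest.fixture
def sym_meta():
    """Symmetric 250 mM KCl, the constant-voltage recording condition."""
    return RecordingMeta(
        voltage_mV=80.0, cis_K_mM=250.0, trans_K_mM=250.0,
        temperature_K=298.15, sample_rate_Hz=10_000.0, duration_s=60.0,
    )


@pytest.fixture
def asym_meta():
    """12.5-fold cis:trans KCl gradient used for reversal potentials."""
    return RecordingMeta(
        voltage_mV=0.0, cis_K_mM=250.0, trans_K_mM=20.0,
        temperature_K=298.15, sample_rate_Hz=10_000.0, duration_s=10.0,
    )


@pytest.fixture
def wt_model():
    return default_model("wildtype")


@pytest.fixture
def mutant_model():
    return default_model("N150A")


@pytest.fixture
def short_protocol():
    return Protocol(voltage_mV=80.0, duration_s=10.0)


def make_step_trace(levels_pA, durations_s, sample_rate=10_000.0, noise_sd=0.0, seed=0):
    """Piecewise-constant trace with optional Gaussian noise (test helper)."""
    from tim23ephys import Trace

    rng = np.random.default_rng(seed)
    pieces = [
        np.full(int(round(d * sample_rate)), lvl, dtype=float)
        for lvl, d in zip(levels_pA, durations_s)
    ]
    x = np.concatenate(pieces)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, len(x))
    meta = RecordingMeta(
        voltage_mV=80.0, cis_K_mM=250.0, trans_K_mM=250.0,
        sample_rate_Hz=sample_rate, duration_s=len(x) / sample_rate,
    )
    return Trace(meta=meta, samples=x)
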