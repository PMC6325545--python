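import numpy as np
import pytest

import sniffalign as sa


@pytest.fixture(scope="session")
def sniff_params():
    return sa.SniffGenParams()


@pytest.fixture(scope="session")
def fd_session(sniff_params):
    """60-trial FD-generated cell-odor dataset, lambda* = 0.4."""
    trials, gt = sa.generate_neural_session(
        sniff_params, sa.NeuralGenParams(lambda_true=0.4), 60, seed=42
    )
    return trials, gt


@pytest.fixture(scope="session")
def phase_session(sniff_params):
    """60-trial dataset whose rate template scales with cycle duration."""
    trials, gt = sa.generate_neural_session(
        sniff_params, sa.NeuralGenParams(latency_model="phase"), 60, seed=43
    )
    return trials, gt


def constant_trace(value=-1.0, duration_ms=200.0, fs=1000.0, lead_ms=0.0):
    """A flat pressure trace (optionally preceded by zeros), for flux tests."""
    n = int(round(duration_ms * fs / 1000.0)) + 1
    samples = np.full(n, value)
    if lead_ms > 0:
        samples = np.concatenate([np.zeros(int(round(lead_ms * fs / 1000.0))), samples])
    return sa.PressureTrace(samples=samples, sample_rate=fs)


def make_trial(spikes, duration, t_inh=None, trial_id=None, flux=None):
    t_inh = duration / 2.0 if t_inh is None else t_inh
    cyc = sa.SniffCycle(onset=0.0, inhalation_offset=t_inh, cycle_end=duration,
                        trial_id=trial_id)
    return sa.SpikeTrainTrial(spike_times=np.asarray(spikes, float), cycle=cyc,
                              trial_id=trial_id, flux=flux)
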