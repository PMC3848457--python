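import numpy as np
import pytest

from spindar import SpindleSimSpec, model1_spec, simulate_ar_changepoint, \
    simulate_spindle_eeg, preprocess


def simulate_ar(coeffs, n, sd=1.0, seed=0, burn=200):
    """Independent tiny AR simulator used as a fixture source."""
    coeffs = np.asarray(coeffs, dtype=float)
    rng = np.random.default_rng(seed)
    p = coeffs.size
    x = np.zeros(n + burn)
    eps = sd * rng.standard_normal(n + burn)
    for t in range(n + burn):
        acc = eps[t]
        for i in range(p):
            if t - i - 1 >= 0:
                acc += coeffs[i] * x[t - i - 1]
        x[t] = acc
    return x[burn:]


@pytest.fixture(scope="session")
def model1_run():
    """Model-1 change-point signal and its SDAR(2, 0.01) traces."""
    from spindar import sdar_run

    x, cps = simulate_ar_changepoint(model1_spec(seed=0))
    loss, params, sigma2, mu = sdar_run(x, 2, 0.01, train_len=500)
    return x, cps, loss, params, sigma2, mu


@pytest.fixture(scope="session")
def spindle_fixture():
    """SNR-3 burst fixture, preprocessed to 128 Hz / [6, 15] Hz."""
    spec = SpindleSimSpec(snr=3.0, seed=0)
    data, truth, labels = simulate_spindle_eeg(spec)
    proc, fs = preprocess(data, spec.fs_gen, (6.0, 15.0), 8, fs_out=128.0)
    return spec, proc, fs, truth, labels
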