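"""Shared fixtures.

The expensive simulations (the full default-scale study run and the
500-spectrum null/peak fit batteries) are computed once per session and
shared between the module tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from colorgamma import peakfit, pipeline, spectral, synthetic

# committed a priori; see notes on stochastic test policy in docs/methods.md
SUITE_SEED = 0


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Default-scale study: 10 participants x 30 trials, registry defaults."""
    out = tmp_path_factory.mktemp("run")
    cfg = pipeline.RunConfig(seed=SUITE_SEED, out_dir=str(out))
    tables = pipeline.run_study(cfg)
    return {"tables": tables, "config": cfg, "out_dir": out}


@pytest.fixture(scope="session")
def null_draws():
    """500 peak-free change spectra at the modeled experiment's fitting scale.

    The fitter operates on per-participant, per-condition trial-average
    spectra; the modeled experiment collects 60 trials per color (two blocks
    of 30), so the operating-characteristic batteries use that averaging.
    (The pipeline's reduced 10x30 acceptance runs are noisier; their higher
    false-peak rate is documented in docs/methods.md.)
    """
    freqs, draws = synthetic.simulate_null_change_spectra(
        500, n_trials=60, seed=SUITE_SEED
    )
    return freqs, draws


@pytest.fixture(scope="session")
def null_fits(null_draws):
    """Three-model fits of the 500 null spectra (specificity battery)."""
    freqs, draws = null_draws
    return [
        peakfit.fit_peak_models(spectral.PowerChangeSpectrum(freqs, d))
        for d in draws
    ]


SENSITIVITY_PEAK_HZ = 45.9
SENSITIVITY_AMP = 20.0
SENSITIVITY_SD_HZ = 4.0
N_SENSITIVITY = 150  # fit cost bounds the battery size; binomially ample


@pytest.fixture(scope="session")
def peak_fits(null_draws):
    """Fits of the first nulls plus a 20%-amplitude, 4-Hz-sd Gaussian peak."""
    freqs, draws = null_draws
    bump = SENSITIVITY_AMP * np.exp(
        -0.5 * ((freqs - SENSITIVITY_PEAK_HZ) / SENSITIVITY_SD_HZ) ** 2
    )
    return [
        peakfit.fit_peak_models(spectral.PowerChangeSpectrum(freqs, d + bump))
        for d in draws[:N_SENSITIVITY]
    ]
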