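"""Shared fixtures: synthetic datasets generated once per session."""

import numpy as np
import pytest
from scipy.signal import lfilter

import memperm as mp


@pytest.fixture(scope="session")
def membrane_run():
    """Full 81-window membrane study on a known landscape, analyzed end to end.

    The generating conditions emulate the umbrella-sampling protocol the
    package targets: windows every 1 Å over −40…40 Å, k = 2.5
    kcal·mol⁻¹·Å⁻², 310 K, 5×10⁴ saved points per window, with a 5.4
    kcal/mol central barrier, −2.8 kcal/mol wells at ±14 Å and a 10-fold
    diffusivity drop in the core. Generated and analyzed once; several
    recovery tests read from it.
    """
    landscape = mp.membrane_landscape(seed=3)
    dataset, truth_w, truth_d = mp.generate_dataset(
        landscape, n_steps=1_000_000, base_seed=3
    )
    config = mp.RunConfig(half_width=14.0)
    result = mp.pipeline_permeation(config, dataset=dataset)
    return {
        "landscape": landscape,
        "dataset": dataset,
        "truth_w": truth_w,
        "truth_d": truth_d,
        "config": config,
        "result": result,
    }


@pytest.fixture(scope="session")
def flat_dataset():
    """Small flat-landscape dataset (pure OU windows, D = 0.1 Å²/ps)."""
    landscape = mp.LandscapeSpec(form="flat")
    dataset, truth_w, truth_d = mp.generate_dataset(
        landscape,
        centers=np.arange(-10.0, 11.0, 2.0),
        n_steps=400_000,
        base_seed=21,
    )
    return landscape, dataset, truth_w, truth_d


def make_ou_series(n, dt, tau, sigma2, seed):
    """Exact AR(1) discretization of an OU process (independent of the
    Brownian-dynamics generator): z_{k+1} = φ z_k + sqrt(σ²(1−φ²)) ξ."""
    rng = np.random.default_rng(seed)
    phi = np.exp(-dt / tau)
    z0 = rng.standard_normal() * np.sqrt(sigma2)
    noise = rng.standard_normal(n) * np.sqrt(sigma2 * (1 - phi**2))
    z, _ = lfilter([1.0], [1.0, -phi], noise, zi=np.array([phi * z0]))
    return z


@pytest.fixture
def ou_series():
    return make_ou_series
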