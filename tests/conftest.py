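"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import rishglm as rg


@pytest.fixture(scope="session")
def dirs60():
    """The packaged 60-direction gradient scheme."""
    return rg.packaged_directions()


@pytest.fixture(scope="session")
def exact_spec():
    """Order-6 basis with exact (unregularized) least-squares fitting."""
    return rg.SHBasisSpec(max_order=6, lambda_reg=0.0)


def tiny_phantom_config(**overrides):
    """A small, fast two-site phantom; overridable per test."""
    base = dict(
        grid_shape=(8, 8, 8),
        sites={"A": rg.SitePopulation(4, 50.0, 5.0, 0.5),
               "B": rg.SitePopulation(4, 50.0, 5.0, 0.5)},
        noise_model="none",
        seed=1,
    )
    base.update(overrides)
    return rg.PhantomConfig(**base)


@pytest.fixture(scope="session")
def tiny_noiseless_cohort():
    """Four subjects per site, no noise, default random site effect."""
    cfg = tiny_phantom_config(age_slope=0.0, sex_offset=0.0)
    return cfg, *rg.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_noisy_cohort():
    """Small Rician-noise cohort used by estimation tests."""
    cfg = tiny_phantom_config(noise_model="rician", snr=30.0,
                              sites={"A": rg.SitePopulation(6, 50, 5, 0.5),
                                     "B": rg.SitePopulation(6, 50, 5, 0.5)})
    return cfg, *rg.simulate_cohort(cfg)


def band_limited_coeffs(rng, grid_shape, max_order=6):
    """Random SH coefficient image (band-limited by construction)."""
    imap = rg.SHIndexMap.for_order(max_order)
    coeffs = rng.normal(size=grid_shape + (len(imap),))
    # keep the mean (l=0) component dominant and positive, like real signals
    coeffs[..., 0] = np.abs(coeffs[..., 0]) + 3.0
    mask = np.ones(grid_shape, dtype=bool)
    return rg.SHCoefficientImage(coeffs, imap, 1000.0, mask)
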