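"""Tensor metrics, adjusted group tests, recovery error, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rishglm as rg
from rishglm.io_core import ShellData


def _tensor_shell(dirs, D, s0=1.0, bval=1000.0, grid=(2, 2, 2)):
    atten = np.exp(-bval * np.einsum("ij,jk,ik->i", dirs, D, dirs))
    data = np.broadcast_to(s0 * atten, grid + (len(dirs),)).copy()
    return ShellData(data, dirs, bval, np.full(grid, s0))


def test_dti_recovers_known_tensor(dirs60):
    D = np.diag([1.7e-3, 0.2e-3, 0.2e-3])
    tensor = rg.fit_dti(_tensor_shell(dirs60, D))
    np.testing.assert_allclose(tensor.elements[0, 0, 0, :3],
                               [1.7e-3, 0.2e-3, 0.2e-3], rtol=1e-8)
    np.testing.assert_allclose(tensor.elements[0, 0, 0, 3:], 0.0, atol=1e-12)
    fa, md = rg.fa_md(tensor)
    np.testing.assert_allclose(md, 0.7e-3, rtol=1e-8)
    # closed form: sqrt(1.5)*||(1,-.5,-.5)||/||(1.7,.2,.2)|| = 0.8704
    np.testing.assert_allclose(fa, 0.87038, rtol=1e-4)


def test_dti_limit_cases(dirs60):
    iso = rg.fit_dti(_tensor_shell(dirs60, np.eye(3) * 1e-3))
    fa, md = rg.fa_md(iso)
    np.testing.assert_allclose(fa, 0.0, atol=1e-8)
    np.testing.assert_allclose(md, 1e-3, rtol=1e-8)
    # all signals equal S0 -> zero tensor, FA defined as 0
    flat = rg.fit_dti(ShellData(np.ones((2, 2, 2, 60)), dirs60, 1000.0,
                                np.ones((2, 2, 2))))
    fa, md = rg.fa_md(flat)
    np.testing.assert_allclose(md, 0.0, atol=1e-12)
    np.testing.assert_allclose(fa, 0.0, atol=1e-12)


def test_dti_rejects_degenerate_directions():
    dirs = np.tile([1.0, 0.0, 0.0], (10, 1))
    with pytest.raises(ValueError, match="rank|directions"):
        rg.fit_dti(ShellData(np.ones((2, 2, 2, 10)), dirs, 1000.0,
                             np.ones((2, 2, 2))))


def _group_table(n_a, n_b, rng):
    df = pd.DataFrame({
        "site": ["A"] * n_a + ["B"] * n_b,
        "age": rng.uniform(40, 60, n_a + n_b),
    }, index=[f"s{i}" for i in range(n_a + n_b)])
    return rg.CovariateTable(df, covariate_columns=("age",))


def test_group_test_matches_classical_t_test():
    """Without covariates the voxel-wise GLM contrast is the classical
    equal-variance two-sample t-test (oracle: scipy.stats.ttest_ind)."""
    rng = np.random.default_rng(0)
    table = _group_table(8, 7, rng)
    maps = [rng.normal(size=(4, 4, 4)) for _ in range(15)]
    res = rg.adjusted_group_test(maps, table, ("A", "B"), covariates=())
    a = np.stack(maps[:8])
    b = np.stack(maps[8:])
    t_ref, p_ref = stats.ttest_ind(b, a, axis=0)
    np.testing.assert_allclose(res.t_map, t_ref, rtol=1e-10)
    np.testing.assert_allclose(res.p_map, p_ref, rtol=1e-10)
    assert res.dof == 13


def test_group_test_type_one_error_calibrated():
    """No site effect: significant fraction ~ alpha (binomial tolerance)."""
    rng = np.random.default_rng(1)
    table = _group_table(10, 10, rng)
    maps = [rng.normal(size=(16, 16, 16)) for _ in range(20)]
    res = rg.adjusted_group_test(maps, table, ("A", "B"),
                                 covariates=("age",), alpha=0.05)
    n_vox = 16 ** 3
    se = np.sqrt(0.05 * 0.95 / n_vox)
    assert abs(res.significant_fraction - 0.05) < 5 * se + 0.01


def test_group_test_power_and_zero_variance_exclusion():
    rng = np.random.default_rng(2)
    table = _group_table(8, 8, rng)
    maps = [rng.normal(size=(4, 4, 4)) for _ in range(8)]
    maps += [rng.normal(loc=5.0, size=(4, 4, 4)) for _ in range(8)]
    res = rg.adjusted_group_test(maps, table, ("A", "B"))
    assert res.significant_fraction > 0.9
    # identical maps for every subject -> undefined t, voxel excluded
    const = [np.ones((2, 2, 2))] * 16
    res0 = rg.adjusted_group_test(const, table, ("A", "B"))
    assert res0.n_excluded == 8
    assert res0.significant_fraction == 0.0


def test_scaling_recovery_error_summaries():
    grid = (3, 3, 3)
    truth = np.full(grid + (2,), 2.0)
    est = rg.ScalingMaps(truth * 1.1, (0, 2), np.ones(grid, bool))
    err = rg.scaling_recovery_error(est, truth)
    assert err[0]["median"] == pytest.approx(0.1)
    assert err[2]["p90"] == pytest.approx(0.1)
    exact = rg.ScalingMaps(truth.copy(), (0, 2), np.ones(grid, bool))
    assert rg.scaling_recovery_error(exact, truth)[0]["median"] == 0.0


def test_age_metric_correlation():
    rng = np.random.default_rng(3)
    ages = rng.uniform(30, 70, 12)
    df = pd.DataFrame({"site": ["A"] * 12, "age": ages},
                      index=[f"s{i}" for i in range(12)])
    table = rg.CovariateTable(df, covariate_columns=("age",))
    maps = [np.full((2, 2, 2), 1.0 - 0.005 * a) for a in ages]
    r, p = rg.age_metric_correlation(maps, table)
    assert r == pytest.approx(-1.0)
    # age-independent metric: |r| small
    rng2 = np.random.default_rng(4)
    noise_maps = [np.full((2, 2, 2), rng2.normal()) for _ in ages]
    r2, p2 = rg.age_metric_correlation(noise_maps, table)
    assert abs(r2) < 0.6 and p2 > 0.01
    # degenerate input reported as undefined
    r3, _ = rg.age_metric_correlation([np.ones((2, 2, 2))] * 12, table)
    assert np.isnan(r3)
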