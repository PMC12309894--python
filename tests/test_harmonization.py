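"""Design matrices, voxel-wise GLM, scaling maps, model lifecycle."""

import numpy as np
import pandas as pd
import pytest

import rishglm as rg
from rishglm.harmonization import GridMismatchError


def _table(sites, ages=None, extra=None):
    n = len(sites)
    df = pd.DataFrame({
        "site": sites,
        "age": ages if ages is not None else np.linspace(40, 60, n),
    }, index=[f"s{i}" for i in range(n)])
    cov = ["age"]
    if extra:
        for k, v in extra.items():
            df[k] = v
            cov.append(k)
    return rg.CovariateTable(df, covariate_columns=tuple(cov))


def _features(rng, n, grid=(3, 3, 3), orders=(0, 2, 4, 6), offset=None):
    out = []
    for i in range(n):
        f = rng.random(grid + (len(orders),)) + 1.0
        if offset is not None:
            f = f + offset[i]
        out.append(rg.RISHFeatureImage(f, orders, np.ones(grid, bool), 1000.0))
    return out


def test_build_design_shape_centering_and_rank():
    table = _table(["S1"] * 15 + ["S2"] * 15, extra={"sex_M": [0, 1] * 15})
    d = rg.build_design(table, ("age", "sex_M"), "S1")
    assert d.matrix.shape == (30, 4)
    assert d.columns == ("S1", "S2", "age", "sex_M")
    # exactly one site indicator per row, covariates mean-centered
    np.testing.assert_array_equal(d.matrix[:, :2].sum(axis=1), 1.0)
    assert abs(d.matrix[:, 2].mean()) < 1e-10
    assert abs(d.matrix[:, 3].mean()) < 1e-10
    # no covariates: pure dummies
    d0 = rg.build_design(table, (), "S1")
    assert d0.matrix.shape == (30, 2)


def test_build_design_rejects_site_collinear_covariate():
    sites = ["S1"] * 4 + ["S2"] * 4
    table = _table(sites, extra={"dup": [0.0] * 4 + [1.0] * 4})
    with pytest.raises(ValueError, match="dup"):
        rg.build_design(table, ("age", "dup"), "S1")


def test_glm_site_betas_equal_group_means_exactly():
    """With a dummies-only design, OLS site coefficients are the per-voxel
    group means; oracle: brute-force per-voxel averages."""
    rng = np.random.default_rng(0)
    table = _table(["S1"] * 5 + ["S2"] * 5)
    feats = _features(rng, 10)
    design = rg.build_design(table, (), "S1")
    betas = rg.fit_rish_glm(feats, design)
    means = rg.fit_site_means(feats, ["S1"] * 5 + ["S2"] * 5)
    for j, site in enumerate(("S1", "S2")):
        oracle = np.mean([f.features for f, s in
                          zip(feats, table.frame["site"]) if s == site],
                         axis=0)
        np.testing.assert_allclose(betas.betas[..., j], oracle, rtol=1e-12)
        np.testing.assert_allclose(means.means[site], oracle, rtol=1e-12)
    # and the two scaling-map estimators coincide
    sg = rg.scaling_from_glm(betas, "S1", "S2")
    sm = rg.scaling_from_means(means, "S1", "S2")
    np.testing.assert_allclose(sg.theta, sm.theta, rtol=1e-10)


def test_glm_recovers_noise_free_coefficients_exactly():
    rng = np.random.default_rng(1)
    table = _table(["S1"] * 6 + ["S2"] * 6,
                   ages=rng.uniform(40, 70, 12))
    design = rg.build_design(table, ("age",), "S1")
    beta_true = rng.random((3, 3, 3, 4, 3)) + 0.5  # grid x orders x columns
    feats = []
    for i in range(12):
        y = np.einsum("...kp,p->...k", beta_true, design.matrix[i])
        feats.append(rg.RISHFeatureImage(y, (0, 2, 4, 6),
                                         np.ones((3, 3, 3), bool), 1000.0))
    betas = rg.fit_rish_glm(feats, design)
    np.testing.assert_allclose(betas.betas, beta_true, rtol=1e-9)
    np.testing.assert_allclose(betas.resid_var, 0.0, atol=1e-18)


def test_glm_age_slope_recovery_with_mild_noise():
    rng = np.random.default_rng(2)
    ages = rng.uniform(30, 70, 30)
    table = _table(["S1"] * 15 + ["S2"] * 15, ages=ages)
    design = rg.build_design(table, ("age",), "S1")
    slope, base = -0.01, 2.0
    feats = []
    for i in range(30):
        centered_age = design.matrix[i, 2]
        y = np.full((2, 2, 2, 4), base + slope * centered_age)
        y += rng.normal(0, 1e-3, y.shape)
        feats.append(rg.RISHFeatureImage(y, (0, 2, 4, 6),
                                         np.ones((2, 2, 2), bool), 1000.0))
    betas = rg.fit_rish_glm(feats, design)
    j_age = betas.columns.index("age")
    assert np.allclose(betas.betas[..., j_age], slope, atol=2e-3)
    # percent effect relative to the adjusted reference mean
    pct = rg.covariate_effect_percent(betas, "age")
    assert np.allclose(pct, 100 * slope / base, atol=0.2)
    with pytest.raises(KeyError):
        rg.covariate_effect_percent(betas, "nope")


def test_scaling_ratio_guard_and_clipping():
    grid = (2, 2, 2)
    orders = (0, 2)
    ref = np.ones(grid + (2,))
    tgt = np.ones(grid + (2,))
    ref[0, 0, 0] = 50.0      # ratio 50 -> clipped to 10
    tgt[1, 1, 1] = 0.0       # zero denominator -> invalid
    means = rg.SiteMeanFeatures({"R": ref, "T": tgt}, orders,
                                np.ones(grid, bool), {"R": 2, "T": 2})
    sc = rg.scaling_from_means(means, "R", "T", clip_bounds=(0.1, 10.0))
    assert not sc.valid[1, 1, 1]
    np.testing.assert_allclose(sc.theta[1, 1, 1], 1.0)
    np.testing.assert_allclose(sc.theta[0, 0, 0], 10.0)
    assert sc.n_clipped[0] == 1


def test_scale_equivariance_of_theta():
    """Multiplying target-site signals by k scales theta by 1/k^2 (energy
    convention); equivalently reference signals by k scales theta by k^2."""
    rng = np.random.default_rng(3)
    sites = ["R"] * 3 + ["T"] * 3
    feats = _features(rng, 6)
    k = 1.7
    scaled = [rg.RISHFeatureImage(f.features * (k ** 2 if s == "T" else 1.0),
                                  f.orders, f.mask, f.bvalue)
              for f, s in zip(feats, sites)]
    base = rg.scaling_from_means(rg.fit_site_means(feats, sites), "R", "T",
                                 clip_bounds=(1e-3, 1e3))
    moved = rg.scaling_from_means(rg.fit_site_means(scaled, sites), "R", "T",
                                  clip_bounds=(1e-3, 1e3))
    np.testing.assert_allclose(moved.theta, base.theta / k ** 2, rtol=1e-10)


def test_one_step_multisite_equals_pairwise_without_covariates(
        tiny_noiseless_cohort):
    cfg, vols, table, truth = tiny_noiseless_cohort
    shells = [rg.select_shell(v, 1000.0) for v in vols]
    one = rg.train(shells, table, rg.TrainConfig("A", "glm", (),
                                                 lambda_reg=0.0))
    pair = rg.train(shells, table, rg.TrainConfig("A", "means",
                                                  lambda_reg=0.0))
    np.testing.assert_allclose(one.scaling["B"].theta,
                               pair.scaling["B"].theta, rtol=1e-10)


def test_training_is_deterministic(tiny_noisy_cohort):
    cfg, vols, table, truth = tiny_noisy_cohort
    shells = [rg.select_shell(v, 1000.0) for v in vols]
    tc = rg.TrainConfig("A", "glm", ("age", "sex_M"), lambda_reg=0.0)
    m1 = rg.train(shells, table, tc)
    m2 = rg.train(shells, table, tc)
    assert np.array_equal(m1.scaling["B"].theta, m2.scaling["B"].theta)


def test_harmonize_reference_passthrough_and_identity_scaling(
        tiny_noiseless_cohort, dirs60):
    cfg, vols, table, truth = tiny_noiseless_cohort
    shells = [rg.select_shell(v, 1000.0) for v in vols]
    model = rg.train(shells, table, rg.TrainConfig("A", "means",
                                                   lambda_reg=0.0))
    # reference subjects are never modified
    out = rg.harmonize_subject(vols[0], model, "A")
    assert out.data is vols[0].data
    # theta == 1 model reduces to the SH projection of the input
    ident = rg.ScalingMaps(np.ones(model.grid_shape + (4,)), model.orders,
                           np.ones(model.grid_shape, bool))
    model.scaling["B"] = ident
    target = vols[len([s for s in table.frame["site"] if s == "A"])]
    harm = rg.harmonize_subject(target, model, "B")
    # phantom shells are band-limited by construction: projection = identity
    np.testing.assert_allclose(harm.data, target.data, rtol=1e-6, atol=1e-8)
    with pytest.raises(KeyError):
        rg.harmonize_subject(target, model, "C")


def test_model_save_load_roundtrip(tmp_path, tiny_noisy_cohort):
    cfg, vols, table, truth = tiny_noisy_cohort
    shells = [rg.select_shell(v, 1000.0) for v in vols]
    tc = rg.TrainConfig("A", "glm", ("age", "sex_M"), lambda_reg=0.0)
    model = rg.train(shells, table, tc)
    rg.save_model(model, tmp_path / "model")
    back = rg.load_model(tmp_path / "model")
    assert back.reference_site == "A"
    assert back.target_sites == ("B",)
    assert back.orders == model.orders
    assert back.method == "glm"
    np.testing.assert_allclose(back.scaling["B"].theta,
                               model.scaling["B"].theta, rtol=1e-6)
    np.testing.assert_array_equal(back.scaling["B"].valid,
                                  model.scaling["B"].valid)
    np.testing.assert_allclose(back.betas.betas, model.betas.betas,
                               rtol=1e-5, atol=1e-7)
    assert back.centering == pytest.approx(model.centering)
    # applying a model on the wrong grid is refused
    small = rg.DwiVolume(vols[0].data[:4, :4, :4], vols[0].affine,
                         vols[0].gradients)
    with pytest.raises(GridMismatchError):
        rg.harmonize_subject(small, back, "B")
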