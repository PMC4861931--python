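"""Positional-analysis tests: projection geometry, Gaussian MLE, ensemble
alignment, EM/BIC clustering (with an independent library cross-check),
and quantile outlier maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ribbonquant import (
    align_ensemble,
    em_cluster,
    fit_gaussian_mle,
    project_to_axes,
    quantile_outlier_map,
)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def test_center_projects_to_origin():
    uv = project_to_axes(
        np.array([[1.0, 2.0, 3.0]]), (1, 2, 3), (0, 1, 0), (1, 0, 0)
    )
    np.testing.assert_allclose(uv, [[0.0, 0.0]])


def test_identity_axes_read_off_coordinates():
    uv = project_to_axes(
        np.array([[0.0, 2.0, 3.0]]), (0, 0, 0), (0, 0, 1), (0, 1, 0)
    )
    np.testing.assert_allclose(uv, [[3.0, 2.0]])


def test_non_orthonormal_axes_rejected():
    with pytest.raises(ValueError):
        project_to_axes(np.zeros((1, 3)), (0, 0, 0), (0, 1, 0), (0, 1, 0))
    with pytest.raises(ValueError):
        project_to_axes(np.zeros((1, 3)), (0, 0, 0), (0, 2, 0), (1, 0, 0))


def test_projection_contracts_pairwise_distances():
    """A rigid projection to a 2D plane never increases pairwise distances
    (1000 random rotations)."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        rot = _random_rotation(rng)
        mp, ch = rot[:, 0], rot[:, 1]
        pts = rng.normal(size=(6, 3)) * 3
        uv = project_to_axes(pts, np.zeros(3), mp, ch)
        d3 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d2 = np.linalg.norm(uv[:, None] - uv[None, :], axis=2)
        assert np.all(d2 <= d3 + 1e-9)


# ---------------------------------------------------------------------------
# Gaussian MLE
# ---------------------------------------------------------------------------


def test_gaussian_mle_degenerate_and_exact_cases():
    pts = np.tile([2.0, -1.0], (4, 1))
    mean, cov = fit_gaussian_mle(pts)
    np.testing.assert_allclose(mean, [2.0, -1.0])
    np.testing.assert_allclose(cov, np.zeros((2, 2)))

    corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    mean, cov = fit_gaussian_mle(corners)
    np.testing.assert_allclose(mean, [0.5, 0.5])
    np.testing.assert_allclose(cov, np.diag([0.25, 0.25]))

    with pytest.raises(ValueError):
        fit_gaussian_mle(np.zeros((2, 2)))


def test_gaussian_mle_monte_carlo_recovery():
    rng = np.random.default_rng(1)
    true_mean = np.array([1.0, -2.0])
    true_cov = np.array([[2.0, 0.6], [0.6, 0.5]])
    n = 4000
    pts = rng.multivariate_normal(true_mean, true_cov, size=n)
    mean, cov = fit_gaussian_mle(pts)
    se_mean = np.sqrt(np.diag(true_cov) / n)
    assert np.all(np.abs(mean - true_mean) < 3 * se_mean)
    # variance-of-variance ~ 2 sigma^4 / n for Gaussian data
    se_var = np.sqrt(2.0 * np.diag(true_cov) ** 2 / n)
    assert np.all(np.abs(np.diag(cov) - np.diag(true_cov)) < 3 * se_var)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _stack_df(rng, n, shift=(0.0, 0.0)):
    pts = rng.normal(size=(n, 2))
    return pd.DataFrame(
        {"u": pts[:, 0] + shift[0], "v": pts[:, 1] + shift[1],
         "volume": rng.uniform(0.05, 0.5, n)}
    )


def test_single_stack_centroid_lands_at_origin():
    rng = np.random.default_rng(2)
    out = align_ensemble({"s1": _stack_df(rng, 12)})
    assert abs(out["u"].mean()) < 1e-9
    assert abs(out["v"].mean()) < 1e-9


def test_alignment_translation_invariant_and_rigid():
    rng = np.random.default_rng(3)
    base = _stack_df(rng, 15)
    shifted = base.copy()
    shifted[["u", "v"]] += [4.2, -1.7]
    out = align_ensemble({"a": base, "b": shifted})
    a = out[out.stack_id == "a"][["u", "v"]].to_numpy()
    b = out[out.stack_id == "b"][["u", "v"]].to_numpy()
    np.testing.assert_allclose(a, b, atol=1e-9)
    # within-stack pairwise distances preserved exactly by translation
    d0 = np.linalg.norm(
        base[["u", "v"]].to_numpy()[:, None] - base[["u", "v"]].to_numpy()[None, :],
        axis=2,
    )
    d1 = np.linalg.norm(a[:, None] - a[None, :], axis=2)
    np.testing.assert_allclose(d0, d1, atol=1e-9)


def test_small_stacks_excluded():
    rng = np.random.default_rng(4)
    out = align_ensemble({"ok": _stack_df(rng, 10), "tiny": _stack_df(rng, 2)})
    assert set(out["stack_id"]) == {"ok"}


# ---------------------------------------------------------------------------
# EM / BIC clustering
# ---------------------------------------------------------------------------


def _two_cluster_data(rng, n=120, sep=3.0, sd=0.5):
    labels = rng.random(n) < 0.5
    pts = rng.normal(scale=sd, size=(n, 2))
    pts[:, 0] += np.where(labels, sep / 2, -sep / 2)
    return pts, labels.astype(int)


def test_bic_selects_two_clusters_when_present():
    rng = np.random.default_rng(5)
    pts, labels = _two_cluster_data(rng, n=150, sep=5.0, sd=0.5)  # 10 sigma
    res = em_cluster(pts, (1, 2, 3), seed=0)
    assert res.k == 2
    acc = max(
        (res.labels == labels).mean(), (res.labels == 1 - labels).mean()
    )
    assert acc >= 0.99


def test_bic_selects_single_cluster_for_unimodal_data():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(150, 2))
    res = em_cluster(pts, (1, 2, 3), seed=0)
    assert res.k == 1


def test_em_loglik_monotone_and_result_valid():
    rng = np.random.default_rng(7)
    pts, _ = _two_cluster_data(rng)
    res = em_cluster(pts, (1, 2, 3), seed=3)
    hist = np.asarray(res.loglik_history)
    assert np.all(np.diff(hist) >= -1e-7 * np.abs(hist[:-1]))
    assert res.weights.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(res.responsibilities.sum(axis=1), 1.0)
    for c in res.covariances:
        np.testing.assert_allclose(c, c.T)
        assert np.all(np.linalg.eigvalsh(c) > 0)
    # BIC parameter count: p = 6k - 1 for full 2D Gaussians
    n = len(pts)
    for k, bic in res.bic_by_k.items():
        assert bic >= -2 * res.loglik_history[-1] - 1e6  # finite sanity
    assert set(res.bic_by_k) == {1, 2, 3}


def test_em_bit_reproducible():
    rng = np.random.default_rng(8)
    pts, _ = _two_cluster_data(rng)
    a = em_cluster(pts, (1, 2, 3), seed=42)
    b = em_cluster(pts, (1, 2, 3), seed=42)
    assert a.bic_by_k == b.bic_by_k
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_array_equal(a.means, b.means)


def test_em_matches_reference_mixture_fit():
    """Our EM reaches the same (or better) log-likelihood as an independent
    full-covariance Gaussian-mixture implementation."""
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(9)
    pts, _ = _two_cluster_data(rng, n=200, sep=4.0)
    res = em_cluster(pts, (2,), seed=1, force_k=2)
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=5, random_state=0,
        tol=1e-8, reg_covar=0.0,
    ).fit(pts)
    ref_ll = gm.score(pts) * len(pts)
    assert res.log_likelihood >= ref_ll - 1e-3
    # same component means up to label swap
    ours = res.means[np.argsort(res.means[:, 0])]
    theirs = gm.means_[np.argsort(gm.means_[:, 0])]
    np.testing.assert_allclose(ours, theirs, atol=0.05)


def test_force_k_overrides_bic():
    rng = np.random.default_rng(10)
    pts = rng.normal(size=(100, 2))
    res = em_cluster(pts, (1, 2, 3), seed=0, force_k=2)
    assert res.k == 2
    assert set(res.bic_by_k) == {1, 2, 3}


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        em_cluster(np.zeros((9, 2)), (1, 2, 3), seed=0)


# ---------------------------------------------------------------------------
# Quantile outliers
# ---------------------------------------------------------------------------


def test_outlier_counting_with_distinct_volumes():
    rng = np.random.default_rng(11)
    df = pd.DataFrame(
        {"u": rng.normal(size=100), "v": rng.normal(size=100),
         "volume": rng.permutation(np.linspace(0.01, 1.0, 100))}
    )
    flags, summary = quantile_outlier_map(df, q=0.9)
    assert flags.sum() == 10
    assert summary["n_outliers"] == 10


def test_equal_volumes_flag_nothing():
    df = pd.DataFrame({"u": np.zeros(20), "v": np.zeros(20), "volume": 0.3})
    flags, _ = quantile_outlier_map(df, q=0.9)
    assert flags.sum() == 0


def test_too_few_points_refused():
    df = pd.DataFrame({"u": np.zeros(5), "v": np.zeros(5), "volume": 0.1})
    with pytest.raises(ValueError):
        quantile_outlier_map(df)
    with pytest.raises(ValueError):
        quantile_outlier_map(
            pd.DataFrame({"u": [0] * 20, "v": [0] * 20, "volume": 0.1}), q=1.5
        )


def test_outliers_localize_where_large_volumes_sit():
    """When large ribbons are placed toward the cuticular pole, the flagged
    set's axial position differs from the rest (rank-sum p < 0.01)."""
    rng = np.random.default_rng(12)
    n = 500
    v_pos = rng.uniform(-3, 3, n)
    # volumes grow toward the cuticular side (negative v here)
    cuticular = v_pos < -1.0
    volume = np.where(
        cuticular, rng.lognormal(np.log(0.45), 0.3, n),
        rng.lognormal(np.log(0.10), 0.3, n),
    )
    df = pd.DataFrame({"u": rng.normal(size=n), "v": v_pos, "volume": volume})
    flags, summary = quantile_outlier_map(df, q=0.9)
    p = mannwhitneyu(
        df["v"][flags], df["v"][~flags], alternative="two-sided"
    ).pvalue
    assert p < 0.01
    assert summary["outlier_mean_v"] < summary["inlier_mean_v"]
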