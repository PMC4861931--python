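"""Deconvolution and segmentation tests: fixed points, flux conservation,
resolution recovery, exhaustive voxel-count oracle, physical-unit
invariants."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import spearmanr

from ribbonquant import PSF, StackMeta, deconvolve, segment_components
from ribbonquant.imaging import _resolve_threshold
from skimage.filters import threshold_otsu

VS = (0.3, 0.08, 0.08)


def _meta(shape, roles=None):
    return StackMeta(voxel_size=VS, shape=shape, channel_roles=roles or {0: "ribbon"})


# ---------------------------------------------------------------------------
# Richardson-Lucy
# ---------------------------------------------------------------------------


def test_flat_stack_is_a_fixed_point():
    flat = np.full((12, 24, 24), 7.0, dtype=np.float32)
    out = deconvolve(flat, PSF(), 10, voxel_size=VS)
    np.testing.assert_allclose(out, flat, rtol=1e-5)


def test_zero_iterations_returns_input():
    rng = np.random.default_rng(0)
    img = rng.poisson(10, size=(6, 16, 16)).astype(np.float32)
    out = deconvolve(img, PSF(), 0, voxel_size=VS)
    np.testing.assert_array_equal(out, img)


def test_output_nonnegative_and_flux_conserved():
    """RL keeps the estimate non-negative and conserves total flux of
    interior sources to within 1%."""
    rng = np.random.default_rng(1)
    img = np.full((16, 40, 40), 2.0, dtype=np.float32)
    img[8, 20, 20] += 500.0
    img[10, 12, 28] += 300.0
    img += rng.normal(0, 0.2, img.shape).astype(np.float32)
    img = np.clip(img, 0, None)
    out = deconvolve(img, PSF(), 25, voxel_size=VS)
    assert out.min() >= 0
    assert abs(out.sum() - img.sum()) / img.sum() < 0.01


def _fwhm(profile, spacing):
    """Full width at half max by linear interpolation around the peak."""
    p = np.asarray(profile, dtype=float)
    p = p - p.min()
    half = p.max() / 2.0
    above = np.nonzero(p >= half)[0]
    lo, hi = above[0], above[-1]

    def frac(i, j):
        return (half - p[i]) / (p[j] - p[i]) if p[j] != p[i] else 0.0

    left = lo - frac(lo, lo - 1) if lo > 0 else lo
    right = hi + frac(hi, hi + 1) if hi < len(p) - 1 else hi
    return (right - left) * spacing


def test_point_source_width_shrinks_monotonically():
    """Deconvolving a PSF-blurred point source sharpens its profile: the
    measured FWHM decreases monotonically with iteration count."""
    psf = PSF()
    truth = np.zeros((24, 48, 48), dtype=np.float32)
    truth[12, 24, 24] = 1000.0
    from scipy.ndimage import gaussian_filter

    blurred = gaussian_filter(truth, psf.sigma_voxels(VS)) + 0.01
    widths = []
    for n_iter in (0, 2, 8, 25):
        out = deconvolve(blurred, psf, n_iter, voxel_size=VS)
        widths.append(_fwhm(out[:, 24, 24], VS[0]))
    assert all(b < a for a, b in zip(widths, widths[1:]))


INNER = (slice(6, 14), slice(8, 40), slice(8, 40))


def test_kernel_psf_path_matches_gaussian_path():
    """Separable-filter and explicit-kernel RL agree away from the stack
    boundary (the two paths handle edges differently)."""
    rng = np.random.default_rng(2)
    img = rng.poisson(4, size=(20, 48, 48)).astype(np.float32)
    img[10, 24, 24] += 200
    psf = PSF()
    a = deconvolve(img, psf, 5, voxel_size=VS)
    b = deconvolve(img, psf.to_kernel(VS), 5)
    assert np.corrcoef(a[INNER].ravel(), b[INNER].ravel())[0, 1] > 0.999


def test_depth_varying_profile_reduces_to_constant_sigma():
    rng = np.random.default_rng(3)
    img = rng.poisson(4, size=(20, 48, 48)).astype(np.float32)
    img[10, 24, 24] += 150
    const = deconvolve(img, PSF(), 5, voxel_size=VS)
    profiled = deconvolve(
        img, PSF(sigma_z_profile=(0.35,) * 20), 5, voxel_size=VS
    )
    np.testing.assert_allclose(
        profiled[INNER], const[INNER], rtol=2e-2, atol=2e-2
    )


def test_invalid_deconvolution_inputs_rejected():
    img = np.ones((4, 8, 8), dtype=np.float32)
    with pytest.raises(ValueError):
        deconvolve(-img, PSF(), 1, voxel_size=VS)
    with pytest.raises(ValueError):
        deconvolve(img, np.zeros((3, 3, 3)), 1)
    with pytest.raises(ValueError):
        deconvolve(img, PSF(), 1)  # parametric PSF needs voxel_size


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def test_empty_and_constant_stacks_give_no_components():
    meta = _meta((6, 10, 10))
    assert segment_components(np.zeros((6, 10, 10)), meta, "ribbon") == []
    assert segment_components(np.full((6, 10, 10), 3.0), meta, "ribbon") == []


def test_threshold_spec_parsing():
    img = np.arange(100.0).reshape(1, 10, 10)
    assert _resolve_threshold(img, "fixed:42") == 42.0
    assert _resolve_threshold(img, ("fixed", 7.0)) == 7.0
    assert _resolve_threshold(img, "quantile:0.5") == pytest.approx(49.5)
    with pytest.raises(ValueError):
        _resolve_threshold(img, "quantile:1.5")
    with pytest.raises(ValueError):
        _resolve_threshold(img, "nope")


def test_two_well_separated_blobs_recovered():
    """Two noise-free blobs 3 µm apart give exactly two components with
    centroids within one voxel of the truth."""
    shape = (20, 80, 80)
    meta = _meta(shape)
    img = np.zeros(shape, dtype=np.float32)
    centers_vox = [(10, 20, 20), (10, 57, 57)]  # ~3 µm apart in xy
    for cz, cy, cx in centers_vox:
        img[cz - 1 : cz + 2, cy - 3 : cy + 4, cx - 3 : cx + 4] = 100.0
    comps = segment_components(img, meta, "ribbon", threshold_method="fixed:50")
    assert len(comps) == 2
    truth = [((c[0] + 0.5) * VS[0], (c[1] + 0.5) * VS[1], (c[2] + 0.5) * VS[2])
             for c in centers_vox]
    for t in truth:
        d = min(
            np.linalg.norm(np.asarray(c.centroid) - np.asarray(t)) for c in comps
        )
        assert d < max(VS)


def test_voxel_count_matches_exhaustive_scan(segmented, rendered, small_scene):
    """Sum of component voxel counts equals an independent brute-force count
    of above-threshold voxels surviving the size filter."""
    stack, meta = rendered
    img = deconvolve(
        stack[0].astype(np.float32), PSF(), 25, voxel_size=meta.voxel_size
    )
    thr = threshold_otsu(img)
    mask = img > thr
    # independent connected-component pass (scipy, explicit 26-structure)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    sizes = np.bincount(labels.ravel())[1:]
    expected = int(sizes[sizes >= 4].sum())
    comps = segment_components(img, meta, "ribbon")
    assert sum(c.voxel_count for c in comps) == expected
    assert len(comps) == int((sizes >= 4).sum())


def test_component_physical_invariants(segmented):
    vox_vol = VS[0] * VS[1] * VS[2]
    for role, comps in segmented.items():
        assert [c.id for c in comps] == list(range(len(comps)))
        for c in comps:
            assert c.volume == pytest.approx(c.voxel_count * vox_vol, rel=1e-9)
            assert c.voxel_count >= 4
            (z0, z1), (y0, y1), (x0, x1) = c.bounding_box
            lo = (z0 * VS[0], y0 * VS[1], x0 * VS[2])
            hi = (z1 * VS[0], y1 * VS[1], x1 * VS[2])
            assert all(l <= v <= h for l, v, h in zip(lo, c.centroid, hi))


def test_segmentation_bit_reproducible(rendered):
    stack, meta = rendered
    img = stack[0].astype(np.float32)
    a = segment_components(img, meta, "ribbon")
    b = segment_components(img, meta, "ribbon")
    assert a == b


def test_detected_count_matches_truth_per_channel(small_scene, segmented):
    """At default noise with resolvable puncta, the per-channel component
    count matches the true synapse count to within a few percent."""
    true_rib = sum(len(c.ribbons) for c in small_scene.cells)
    true_rec = sum(len(c.receptors) for c in small_scene.cells)
    assert abs(len(segmented["ribbon"]) - true_rib) <= max(2, 0.05 * true_rib)
    assert abs(len(segmented["receptor"]) - true_rec) <= max(2, 0.05 * true_rec)


def test_estimated_volumes_track_truth(small_scene, segmented):
    """Estimated component volumes correlate monotonically with true
    volumes (Spearman >= 0.9) at default noise."""
    truths = [
        (np.asarray(r.position), r.volume)
        for c in small_scene.cells
        for r in c.ribbons
    ]
    cents = np.asarray([c.centroid for c in segmented["ribbon"]])
    est, true = [], []
    for pos, vol in truths:
        d = np.sqrt(((cents - pos) ** 2).sum(1))
        k = int(np.argmin(d))
        if d[k] < 0.5:
            est.append(segmented["ribbon"][k].volume)
            true.append(vol)
    assert len(est) > 0.9 * len(truths)
    rho = spearmanr(est, true).statistic
    assert rho >= 0.9
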