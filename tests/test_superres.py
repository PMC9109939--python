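import numpy as np
import pytest
from scipy.stats import spearmanr

from aeslice.dataset import (NormalizedVolume, normalize_volume,
                             plan_slice_removal)
from aeslice.superres import (baseline_interp, enhance_volume,
                              histogram_normalize, interpolate_latent,
                              replace_slice, synthesize_middle, weights_for)


def test_latent_interpolation_identities():
    rng = np.random.default_rng(0)
    z_a, z_b = rng.random((8, 4, 4)), rng.random((8, 4, 4))
    np.testing.assert_array_equal(interpolate_latent(z_a, z_b, 1.0), z_a)
    np.testing.assert_allclose(interpolate_latent(z_a, z_a, 0.3), z_a,
                               rtol=1e-15)
    mid = interpolate_latent(z_a, z_b, 0.5)
    np.testing.assert_allclose(mid, 0.5 * (z_a + z_b))
    # convexity: within the elementwise envelope
    for w in (0.1, 0.5, 0.9):
        out = interpolate_latent(z_a, z_b, w)
        assert np.all(out <= np.maximum(z_a, z_b) + 1e-12)
        assert np.all(out >= np.minimum(z_a, z_b) - 1e-12)


def test_latent_interpolation_errors():
    z = np.zeros((2, 2, 2))
    with pytest.raises(ValueError, match="shape"):
        interpolate_latent(z, np.zeros((2, 2, 3)), 0.5)
    with pytest.raises(ValueError, match="weight"):
        interpolate_latent(z, z, 1.5)


def test_synthesis_weights():
    assert weights_for(1) == (0.5,)
    w2 = weights_for(2)
    # nearer neighbour dominates: slice nearer a takes 2/3 on z_a
    assert w2 == pytest.approx((2 / 3, 1 / 3))
    assert all(0 < w < 1 for w in w2)


def test_histogram_normalize_identity_and_constant():
    rng = np.random.default_rng(1)
    img = rng.random((32, 32)).astype(np.float32)
    out = histogram_normalize(img, img)
    np.testing.assert_allclose(out, img, atol=1 / 255)
    const = np.full((32, 32), 0.42, dtype=np.float32)
    np.testing.assert_allclose(histogram_normalize(img, const), 0.42)


def test_histogram_normalize_matches_quantiles_and_ranks():
    rng = np.random.default_rng(2)
    img = rng.normal(0.5, 0.1, (64, 64)).astype(np.float32)
    ref = rng.beta(2, 5, (64, 64)).astype(np.float32)
    out = histogram_normalize(img, ref)
    q = np.linspace(0, 1, 256)
    np.testing.assert_allclose(np.quantile(out, q), np.quantile(ref, q),
                               atol=1 / 255)
    rho = spearmanr(img.ravel(), out.ravel()).statistic
    assert rho > 0.9999


def test_synthesize_middle_contracts(tiny_model):
    rng = np.random.default_rng(3)
    a = rng.random((32, 32)).astype(np.float32)
    b = rng.random((32, 32)).astype(np.float32)
    # identical inputs: output histogram matches the input's own
    out, = synthesize_middle(tiny_model, a, a, N=1)
    q = np.linspace(0, 1, 256)
    np.testing.assert_allclose(np.quantile(out, q), np.quantile(a, q),
                               atol=1 / 255)
    # N=2: two slices, ordered a-side first, quantiles match the references
    outs = synthesize_middle(tiny_model, a, b, N=2)
    assert len(outs) == 2
    for w, s in zip(weights_for(2), outs):
        ref = w * a + (1 - w) * b
        np.testing.assert_allclose(np.quantile(s, q), np.quantile(ref, q),
                                   atol=1 / 255)
    means = [s.mean() for s in outs]
    refs = [np.mean(w * a + (1 - w) * b) for w in weights_for(2)]
    np.testing.assert_allclose(means, refs, atol=1e-3)


def _toy_normalized(rng, shape=(32, 32, 5, 2)):
    data = rng.random(shape).astype(np.float32)
    return NormalizedVolume(data, np.ones(shape[3]), np.eye(4))


def test_enhance_volume_geometry(tiny_model):
    rng = np.random.default_rng(4)
    nv = _toy_normalized(rng)
    for N in (1, 2):
        out = enhance_volume(tiny_model, nv, N=N)
        assert out.n_slices == 5 + 4 * N
        # originals unmodified at k*(N+1)
        for k in range(5):
            np.testing.assert_array_equal(out.data[:, :, k * (N + 1), :],
                                          nv.data[:, :, k, :])
        np.testing.assert_allclose(out.spacing[2], nv.spacing[2] / (N + 1))


def test_enhance_two_slices_n1(tiny_model):
    rng = np.random.default_rng(5)
    nv = _toy_normalized(rng, (32, 32, 2, 1))
    out = enhance_volume(tiny_model, nv, N=1)
    assert out.n_slices == 3
    expected, = synthesize_middle(tiny_model, nv.data[:, :, 0, 0],
                                  nv.data[:, :, 1, 0], N=1)
    np.testing.assert_array_equal(out.data[:, :, 1, 0], expected)


def test_enhance_then_downsample_is_identity(tiny_model):
    rng = np.random.default_rng(6)
    nv = _toy_normalized(rng)
    for N in (1, 2):
        out = enhance_volume(tiny_model, nv, N=N)
        back = out.data[:, :, ::N + 1, :]
        np.testing.assert_array_equal(back, nv.data)


def test_replace_slice_touches_only_k(tiny_model):
    rng = np.random.default_rng(7)
    nv = _toy_normalized(rng)
    out = replace_slice(tiny_model, nv, 2)
    for k in (0, 1, 3, 4):
        np.testing.assert_array_equal(out.data[:, :, k, :], nv.data[:, :, k, :])
    assert not np.array_equal(out.data[:, :, 2, :], nv.data[:, :, 2, :])
    with pytest.raises(ValueError):
        replace_slice(tiny_model, nv, 0)
    with pytest.raises(ValueError):
        replace_slice(tiny_model, nv, 4)


def test_linear_baseline_equals_neighbor_mean():
    rng = np.random.default_rng(8)
    vol = rng.random((16, 16, 7)).astype(np.float64)
    plan = plan_slice_removal(7, 1)
    pred = baseline_interp(vol, plan, "linear")
    for i, r in enumerate(plan.removed_indices):
        np.testing.assert_allclose(pred[:, :, i],
                                   0.5 * (vol[:, :, r - 1] + vol[:, :, r + 1]),
                                   atol=1e-12)
    # constant neighbours -> constant midpoint
    cvol = np.zeros((4, 4, 3))
    cvol[:, :, 0], cvol[:, :, 2] = 1.0, 3.0
    cpred = baseline_interp(cvol, plan_slice_removal(3, 1), "linear")
    np.testing.assert_allclose(cpred[:, :, 0], 2.0)


@pytest.mark.parametrize("N", [1, 2])
def test_spline5_exact_on_quintic_profiles(N):
    """A degree-5 polynomial through-plane profile is reproduced exactly."""
    Z = 19
    z = np.arange(Z, dtype=np.float64)
    poly = 1.0 + 0.5 * z - 0.2 * z ** 2 + 0.03 * z ** 3 - 1e-3 * z ** 4 \
        + 1e-5 * z ** 5
    vol = np.tile(poly, (4, 4, 1))
    plan = plan_slice_removal(Z, N)
    pred = baseline_interp(vol, plan, "spline5")
    gt = vol[:, :, list(plan.removed_indices)]
    np.testing.assert_allclose(pred, gt, rtol=1e-9, atol=1e-6)


def test_cubic_exact_on_cubic_profiles():
    Z = 9
    z = np.arange(Z, dtype=np.float64)
    poly = 2.0 - z + 0.3 * z ** 2 + 0.01 * z ** 3
    vol = np.tile(poly, (3, 3, 1))
    plan = plan_slice_removal(Z, 1)
    pred = baseline_interp(vol, plan, "cubic")
    np.testing.assert_allclose(pred, vol[:, :, list(plan.removed_indices)],
                               atol=1e-10)


def test_unknown_baseline_method_raises():
    with pytest.raises(ValueError, match="unknown method"):
        baseline_interp(np.zeros((2, 2, 5)), plan_slice_removal(5, 1), "sinc")
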