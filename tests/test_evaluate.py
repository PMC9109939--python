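import itertools
import math

import numpy as np
import pytest

from aeslice.evaluate import (gradient_angle, mse, paired_wilcoxon, psnr,
                              volume_distance)


def test_mse_psnr_closed_forms():
    a = np.zeros((4, 4))
    b = np.ones((4, 4))
    assert mse(a, a) == 0.0
    assert psnr(a, a) == math.inf
    assert mse(a, b) == 1.0
    assert psnr(a, b, peak=1.0) == pytest.approx(0.0)
    c = np.full((4, 4), 0.1)
    assert mse(a, c) == pytest.approx(0.01)
    assert psnr(a, c, peak=1.0) == pytest.approx(20.0)


def test_mse_respects_mask():
    a = np.zeros((2, 2))
    b = np.array([[1.0, 0.0], [0.0, 0.0]])
    m = np.array([[False, True], [True, True]])
    assert mse(a, b) == 0.25
    assert mse(a, b, mask=m) == 0.0


def test_psnr_mse_inverse_monotonicity():
    rng = np.random.default_rng(0)
    a = rng.random((8, 8))
    pairs = [(mse(a, a + eps), psnr(a, a + eps)) for eps in (0.01, 0.05, 0.2)]
    ms, ps = zip(*pairs)
    assert list(ms) == sorted(ms)
    assert list(ps) == sorted(ps, reverse=True)


def test_volume_distance_examples():
    u = np.array([1.0, 2.0, 2.0, 0.0]).reshape(2, 2, 1)
    v = np.array([0.0, 2.0, 2.0, 2.0]).reshape(2, 2, 1)
    assert volume_distance(u, u) == 0.0
    assert volume_distance(u, v) == pytest.approx(np.sqrt(5), abs=1e-12)
    # mean over slices: distances 1 and 3 -> 2
    u2 = np.zeros((1, 1, 2))
    v2 = np.array([[[1.0, 3.0]]])
    assert volume_distance(u2, v2) == pytest.approx(2.0)


def test_volume_distance_vs_brute_force_single_slice():
    rng = np.random.default_rng(1)
    u, v = rng.random((5, 7, 1)), rng.random((5, 7, 1))
    brute = np.linalg.norm((u - v).ravel())
    assert volume_distance(u, v) == pytest.approx(brute)


def test_gradient_angle():
    assert gradient_angle([1, 0, 0], [1, 0, 0]) == pytest.approx(0.0)
    assert gradient_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)
    s = 1 / np.sqrt(2)
    assert gradient_angle([1, 0, 0], [s, s, 0]) == pytest.approx(45.0)
    assert gradient_angle([1, 0, 0], [-1, 0, 0]) == pytest.approx(180.0)
    with pytest.raises(ValueError):
        gradient_angle([0, 0, 0], [1, 0, 0])


def _exact_wilcoxon_enumeration(d):
    """Brute-force two-sided signed-rank p-value over all 2^n sign flips."""
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.asarray(stats)
    w_min = min(w_plus, n * (n + 1) / 2 - w_plus)
    p = np.mean(np.minimum(stats, n * (n + 1) / 2 - stats) <= w_min)
    return p


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_exact_wilcoxon_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    for n in (6, 8, 10):
        x = rng.normal(0.3, 1.0, n)
        y = np.zeros(n)
        res = paired_wilcoxon(x, y)
        assert res["method"] == "exact"
        assert res["pvalue"] == pytest.approx(_exact_wilcoxon_enumeration(x),
                                              abs=1e-12)


def test_wilcoxon_all_zero_differences():
    x = np.ones(8)
    res = paired_wilcoxon(x, x)
    assert res["pvalue"] == 1.0
    assert res["zero_differences"]


def test_wilcoxon_detects_consistent_shift():
    rng = np.random.default_rng(4)
    x = rng.random(20)
    y = x + 0.5 + 0.01 * rng.random(20)
    assert paired_wilcoxon(x, y)["pvalue"] < 1e-4


def test_similarity_rows_count(tiny_model, phantom_dwi):
    from aeslice.dataset import normalize_volume
    from aeslice.evaluate import similarity_analysis
    from aeslice.formats_io import select_shell

    shell = select_shell(phantom_dwi, 700.0, tol=50.0)
    # shrink to a handful of volumes and pad slices to the model size
    small = shell.with_data(shell.data[16:48, 16:48, :, :5],
                            gradients=shell.gradients.subset(np.arange(5)),
                            mask=None)
    rows = similarity_analysis(tiny_model, small)
    assert len(rows) == 5 * 4 // 2
    for r in rows:
        assert 0.0 <= r.angle_deg <= 180.0
        assert r.input_distance >= 0 and r.latent_distance >= 0


def test_removal_experiment_gt_oracle_and_linear(tiny_model):
    from aeslice.dataset import NormalizedVolume
    from aeslice.evaluate import run_removal_experiment

    rng = np.random.default_rng(5)
    data = rng.random((32, 32, 7, 2)).astype(np.float32)
    nv = NormalizedVolume(data, np.ones(2), np.eye(4))
    recs = run_removal_experiment(tiny_model, nv, N=1,
                                  methods=("gt", "linear"))
    from aeslice.dataset import plan_slice_removal
    plan = plan_slice_removal(7, 1)
    for r in recs:
        if r.method == "gt":
            assert r.mse == 0.0 and r.psnr == math.inf
        else:
            v3d = data[:, :, :, r.volume]
            expected = np.mean([
                np.mean((0.5 * (v3d[:, :, k - 1] + v3d[:, :, k + 1])
                         - v3d[:, :, k]) ** 2)
                for k in plan.removed_indices])
            # records average over all removed slices at once
            gt = v3d[:, :, list(plan.removed_indices)]
            pred = np.stack([0.5 * (v3d[:, :, k - 1] + v3d[:, :, k + 1])
                             for k in plan.removed_indices], axis=2)
            assert r.mse == pytest.approx(float(np.mean((pred - gt) ** 2)),
                                          rel=1e-6)


def test_removal_records_invariant_to_volume_order(tiny_model):
    from aeslice.dataset import NormalizedVolume
    from aeslice.evaluate import run_removal_experiment

    rng = np.random.default_rng(6)
    data = rng.random((32, 32, 5, 2)).astype(np.float32)
    nv = NormalizedVolume(data, np.ones(2), np.eye(4))
    nv_swap = NormalizedVolume(data[..., ::-1], np.ones(2), np.eye(4))
    r1 = run_removal_experiment(tiny_model, nv, N=1, methods=("linear",))
    r2 = run_removal_experiment(tiny_model, nv_swap, N=1, methods=("linear",))
    assert r1[0].mse == pytest.approx(r2[1].mse)
    assert r1[1].mse == pytest.approx(r2[0].mse)


def test_weight_grid_is_nine_values(tiny_model):
    from aeslice.evaluate import weight_grid_search

    rng = np.random.default_rng(7)
    a, b = rng.random((32, 32), dtype=np.float32), rng.random((32, 32), dtype=np.float32)
    gt = 0.5 * (a + b)
    res = weight_grid_search(tiny_model, [(a, b, gt)])
    ws = sorted(res["mse_by_weight"])
    np.testing.assert_allclose(ws, np.arange(0.1, 0.95, 0.1), atol=1e-9)
    assert len(ws) == 9
    # argmin consistency with the returned table
    tab = res["mse_by_weight"]
    assert tab[res["best_weight"]] == min(tab.values())
    with pytest.raises(ValueError):
        weight_grid_search(tiny_model, [])
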