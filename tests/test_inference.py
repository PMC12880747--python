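"""Variance partitioning, permutation inference, noise ceilings, ROIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sceneenc.encoding import epoch_and_average
from sceneenc.inference import (
    bh_fdr,
    group_permutation_test,
    noise_ceiling,
    permutation_null_r,
    permutation_null_roi,
    rescale_by_nc,
    select_roi_voxels,
    signed_r2,
    sliding_window,
    variance_partition,
    voxel_count_sweep,
)
from sceneenc.synth import DesignSpec, VoxelPopulationSpec, simulate_voxel_responses
from sceneenc.validation import _null_encoding_result


# -- variance partitioning ---------------------------------------------------


def test_partition_duplicate_model_collapses_to_shared():
    r = np.array([0.5, -0.2, 0.9])
    part = variance_partition(r, r, r)
    assert np.allclose(part.unique_a, 0.0, atol=1e-12)
    assert np.allclose(part.unique_b, 0.0, atol=1e-12)
    assert np.allclose(part.shared, signed_r2(r), atol=1e-12)


@settings(max_examples=200, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
        ),
        min_size=1,
        max_size=8,
    )
)
def test_partition_algebraic_identities(triples):
    ra, rb, rab = (np.array(x) for x in zip(*triples))
    part = variance_partition(ra, rb, rab)
    assert np.allclose(
        part.unique_a + part.unique_b + part.shared, signed_r2(rab), atol=1e-10
    )
    assert np.allclose(part.unique_a + part.shared, signed_r2(ra), atol=1e-10)
    assert np.allclose(part.unique_b + part.shared, signed_r2(rb), atol=1e-10)


def test_partition_recovers_single_source_model():
    """If y is built from model A's features only (B orthogonal noise
    features, noiseless), A explains everything uniquely."""
    from sceneenc.encoding import RidgeConfig, make_folds, nested_cv_predict

    rng = np.random.default_rng(0)
    n_runs, tpr = 8, 40
    run = np.repeat(np.arange(n_runs), tpr)
    task = np.asarray(["scene" if r % 2 == 0 else "dot" for r in run])
    n = n_runs * tpr
    A = rng.standard_normal((n, 5))
    B = rng.standard_normal((n, 5))
    Y = A @ rng.standard_normal((5, 3))
    plan = make_folds(run, task, n_folds=4)
    cfg = RidgeConfig(n_outer_folds=4, n_inner_folds=3)
    rA = nested_cv_predict(A, Y, plan, cfg, run_labels=run).voxel_r
    rB = nested_cv_predict(B, Y, plan, cfg, run_labels=run).voxel_r
    rAB = nested_cv_predict(np.hstack([A, B]), Y, plan, cfg, run_labels=run).voxel_r
    part = variance_partition(rA, rB, rAB)
    assert np.all(part.unique_a > 0.9)
    # unique_B is exactly R2_AB - R2_A = 0 here; shared carries only the
    # noise model's held-out sampling noise.
    assert np.all(np.abs(part.unique_b) < 0.05)
    assert np.all(np.abs(part.shared) < 0.15)


def test_partition_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        variance_partition(np.zeros(3), np.zeros(3), np.zeros(4))


# -- permutation machinery ---------------------------------------------------


def test_identity_permutation_reproduces_observed():
    rng = np.random.default_rng(1)
    res = _null_encoding_result(rng, n_folds=4, n_test=15, n_voxels=6)
    null = permutation_null_r(
        {"m": res}, np.arange(6), n_perm=10, seed=0, identity_first=True
    )["m"]
    assert np.allclose(null[0], res.voxel_r, atol=1e-10)


def test_null_distribution_centered_at_zero():
    rng = np.random.default_rng(2)
    res = _null_encoding_result(rng, n_folds=6, n_test=30, n_voxels=10)
    roi_null = permutation_null_roi(res, np.arange(10), n_perm=400, seed=0)
    assert abs(roi_null.mean()) < 0.01
    assert roi_null.std() > 0


def test_group_test_limits():
    rng = np.random.default_rng(3)
    nulls = rng.standard_normal((5, 200)) * 0.1
    # Observed far beyond every null value -> minimum attainable p.
    p = group_permutation_test(np.full(5, 10.0), nulls)
    assert p == pytest.approx(2.0 / 201.0)
    # Observed at the null median t -> p near 1.
    t_cols = nulls.mean(axis=0) / (nulls.std(axis=0, ddof=1) / np.sqrt(5))
    median_col = int(np.argsort(t_cols)[len(t_cols) // 2])
    p = group_permutation_test(nulls[:, median_col], nulls)
    assert p > 0.95
    with pytest.raises(ValueError):
        group_permutation_test(np.array([1.0]), nulls[:1])


# -- noise ceilings ----------------------------------------------------------


def _repeat_data(rng, n_stim=100, reps=3, n_vox=4, signal_sd=1.0, noise_sd=1.0):
    signal = rng.standard_normal((n_stim, n_vox)) * signal_sd
    labels = np.repeat(np.arange(n_stim), reps)
    y = signal[labels] + rng.standard_normal((n_stim * reps, n_vox)) * noise_sd
    return y, labels


def test_noise_ceiling_limits():
    rng = np.random.default_rng(4)
    y, labels = _repeat_data(rng, noise_sd=1e-9)
    nc = noise_ceiling(y, labels, n_perm=50, seed=0)
    assert np.all(nc.nc > 0.999)  # zero noise -> NC 1
    y, labels = _repeat_data(rng, signal_sd=0.0)
    nc = noise_ceiling(y, labels, n_perm=50, seed=0)
    assert np.all(nc.nc < 0.1)  # zero signal -> NC near 0
    assert np.all(nc.p > 0.05)


def test_noise_ceiling_significance_detects_signal():
    rng = np.random.default_rng(5)
    y, labels = _repeat_data(rng, signal_sd=1.0, noise_sd=1.0)
    nc = noise_ceiling(y, labels, n_perm=200, seed=0)
    assert np.all(nc.p <= 1.0 / 201.0 + 1e-12)


def test_noise_ceiling_requires_repeats():
    rng = np.random.default_rng(6)
    y = rng.standard_normal((10, 2))
    with pytest.raises(ValueError, match="repeat"):
        noise_ceiling(y, np.arange(10), n_perm=10, seed=0)


def test_rescale_by_nc():
    r = np.array([0.2, 0.4])
    nc = np.array([1.0, 0.25])
    out = rescale_by_nc(r, nc, kind="r")
    assert out[0] == pytest.approx(0.2)
    assert out[1] == pytest.approx(0.8)  # r scales by 1/sqrt(NC)
    var = rescale_by_nc(np.array([0.1, 0.1]), nc, kind="variance")
    assert var[1] == pytest.approx(0.4)  # variance scales by 1/NC
    # Positive scaling preserves within-voxel model ordering.
    a, b = np.array([0.3]), np.array([0.2])
    assert rescale_by_nc(a, np.array([0.5]))[0] > rescale_by_nc(b, np.array([0.5]))[0]
    with pytest.raises(ValueError):
        rescale_by_nc(r, np.array([0.5, 0.0]))


# -- ROI selection -----------------------------------------------------------


def test_select_roi_cap_minimum_and_exclusion():
    rng = np.random.default_rng(7)
    stats = rng.standard_normal(300)
    roi = select_roi_voxels(stats, np.ones(300, bool), cap=200, minimum=75)
    assert roi.voxel_idx.size == 200
    # Kept voxels are the strongest; ordered descending by statistic.
    assert np.all(np.diff(stats[roi.voxel_idx]) <= 0)
    assert stats[roi.voxel_idx].min() >= np.sort(stats)[::-1][199]
    # Below the minimum the ROI is dropped.
    small = select_roi_voxels(stats, np.arange(300) < 74, cap=200, minimum=75)
    assert small is None
    # Excluded retinotopic voxels are removed before ranking.
    exclusion = np.zeros(300, bool)
    exclusion[np.argmax(stats)] = True
    roi2 = select_roi_voxels(
        stats, np.ones(300, bool), exclusion_masks=[exclusion], cap=200, minimum=75
    )
    assert np.argmax(stats) not in roi2.voxel_idx


def test_select_roi_nc_filter():
    stats = np.linspace(1, 0, 10)
    nc_p = np.array([0.5, 0.01, 0.01, 0.5, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])
    roi = select_roi_voxels(
        stats, np.ones(10, bool), cap=10, minimum=1, nc_p=nc_p, nc_alpha=0.05
    )
    assert 0 not in roi.voxel_idx and 3 not in roi.voxel_idx


# -- sliding windows and sweeps ----------------------------------------------


def test_sliding_window_count_and_peak_location():
    rng = np.random.default_rng(8)
    design = DesignSpec(n_runs=4, repeats_per_stimulus=2)
    feats = {"gabor": rng.standard_normal((20, 8))}
    pops = [VoxelPopulationSpec(6, "gabor-coded", noise_sd=0.3, weight_seed=1)]
    trials = simulate_voxel_responses(feats, pops, design, seed=0)
    amp = (feats["gabor"] @ trials.true_weights["gabor"].T)[trials.stimulus_idx]

    def corr_with_signal(ds, k):
        from sceneenc.encoding import _pearson_columns

        return float(_pearson_columns(ds.y, amp).mean())

    curves = sliding_window(trials, corr_with_signal, zscore=False)
    assert len(curves) == 10  # 12 TRs, 3-TR windows
    # The injected profile peaks between 2.4 and 4.8 s: windows covering
    # TRs 3-6 should beat the earliest/last windows.
    peak = int(np.argmax(curves))
    assert 2 <= peak <= 5
    assert curves[peak] > curves[0]
    assert curves[peak] > curves[-1]


def test_sliding_window_too_short_epoch():
    design = DesignSpec(n_runs=2, repeats_per_stimulus=1, epoch_len_trs=6)
    rng = np.random.default_rng(9)
    feats = {"gabor": rng.standard_normal((10, 4))}
    pops = [VoxelPopulationSpec(2, "gabor-coded", noise_sd=1.0)]
    trials = simulate_voxel_responses(feats, pops, design, seed=0)
    with pytest.raises(ValueError, match="too short"):
        sliding_window(trials, lambda ds, k: 0.0, n_windows=10)


def test_voxel_count_sweep_matches_brute_force():
    rng = np.random.default_rng(10)
    vals = rng.standard_normal(50)
    stats = rng.standard_normal(50)
    order = np.argsort(-stats, kind="stable")
    curve = voxel_count_sweep(vals, order=order)
    assert curve[0] == pytest.approx(vals[order[0]])
    for n in (1, 7, 50):
        assert curve[n - 1] == pytest.approx(vals[order[:n]].mean(), abs=1e-12)
    assert curve[-1] == pytest.approx(vals.mean())


# -- FDR ---------------------------------------------------------------------


def _brute_force_bh(p, q):
    n = len(p)
    order = np.argsort(p)
    thresh = 0
    for k in range(1, n + 1):
        if p[order[k - 1]] <= q * k / n:
            thresh = k
    reject = np.zeros(n, bool)
    reject[order[:thresh]] = True
    return reject


def test_bh_fdr_cases_and_oracle():
    assert not bh_fdr(np.ones(10), q=0.05).any()
    assert bh_fdr(np.array([0.01]), q=0.05).all()
    rng = np.random.default_rng(11)
    p = rng.random(20) ** 2
    assert np.array_equal(bh_fdr(p, q=0.05), _brute_force_bh(p, 0.05))
    with pytest.raises(ValueError):
        bh_fdr(np.array([-0.1, 0.5]))
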