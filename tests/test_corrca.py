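"""CorrCA core: covariance oracles, eigenproblem, ISC limits, windows."""

import numpy as np
import pytest

from eegisc.containers import CovariancePair
from eegisc.corrca import (
    cohort_isc,
    compute_covariances,
    fit_corrca,
    fit_corrca_videos,
    loo_isc,
    pool_covariances,
    project,
    time_resolved_isc,
    window_grid,
    within_group_isc,
)
from eegisc.synthetic import CohortSpec, generate_cohort

from conftest import make_eeg


def brute_force_covariances(data):
    """Direct double-loop Rb/Rw summation (the definition, O(N^2))."""
    n, d, t = data.shape
    centred = data - data.mean(axis=2, keepdims=True)
    r = np.zeros((n, n, d, d))
    for k in range(n):
        for l in range(n):
            r[k, l] = centred[k] @ centred[l].T / t
    rw = sum(r[k, k] for k in range(n)) / n
    rb = sum(r[k, l] for k in range(n) for l in range(n) if k != l) / (n * (n - 1))
    return rb, rw


class TestCovariances:
    def test_matches_double_loop_oracle(self, rng):
        data = rng.integers(-5, 6, size=(3, 2, 5)).astype(float)
        pair = compute_covariances(make_eeg(data))
        rb, rw = brute_force_covariances(data)
        np.testing.assert_allclose(pair.rb, rb, atol=1e-12)
        np.testing.assert_allclose(pair.rw, rw, atol=1e-12)

    def test_identical_subjects_rb_equals_rw(self, rng):
        x = rng.standard_normal((1, 3, 100))
        data = np.repeat(x, 2, axis=0)
        pair = compute_covariances(make_eeg(data))
        np.testing.assert_allclose(pair.rb, pair.rw, atol=1e-12)

    def test_orthogonal_subjects_rb_zero(self):
        # two subjects whose (zero-mean) channels are exactly orthogonal
        t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        a = np.stack([np.cos(t), np.sin(t)])
        b = np.stack([np.cos(2 * t), np.sin(2 * t)])
        pair = compute_covariances(make_eeg(np.stack([a, b])))
        np.testing.assert_allclose(pair.rb, 0, atol=1e-12)

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_covariances(make_eeg(rng.standard_normal((1, 2, 10))))


class TestPooling:
    def test_single_pair_identity(self, rng):
        m = rng.standard_normal((3, 3))
        pair = CovariancePair(rb=m @ m.T, rw=np.eye(3), n_subjects=2, n_samples=10)
        pooled = pool_covariances([pair])
        np.testing.assert_array_equal(pooled.rb, pair.rb)

    def test_mean_of_pairs(self, rng):
        m = rng.standard_normal((2, 2))
        m = m @ m.T
        p1 = CovariancePair(rb=np.zeros((2, 2)), rw=np.eye(2), n_subjects=2, n_samples=10)
        p2 = CovariancePair(rb=m, rw=3 * np.eye(2), n_subjects=2, n_samples=10)
        pooled = pool_covariances([p1, p2])
        np.testing.assert_allclose(pooled.rb, m / 2)
        np.testing.assert_allclose(pooled.rw, 2 * np.eye(2))

    def test_four_videos_match_arithmetic_oracle(self, rng):
        pairs = []
        mats = []
        for _ in range(4):
            a = rng.standard_normal((3, 3))
            mats.append((a + a.T, np.eye(3) + a @ a.T))
            pairs.append(CovariancePair(rb=mats[-1][0], rw=mats[-1][1], n_subjects=2, n_samples=10))
        pooled = pool_covariances(pairs)
        np.testing.assert_allclose(pooled.rb, np.mean([m[0] for m in mats], axis=0))
        np.testing.assert_allclose(pooled.rw, np.mean([m[1] for m in mats], axis=0))

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            pool_covariances([])
        p2 = CovariancePair(rb=np.eye(2), rw=np.eye(2), n_subjects=2, n_samples=5)
        p3 = CovariancePair(rb=np.eye(3), rw=np.eye(3), n_subjects=2, n_samples=5)
        with pytest.raises(ValueError):
            pool_covariances([p2, p3])


def random_search_ratio(rb, rw, n_dirs=100_000, seed=0):
    """Independent maximization oracle: best w'Rb w / w'Rw w over random w.

    Staged random search: half the budget samples directions globally, the
    rest perturbs the incumbent with shrinking radius.  No eigendecomposition
    involved.
    """
    rng = np.random.default_rng(seed)

    def ratios(w):
        num = np.einsum("dn,de,en->n", w, rb, w)
        den = np.einsum("dn,de,en->n", w, rw, w)
        return num / den

    d = rb.shape[0]
    w = rng.standard_normal((d, n_dirs // 2))
    r = ratios(w)
    best = w[:, np.argmax(r)] / np.linalg.norm(w[:, np.argmax(r)])
    best_r = r.max()
    n_local = n_dirs // 8
    for radius in (0.3, 0.1, 0.03, 0.01):
        w = best[:, None] + radius * rng.standard_normal((d, n_local))
        r = ratios(w)
        if r.max() > best_r:
            best_r = r.max()
            best = w[:, np.argmax(r)] / np.linalg.norm(w[:, np.argmax(r)])
    return best_r


class TestFitCorrCA:
    def test_identity_case(self):
        pair = CovariancePair(rb=np.eye(3), rw=np.eye(3), n_subjects=2, n_samples=10)
        model = fit_corrca(pair, shrinkage=0.0)
        np.testing.assert_allclose(model.eigenvalues, 1.0, atol=1e-12)

    def test_diagonal_closed_form(self):
        pair = CovariancePair(
            rb=np.diag([0.8, 0.2]), rw=np.eye(2), n_subjects=2, n_samples=10
        )
        model = fit_corrca(pair, shrinkage=0.0)
        np.testing.assert_allclose(model.eigenvalues, [0.8, 0.2], atol=1e-12)
        np.testing.assert_allclose(np.abs(model.w), np.eye(2), atol=1e-9)

    def test_leading_ratio_matches_random_search(self, rng):
        for trial in range(3):
            a = rng.standard_normal((4, 4))
            rw = a @ a.T + 4 * np.eye(4)
            b = rng.standard_normal((4, 4))
            rb = b @ b.T
            pair = CovariancePair(rb=rb, rw=rw, n_subjects=2, n_samples=10)
            model = fit_corrca(pair, shrinkage=0.0)
            oracle = random_search_ratio(rb, rw, seed=trial)
            assert model.eigenvalues[0] >= oracle - 1e-12
            assert model.eigenvalues[0] == pytest.approx(oracle, abs=1e-3)

    def test_eigenvalues_descending_and_signs_fixed(self, rng):
        a = rng.standard_normal((5, 5))
        pair = CovariancePair(
            rb=a @ a.T, rw=np.eye(5) + 0.1 * a @ a.T, n_subjects=2, n_samples=10
        )
        model = fit_corrca(pair, shrinkage=0.05)
        assert (np.diff(model.eigenvalues) <= 1e-12).all()
        for j in range(model.n_components):
            assert model.a[np.argmax(np.abs(model.a[:, j])), j] > 0

    def test_singular_rw_needs_shrinkage(self):
        rw = np.diag([1.0, 0.0])
        pair = CovariancePair(rb=np.eye(2), rw=rw, n_subjects=2, n_samples=10)
        with pytest.raises(np.linalg.LinAlgError):
            fit_corrca(pair, shrinkage=0.0)
        model = fit_corrca(pair, shrinkage=0.1)  # regularized: fine
        assert model.n_components == 2

    def test_k_bounds(self):
        pair = CovariancePair(rb=np.eye(2), rw=np.eye(2), n_subjects=2, n_samples=10)
        with pytest.raises(ValueError):
            fit_corrca(pair, k=3)


class TestProjection:
    def test_axis_vector_selects_channel(self, rng):
        from eegisc.containers import CorrCAModel

        data = rng.standard_normal((2, 3, 20))
        w = np.array([[1.0], [0.0], [0.0]])
        model = CorrCAModel(w=w, eigenvalues=np.array([1.0]), a=w, shrinkage=0.0)
        proj = project(make_eeg(data), model)
        np.testing.assert_array_equal(proj[:, 0, :], data[:, 0, :])

    def test_zero_data_zero_projection(self):
        from eegisc.containers import CorrCAModel

        w = np.ones((2, 2))
        model = CorrCAModel(w=w, eigenvalues=np.ones(2), a=w, shrinkage=0.0)
        proj = project(make_eeg(np.zeros((2, 2, 5))), model)
        assert (proj == 0).all()

    def test_dimension_mismatch_rejected(self, rng):
        from eegisc.containers import CorrCAModel

        w = np.ones((4, 1))
        model = CorrCAModel(w=w, eigenvalues=np.ones(1), a=w, shrinkage=0.0)
        with pytest.raises(ValueError):
            project(make_eeg(rng.standard_normal((2, 3, 5))), model)


class TestLooISC:
    def test_identical_target_gives_one(self, rng):
        x = rng.standard_normal((1, 2, 50))
        proj = np.repeat(x, 4, axis=0)
        isc = loo_isc(proj, 0, [0, 1, 2, 3])
        np.testing.assert_allclose(isc, 1.0, atol=1e-12)

    def test_orthogonal_target_gives_zero(self):
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        target = np.stack([np.cos(t)])
        refs = np.stack([np.stack([np.sin(t)]), np.stack([np.cos(2 * t)])])
        proj = np.concatenate([target[None], refs])
        isc = loo_isc(proj, 0, [1, 2])
        np.testing.assert_allclose(isc, 0.0, atol=1e-12)

    def test_mean_of_pairwise_pearson_oracle(self):
        # printed toy vectors, T=6; oracle = hand/numpy Pearson mean
        target = np.array([[1.0, 3.0, 2.0, 5.0, 4.0, 6.0]])
        refs = np.array(
            [
                [[2.0, 3.0, 1.0, 4.0, 6.0, 5.0]],
                [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
                [[6.0, 5.0, 4.0, 3.0, 2.0, 1.0]],
            ]
        )
        proj = np.concatenate([target[None], refs])
        expected = np.mean(
            [np.corrcoef(target[0], refs[r, 0])[0, 1] for r in range(3)]
        )
        isc = loo_isc(proj, 0, [1, 2, 3])
        assert isc[0] == pytest.approx(expected, abs=1e-12)

    def test_reference_excludes_target(self, rng):
        proj = rng.standard_normal((3, 1, 30))
        with_self = loo_isc(proj, 0, [0, 1, 2])
        without = loo_isc(proj, 0, [1, 2])
        np.testing.assert_allclose(with_self, without)
        with pytest.raises(ValueError):
            loo_isc(proj, 0, [0])

    def test_subject_permutation_invariance(self, small_cohort):
        _, videos, _ = small_cohort
        model = fit_corrca_videos(videos)
        isc = cohort_isc(videos, model)
        perm = np.arange(videos[0].n_subjects)[::-1]
        videos_p = [v.subset_subjects(perm) for v in videos]
        isc_p = cohort_isc(videos_p, model)
        np.testing.assert_allclose(isc.topk_sum[perm], isc_p.topk_sum, atol=1e-9)

    def test_subject_scale_invariance(self, small_cohort):
        _, videos, _ = small_cohort
        model = fit_corrca_videos(videos)
        isc = cohort_isc(videos, model)
        scaled = [v.copy() for v in videos]
        for v in scaled:
            v.data[2] *= 7.3   # healthy subject, not in its own reference pairs
        isc_s = cohort_isc(scaled, model)
        assert isc_s.topk_sum[2] == pytest.approx(isc.topk_sum[2], abs=1e-9)


class TestWithinGroupISC:
    def test_shared_source_group_positive(self):
        spec = CohortSpec(
            n_healthy=0, n_patient=8, gain_patient=0.8, duration=8,
            n_videos=1, seed=11,
        )
        videos, _ = generate_cohort(spec)
        isc = within_group_isc(videos, "patient")
        assert (isc.topk_sum > 0).all()

    def test_too_few_members_rejected(self, rng):
        videos = [make_eeg(rng.standard_normal((2, 3, 100)))]
        with pytest.raises(ValueError):
            within_group_isc(videos, "healthy")


class TestWindowedISC:
    def test_grid_arithmetic(self):
        grid = window_grid(6.0, 1.5, 0.3)
        assert grid.shape[0] == int(np.floor((6.0 - 1.5) / 0.3)) + 1 == 16
        np.testing.assert_allclose(grid[0], [0.0, 1.5])
        np.testing.assert_allclose(grid[1, 0], 0.3)

    def test_sample_counts_at_500hz(self, small_cohort):
        _, videos, _ = small_cohort
        model = fit_corrca_videos(videos)
        win = time_resolved_isc(videos[0], model, window_length=1.5, overlap=1.2)
        assert int(round(win.window_length * videos[0].fs)) == 750
        assert int(round(win.step * videos[0].fs)) == 150
        expected = int(np.floor((videos[0].duration - 1.5) / 0.3 + 1e-9)) + 1
        assert win.n_windows == expected

    def test_stationary_mean_tracks_whole_recording(self):
        spec = CohortSpec(n_healthy=8, n_patient=0, duration=30, n_videos=1, seed=21)
        videos, _ = generate_cohort(spec)
        model = fit_corrca_videos(videos)
        whole = cohort_isc(videos, model)
        win = time_resolved_isc(videos[0], model, window_length=1.5, overlap=1.2)
        mean_c1 = np.nanmean(win.values[:, :, 0])
        assert mean_c1 == pytest.approx(np.nanmean(whole.values[:, 0, 0]), abs=0.05)

    def test_alternative_window_lengths_run(self, small_cohort):
        _, videos, _ = small_cohort
        model = fit_corrca_videos(videos)
        for wl in (0.2, 0.5, 0.8, 1.0, 2.0, 5.0):
            win = time_resolved_isc(videos[0], model, window_length=wl, overlap=wl * 0.8)
            assert win.n_windows >= 1

    def test_mostly_zero_window_missing(self, small_cohort):
        _, videos, _ = small_cohort
        v = videos[0].copy()
        v.data[0, :, :750] = 0.0    # first window fully blank for subject 0
        model = fit_corrca_videos([v])
        win = time_resolved_isc(v, model, window_length=1.5, overlap=1.2)
        assert np.isnan(win.values[0, 0]).all()
        assert not np.isnan(win.values[1, 0]).any()
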