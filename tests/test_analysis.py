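"""Separation statistics, overlap probability, bootstrap C, PCA, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import facesculpt as fs
from facesculpt.analysis import (
    bootstrap_correlation,
    cross_experiment_offset,
    empirical_p12,
    gaussian_p12,
    group_coordinate_test,
    pca_decompose,
    project_pcs,
    separation_stats,
)
from facesculpt.schema import DISTANCE_COLUMNS, standardize

D = 11


def _dataset(f, subjects):
    df = pd.DataFrame(f, columns=DISTANCE_COLUMNS)
    df.insert(0, "member", 0)
    df.insert(0, "generation", 10)
    df.insert(0, "replicate", 0)
    df.insert(0, "subject_id", subjects)
    df.insert(0, "experiment_id", "E1")
    return standardize(df)


class TestSeparationStats:
    def test_identical_sets_give_t_zero_and_half_overlap(self):
        x = [1.0, 2.0, 3.0, 4.0]
        s = separation_stats(x, x)
        assert s.t == pytest.approx(0.0)
        assert s.gaussian_p12 == pytest.approx(0.5)

    def test_closed_form_t(self):
        # mu_i = 2, mu_sc = 1, sigma_i = sigma_sc = 1 -> t = 1/sqrt(2)
        inter = [1.0, 2.0, 3.0]  # mean 2, sd 1
        sc = [0.0, 1.0, 2.0]  # mean 1, sd 1
        s = separation_stats(inter, sc)
        assert s.t == pytest.approx(1 / np.sqrt(2))
        assert s.mu_i == pytest.approx(2.0)
        assert s.sigma_sc == pytest.approx(1.0)

    def test_gaussian_p12_is_increasing_and_anchored(self):
        assert gaussian_p12(0.0) == pytest.approx(0.5)
        ts = np.linspace(-2, 2, 9)
        ps = [gaussian_p12(t) for t in ts]
        assert np.all(np.diff(ps) > 0)

    def test_counts_and_standard_errors(self):
        rng = np.random.default_rng(0)
        inter, sc = rng.normal(2, 1, 100), rng.normal(1, 1, 30)
        s = separation_stats(inter, sc)
        assert (s.n_i, s.n_sc) == (100, 30)
        assert s.se_i == pytest.approx(s.sigma_i / 10)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            separation_stats([1.0], [1.0, 2.0])


class TestEmpiricalP12:
    def test_identical_sets_give_half(self):
        x = np.arange(10.0)
        assert empirical_p12(x, x) == pytest.approx(0.5)

    def test_fully_separated_sets_give_one(self):
        assert empirical_p12([1.0, 2.0], [5.0, 6.0]) == pytest.approx(1.0)

    def test_matches_gaussian_overlap_on_synthetic_sets(self):
        # two Gaussians built so that t = 0.82 -> P(same < diff) = Phi(0.82)
        rng = np.random.default_rng(1)
        t = 0.82
        same = rng.normal(0.0, 1.0, 2000)
        diff = rng.normal(t * np.sqrt(2), 1.0, 2000)
        p = empirical_p12(same, diff, rng)
        assert p == pytest.approx(gaussian_p12(t), abs=0.02)

    def test_monte_carlo_branch_agrees_with_exhaustive(self):
        rng = np.random.default_rng(2)
        same = rng.normal(0, 1, 900)
        diff = rng.normal(1, 1, 1200)  # 1.08e6 pairs -> MC branch
        exact = (same[:, None] < diff[None, :]).mean()
        p = empirical_p12(same, diff, np.random.default_rng(3), n_samples=200_000)
        assert p == pytest.approx(exact, abs=0.01)


class TestBootstrapCorrelation:
    def test_perfectly_coupled_coordinates(self, rng):
        f = rng.normal(0.3, 0.05, size=(60, D))
        f[:, 2] = f[:, 1]  # y_2 == y_1
        ds = _dataset(f, subjects=np.arange(60))
        res = bootstrap_correlation(ds, B=200, rng=rng)
        assert res.C[1, 2] == pytest.approx(1.0, abs=1e-9)

    def test_independent_coordinates_stay_within_sampling_bound(self, rng):
        S = 200
        f = rng.normal(0.3, 0.05, size=(S, D))
        ds = _dataset(f, subjects=np.arange(S))
        res = bootstrap_correlation(ds, B=300, rng=rng)
        off = res.C[~np.eye(D, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(S)

    def test_one_vector_per_subject_kills_within_subject_correlation(self, rng):
        # two coordinates correlated *within* each subject's population but
        # independent across subjects must show no correlation
        S, n = 50, 20
        rows, subjects = [], []
        for s in range(S):
            base = rng.normal(0.3, 0.05, D)
            within = rng.normal(0, 0.02, n)
            block = np.tile(base, (n, 1))
            block[:, 3] += within
            block[:, 5] += within  # coupled only within the subject
            rows.append(block)
            subjects.extend([s] * n)
        ds = _dataset(np.vstack(rows), subjects=np.array(subjects))
        res = bootstrap_correlation(ds, B=300, rng=rng)
        assert abs(res.C[3, 5]) < 3 / np.sqrt(S)

    def test_symmetry_and_unit_diagonal(self, rng):
        f = rng.normal(0.3, 0.05, size=(40, D))
        ds = _dataset(f, subjects=np.arange(40))
        res = bootstrap_correlation(ds, B=150, rng=rng)
        assert np.allclose(res.C, res.C.T)
        assert np.allclose(np.diag(res.C), 1.0)
        assert np.all((res.p >= 0) & (res.p <= 1))

    def test_requires_enough_realizations_and_subjects(self, rng):
        f = rng.normal(0.3, 0.05, size=(40, D))
        ds = _dataset(f, subjects=np.arange(40))
        with pytest.raises(ValueError):
            bootstrap_correlation(ds, B=10, rng=rng)
        one = _dataset(f[:5], subjects=np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            bootstrap_correlation(one, B=100, rng=rng)


class TestPCA:
    def test_diagonal_matrix_gives_axes_and_sorted_eigenvalues(self):
        C = np.diag([3.0, 1.0, 2.0])
        res = pca_decompose(C)
        assert np.allclose(res.eigenvalues, [1.0, 2.0, 3.0])
        assert np.allclose(np.abs(res.E), np.eye(3)[[1, 2, 0]])

    def test_two_by_two_closed_form(self):
        res = pca_decompose(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert np.allclose(res.eigenvalues, [0.0, 2.0], atol=1e-12)
        assert np.allclose(res.E[1], [1, 1] / np.sqrt(2))

    def test_diagonalization_and_orthonormality(self, rng):
        A = rng.normal(size=(D, D))
        C = A @ A.T
        res = pca_decompose(C)
        assert np.allclose(res.E @ C @ res.E.T, np.diag(res.eigenvalues), atol=1e-9)
        assert np.allclose(res.E @ res.E.T, np.eye(D), atol=1e-12)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(C))

    def test_sign_convention_deterministic(self, rng):
        C = np.cov(rng.normal(size=(50, 4)), rowvar=False)
        a, b = pca_decompose(C), pca_decompose(C)
        assert np.array_equal(a.E, b.E)
        for row in a.E:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constraint_null_space_shows_up_as_zero_eigenvalue(self, schema, rng):
        # raw distance vectors obey sum(d_1..d_4) = 1, so their covariance
        # has a null eigenvector with equal weights on the four segments
        faces = np.stack(
            [
                fs.project_to_constraint(
                    rng.uniform(schema.lo, schema.hi), schema
                ).d
                for _ in range(300)
            ]
        )
        C = np.cov(faces, rowvar=False)
        res = pca_decompose(C)
        assert res.eigenvalues[0] == pytest.approx(0.0, abs=1e-12)
        e0 = res.E[0]
        expected = np.zeros(D)
        expected[[1, 2, 3, 4]] = 0.5
        assert np.allclose(np.abs(e0), expected, atol=1e-6)

    def test_projections_are_uncorrelated_with_eigenvalue_variance(self, rng):
        y = rng.normal(size=(500, D))
        y -= y.mean(axis=0)
        C = (y.T @ y) / len(y)
        res = pca_decompose(C)
        yp = project_pcs(y, res)
        cov = (yp.T @ yp) / len(y)
        assert np.allclose(cov, np.diag(res.eigenvalues), atol=1e-9)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            pca_decompose(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestGroupTests:
    def _two_groups(self, rng, offset=None, n=30):
        fa = rng.normal(0.3, 0.05, size=(n, D))
        fb = rng.normal(0.3, 0.05, size=(n, D))
        if offset is not None:
            fb = fb + offset
        return (
            _dataset(fa, subjects=np.arange(n)),
            _dataset(fb, subjects=np.arange(n)),
        )

    def test_label_swap_negates_t(self, rng):
        a, b = self._two_groups(rng)
        r1 = group_coordinate_test(a, b)
        r2 = group_coordinate_test(b, a)
        assert np.allclose(r1.t, -r2.t)
        assert np.allclose(r1.p, r2.p)

    def test_planted_offset_flagged_on_right_coordinate(self, rng):
        off = np.zeros(D)
        off[9] = 0.05  # +1 sd on the nose width
        a, b = self._two_groups(rng, offset=off, n=40)
        res = group_coordinate_test(a, b)
        assert res.p[9] < 1e-4
        assert np.sum(res.p[np.arange(D) != 9] < 0.05) <= 2

    def test_null_split_false_positive_rate(self, rng):
        hits, total = 0, 0
        for _ in range(30):
            a, b = self._two_groups(rng)
            res = group_coordinate_test(a, b)
            hits += (res.p < 0.05).sum()
            total += D
        assert 0.0 <= hits / total < 0.12  # ~5% nominal

    def test_benjamini_hochberg_adjustment_is_monotone_and_conservative(self, rng):
        a, b = self._two_groups(rng)
        raw = group_coordinate_test(a, b)
        adj = group_coordinate_test(a, b, adjust="bh")
        assert np.all(adj.p >= raw.p - 1e-15)
        assert np.allclose(adj.p, stats.false_discovery_control(raw.p))

    def test_per_pc_mode(self, rng):
        a, b = self._two_groups(rng)
        pca = pca_decompose(np.eye(D))
        res = group_coordinate_test(a, b, per="pc", pca=pca)
        assert len(res.p) == D
        assert res.labels[0] == "pc_0"

    def test_pooled_variance_option_matches_scipy(self, rng):
        a, b = self._two_groups(rng)
        res = group_coordinate_test(a, b, equal_var=True)
        fa = a.records[DISTANCE_COLUMNS].to_numpy(dtype=float)
        fb = b.records[DISTANCE_COLUMNS].to_numpy(dtype=float)
        pooled = np.vstack([fa, fb])
        ya = (fa - pooled.mean(0)) / pooled.std(0, ddof=1)
        yb = (fb - pooled.mean(0)) / pooled.std(0, ddof=1)
        A = np.stack([ya[v].mean(axis=0) for v in a.subject_groups().values()])
        B = np.stack([yb[v].mean(axis=0) for v in b.subject_groups().values()])
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=True)
        assert np.allclose(res.t, t)


class TestCrossExperimentOffset:
    def test_same_dataset_has_zero_offset(self, rng):
        f = rng.normal(0.3, 0.05, size=(40, D))
        ds = _dataset(f, subjects=np.arange(40))
        res = cross_experiment_offset(ds, ds)
        assert np.allclose(res["offset"], 0.0, atol=1e-12)

    def test_planted_shift_recovered(self, rng):
        fa = rng.normal(0.3, 0.01, size=(80, D))
        fb = rng.normal(0.3, 0.01, size=(80, D))
        fb[:, 2] += 0.02
        a = _dataset(fa, subjects=np.arange(80))
        b = _dataset(fb, subjects=np.arange(80))
        res = cross_experiment_offset(a, b)
        assert res["offset"]["d_2"] == pytest.approx(-0.02, abs=3 * res["se"]["d_2"])
        others = res.drop(index="d_2")
        assert np.all(np.abs(others["offset"]) < 4 * others["se"])

    def test_standard_error_halves_when_sizes_quadruple(self, rng):
        def se_for(S):
            fa = rng.normal(0.3, 0.01, size=(S, D))
            fb = rng.normal(0.3, 0.01, size=(S, D))
            a = _dataset(fa, subjects=np.arange(S))
            b = _dataset(fb, subjects=np.arange(S))
            return cross_experiment_offset(a, b)["se"].mean()

        assert se_for(400) == pytest.approx(se_for(100) / 2, rel=0.2)
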