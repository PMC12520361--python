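"""Tests for preprocessing, CMD embedding, circle fit, time inference,
moving statistics, boundaries, BH-FDR and robustness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cycletime import pseudotime as pt


def _table(values, markers=None, add_meta=True):
    markers = markers or [f"m{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, columns=markers)
    if add_meta:
        df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
        df.insert(1, "condition", "untreated")
    return df


class TestPreprocess:
    def test_identical_cells_zero_variance_error(self):
        tab = _table(np.ones((5, 3)))
        with pytest.raises(ValueError, match="zero-variance"):
            pt.preprocess(tab)

    def test_two_cells_give_plus_minus_one(self):
        tab = _table(np.array([[1.0, 5.0], [10.0, 2.0]]))
        mm = pt.preprocess(tab)
        np.testing.assert_allclose(np.abs(mm.values), 1.0)

    def test_lognormal_becomes_gaussian(self):
        rng = np.random.default_rng(0)
        vals = np.column_stack([rng.lognormal(0, 0.5, 200),
                                rng.lognormal(1, 0.3, 200)])
        mm = pt.preprocess(_table(vals))
        for j in range(2):
            assert stats.shapiro(mm.values[:, j]).pvalue > 0.01

    def test_nonpositive_floored(self):
        vals = np.array([[0.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        mm = pt.preprocess(_table(vals))
        assert np.isfinite(mm.values).all()

    def test_hidden_and_meta_columns_excluded(self):
        tab = _table(np.random.default_rng(1).lognormal(0, 1, (10, 3)))
        tab["__true_phase"] = 0.5
        mm = pt.preprocess(tab)
        assert mm.marker_names == ["m0", "m1", "m2"]


class TestCmdEmbed:
    def test_recovers_square_through_isometry(self):
        """Unit-square corners rigidly embedded in 5-D come back exactly."""
        rng = np.random.default_rng(2)
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        basis, _ = np.linalg.qr(rng.normal(size=(5, 2)))
        high = square @ basis.T + rng.normal(size=5)  # isometry + offset
        coords = pt.cmd_embed(high)
        d_in = np.linalg.norm(square[:, None] - square[None], axis=2)
        d_out = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        np.testing.assert_allclose(d_out, d_in, atol=1e-8)

    def test_gram_matches_dense_eigendecomposition_oracle(self):
        """Dual route: dense eigh of the double-centred -D^2/2 matrix."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        coords = pt.cmd_embed(X)
        D2 = ((X[:, None] - X[None]) ** 2).sum(axis=2)
        n = X.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        w, V = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:2]
        oracle = V[:, idx] * np.sqrt(w[idx])
        got = coords.T @ coords
        want = oracle.T @ oracle
        np.testing.assert_allclose(coords @ coords.T, oracle @ oracle.T,
                                   atol=1e-8)
        np.testing.assert_allclose(np.sort(np.diag(got)),
                                   np.sort(np.diag(want)), rtol=1e-8)

    def test_invariant_to_marker_permutation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        a = pt.cmd_embed(X)
        b = pt.cmd_embed(X[:, ::-1])
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_invariant_to_column_shift(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 5))
        Y = X.copy()
        Y[:, 2] += 7.5
        np.testing.assert_allclose(pt.cmd_embed(X), pt.cmd_embed(Y), atol=1e-8)

    def test_degenerate_raises(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10)  # rank 1
        with pytest.raises(ValueError):
            pt.cmd_embed(X)


class TestFitCircle:
    def test_exact_on_noiseless_circle(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        coords = np.column_stack([1 + 3 * np.cos(th), -2 + 3 * np.sin(th)])
        center, radius = pt.fit_circle(coords)
        np.testing.assert_allclose(center, [1, -2], atol=1e-10)
        assert radius == pytest.approx(3.0, abs=1e-10)

    def test_noisy_circle_center_error(self):
        """Monte Carlo over 100 seeds: center error below the noise scale."""
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            coords = np.column_stack([3 * np.cos(th), 3 * np.sin(th)])
            coords += rng.normal(0, 0.03, coords.shape)  # sigma = 0.01 * r
            center, _ = pt.fit_circle(coords)
            errs.append(np.linalg.norm(center))
        assert np.mean(errs) < 0.01 * 3.0

    def test_three_points_circumcircle_oracle(self):
        """Closed-form circumcenter of a triangle."""
        A, B, C = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
        d = 2 * (A[0] * (B[1] - C[1]) + B[0] * (C[1] - A[1])
                 + C[0] * (A[1] - B[1]))
        ux = ((A @ A) * (B[1] - C[1]) + (B @ B) * (C[1] - A[1])
              + (C @ C) * (A[1] - B[1])) / d
        uy = ((A @ A) * (C[0] - B[0]) + (B @ B) * (A[0] - C[0])
              + (C @ C) * (B[0] - A[0])) / d
        center, radius = pt.fit_circle(np.vstack([A, B, C]))
        np.testing.assert_allclose(center, [ux, uy], atol=1e-9)
        assert radius == pytest.approx(np.linalg.norm(A - [ux, uy]), abs=1e-9)

    def test_collinear_raises(self):
        coords = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            pt.fit_circle(coords)


class TestAngles:
    def test_mirrored_coords_same_angles(self, embedded):
        mm, coords = embedded["mm"], embedded["coords"]
        mirrored = coords.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        circle_m = pt.fit_circle(mirrored)
        emb_m = pt.angles(mirrored, circle_m, mm)
        emb = pt.angles(coords, embedded["circle"], mm)
        # orientation rule resolves the reflection: angles agree up to a
        # global rotation
        delta = (emb_m.angle - emb.angle) % (2 * np.pi)
        spread = stats.circstd(delta)
        assert spread < 0.05

    def test_angle_tracks_true_phase(self, embedded):
        tab = embedded["tab"]
        corr = pt.circular_corr(embedded["emb"].angle,
                                tab["__true_phase"].to_numpy() * 2 * np.pi)
        assert corr >= 0.9

    def test_missing_cyclins_need_override(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        mm = pt.MarkerMatrix(X, ["a", "b", "c"], np.arange(50))
        coords = pt.cmd_embed(X)
        circle = pt.fit_circle(coords)
        with pytest.raises(ValueError, match="orientation"):
            pt.angles(coords, circle, mm)
        emb = pt.angles(coords, circle, mm, orientation_override=False)
        assert emb.angle.shape == (50,)


class TestErgodicTimes:
    def test_four_cell_example(self):
        emb = pt.CircularEmbedding(coords=np.zeros((4, 2)),
                                   center=np.zeros(2), radius=1.0,
                                   angle=np.array([2.0, 0.1, 6.0, 4.0]))
        asn = pt.ergodic_times(emb, T=24.0)
        np.testing.assert_allclose(asn.time, [6.0, 0.0, 18.0, 12.0])

    def test_uniform_marginal_by_construction(self):
        rng = np.random.default_rng(7)
        emb = pt.CircularEmbedding(coords=np.zeros((100, 2)),
                                   center=np.zeros(2), radius=1.0,
                                   angle=rng.uniform(0, 2 * np.pi, 100))
        asn = pt.ergodic_times(emb, T=24.0)
        np.testing.assert_allclose(np.sort(asn.time), np.arange(100) * 0.24)

    def test_recovers_true_time(self, embedded):
        tab, asn, T = embedded["tab"], embedded["asn"], embedded["T"]
        true_t = tab["__true_phase"].to_numpy() * T
        delta = (asn.time - true_t) % T
        # remove the arbitrary circular offset before the MAE
        offset = np.angle(np.exp(1j * 2 * np.pi * delta / T).mean()) * T / (2 * np.pi)
        err = np.abs((delta - offset + T / 2) % T - T / 2)
        assert err.mean() < 0.1 * T


class TestKafriTimes:
    def test_closed_form_values(self):
        assert pt.kafri_time(0, 100, 24.0) == 0.0
        assert pt.kafri_time(100, 100, 24.0) == pytest.approx(24.0)
        assert pt.kafri_time(50, 100, 24.0) == pytest.approx(
            24.0 * np.log2(4.0 / 3.0))

    def test_monotone_in_rank(self):
        t = pt.kafri_time(np.arange(101), 100, 24.0)
        assert np.all(np.diff(t) > 0)

    def test_defensive_rank_bound(self):
        with pytest.raises(ValueError):
            pt.kafri_time(200, 100, 24.0)

    def test_assignment_spans_zero_to_below_T(self):
        rng = np.random.default_rng(8)
        emb = pt.CircularEmbedding(coords=np.zeros((50, 2)),
                                   center=np.zeros(2), radius=1.0,
                                   angle=rng.uniform(0, 2 * np.pi, 50))
        asn = pt.kafri_times(emb, T=24.0)
        assert asn.time.min() == 0.0
        assert asn.time.max() < 24.0


class TestMovingStats:
    def _asn(self, n, T=24.0, seed=0):
        rng = np.random.default_rng(seed)
        emb = pt.CircularEmbedding(coords=np.zeros((n, 2)), center=np.zeros(2),
                                   radius=1.0,
                                   angle=rng.uniform(0, 2 * np.pi, n))
        return pt.ergodic_times(emb, T)

    def test_constant_marker(self):
        asn = self._asn(200)
        traj = pt.moving_stats(np.full((200, 1), 3.3), asn, window=21)
        np.testing.assert_allclose(traj.med[:, 0], 3.3)
        np.testing.assert_allclose(traj.mad[:, 0], 0.0)

    def test_full_window_gives_global_median(self):
        asn = self._asn(101)
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(101, 1))
        traj = pt.moving_stats(vals, asn, window=101)
        np.testing.assert_allclose(traj.med[:, 0], np.median(vals))

    def test_sinusoid_within_two_mad(self):
        asn = self._asn(3000, seed=2)
        rng = np.random.default_rng(3)
        true = np.sin(2 * np.pi * asn.time / 24.0)
        vals = (true + rng.normal(0, 0.3, 3000))[:, None]
        traj = pt.moving_stats(vals, asn, window=151)
        ref = np.sin(2 * np.pi * traj.grid / 24.0)
        ok = np.abs(traj.med[:, 0] - ref) <= 2 * traj.mad[:, 0]
        assert ok.mean() >= 0.95

    def test_window_larger_than_n_raises(self):
        asn = self._asn(10)
        with pytest.raises(ValueError):
            pt.moving_stats(np.zeros((10, 1)), asn, window=11)

    def test_shift_equivariance(self):
        """Rotating all angles rotates the reconstructed trajectory.

        Equally spaced angles make the rank shift exact, so the rolled
        trajectories must agree to numerical precision.
        """
        n, T = 2000, 24.0
        ang = 2 * np.pi * np.arange(n) / n
        vals = np.cos(ang)[:, None]
        shift_frac = 0.25
        emb1 = pt.CircularEmbedding(np.zeros((n, 2)), np.zeros(2), 1.0, ang)
        emb2 = pt.CircularEmbedding(np.zeros((n, 2)), np.zeros(2), 1.0,
                                    (ang + 2 * np.pi * shift_frac) % (2 * np.pi))
        t1 = pt.moving_stats(vals, pt.ergodic_times(emb1, T), window=101)
        t2 = pt.moving_stats(vals, pt.ergodic_times(emb2, T), window=101)
        rolled = np.roll(t2.med[:, 0], -int(shift_frac * 100))
        assert np.abs(rolled - t1.med[:, 0]).max() < 1e-9


class TestPhaseBoundaries:
    def test_two_von_mises_modes(self):
        """Brute-force scan oracle: minima of the smoothed histogram."""
        rng = np.random.default_rng(9)
        ang = np.concatenate([
            stats.vonmises.rvs(8.0, loc=np.pi / 2, size=4000, random_state=rng),
            stats.vonmises.rvs(8.0, loc=3 * np.pi / 2, size=4000,
                               random_state=rng)]) % (2 * np.pi)
        emb = pt.CircularEmbedding(np.zeros((8000, 2)), np.zeros(2), 1.0, ang)
        b = pt.phase_boundaries(emb, n_bins=50)
        assert b.size == 2
        bin_w = 2 * np.pi / 50
        d0 = min(abs(b - 0.0).min(), abs(b - 2 * np.pi).min())
        dpi = abs(b - np.pi).min()
        assert d0 <= 1.5 * bin_w
        assert dpi <= 1.5 * bin_w

    def test_uniform_flagged_empty(self):
        rng = np.random.default_rng(10)
        ang = rng.uniform(0, 2 * np.pi, 5000)
        emb = pt.CircularEmbedding(np.zeros((5000, 2)), np.zeros(2), 1.0, ang)
        assert pt.phase_boundaries(emb).size == 0

    def test_unimodal_arrested_empty(self):
        rng = np.random.default_rng(11)
        ang = stats.vonmises.rvs(6.0, loc=1.0, size=3000,
                                 random_state=rng) % (2 * np.pi)
        emb = pt.CircularEmbedding(np.zeros((3000, 2)), np.zeros(2), 1.0, ang)
        assert pt.phase_boundaries(emb).size == 0


class TestBhAdjust:
    @staticmethod
    def _brute_force(p):
        """Literal step-up definition: adj_i = min_{j >= rank(i)}
        p_(j) * m / j, capped at 1."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            adj[order[i]] = min(1.0, min(sorted_p[j] * m / (j + 1)
                                         for j in range(i, m)))
        return adj

    def test_known_example(self):
        p = [0.01, 0.04, 0.03, 0.005]
        np.testing.assert_allclose(pt.bh_adjust(p), [0.02, 0.04, 0.04, 0.02])

    def test_all_equal(self):
        np.testing.assert_allclose(pt.bh_adjust([0.07] * 5), 0.07)

    def test_single_value(self):
        np.testing.assert_allclose(pt.bh_adjust([0.3]), [0.3])

    def test_matches_brute_force_exhaustive(self):
        rng = np.random.default_rng(12)
        for n in range(1, 8):
            for _ in range(20):
                p = rng.random(n)
                np.testing.assert_allclose(pt.bh_adjust(p),
                                           self._brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.random(25)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(pt.bh_adjust(p), adj, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_properties(self, p):
        adj = pt.bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pt.bh_adjust([0.5, 1.5])


class TestCircularCorr:
    @staticmethod
    def _brute_force(a, b):
        n = len(a)
        num = den_a = den_b = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                num += np.sin(a[i] - a[j]) * np.sin(b[i] - b[j])
                den_a += np.sin(a[i] - a[j]) ** 2
                den_b += np.sin(b[i] - b[j]) ** 2
        return num / np.sqrt(den_a * den_b)

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            a = rng.uniform(0, 2 * np.pi, 40)
            b = (a + rng.normal(0, 0.5, 40)) % (2 * np.pi)
            assert pt.circular_corr(a, b) == pytest.approx(
                self._brute_force(a, b), abs=1e-10)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(15)
        a = rng.uniform(0, 2 * np.pi, 200)
        b = (a + rng.normal(0, 0.2, 200)) % (2 * np.pi)
        c1 = pt.circular_corr(a, b)
        c2 = pt.circular_corr((a + 1.3) % (2 * np.pi), b)
        assert c1 == pytest.approx(c2, abs=1e-9)

    def test_perfect_correlation(self):
        a = np.random.default_rng(16).uniform(0, 2 * np.pi, 100)
        assert pt.circular_corr(a, a) == pytest.approx(1.0)
        assert pt.circular_corr(a, (-a) % (2 * np.pi)) == pytest.approx(-1.0)


class TestLooRobustness:
    @pytest.fixture(scope="class")
    def small_snapshot(self, limit_cycle):
        from cycletime.synthetic import SnapshotSpec, sample_snapshot

        spec = SnapshotSpec(n_cells=800, noise_cv=0.2, seed=31)
        return sample_snapshot(limit_cycle, spec)

    def test_redundant_marker_not_significant(self, small_snapshot):
        tab = small_snapshot.copy()
        tab["dup"] = tab["cycB"].to_numpy() * 1.0001  # exactly redundant
        rep = pt.loo_marker_robustness(tab, T=24.0, window=51, n_grid=40)
        p_dup = rep.loc[rep["marker"] == "dup", "p_adj"].iloc[0]
        assert p_dup > 0.05

    def test_report_schema(self, small_snapshot):
        rep = pt.loo_marker_robustness(small_snapshot, T=24.0, window=51,
                                       n_grid=30)
        assert set(rep.columns) == {"marker", "p", "p_adj"}
        assert len(rep) == 12
        assert (rep["p_adj"] >= rep["p"] - 1e-12).all()

    def test_null_type_one_error_controlled(self):
        """All-noise markers: BH-adjusted discoveries stay near nominal.

        Null replicates are scaled down (30 instead of 500) to fit the
        test budget; the binomial bound is adjusted accordingly.
        """
        rng = np.random.default_rng(17)
        n_disc = 0
        n_tests = 0
        for rep in range(25):
            vals = rng.lognormal(0, 0.3, size=(120, 6))
            tab = _table(vals, markers=[f"m{j}" for j in range(6)])
            out = pt.loo_marker_robustness(tab, T=24.0, window=31, n_grid=20,
                                           orientation_override=False)
            n_disc += int((out["p_adj"] < 0.05).sum())
            n_tests += len(out)
        # Expected false-discovery count at FDR 0.05 is 0.05 * n_tests when
        # every null is true; allow binomial slack (3 sigma).
        bound = 0.05 * n_tests + 3 * np.sqrt(0.05 * 0.95 * n_tests)
        assert n_disc <= bound
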