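"""Cell scoring: alignment formula, pseudotime, fate, potential, baselines."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import linregress, spearmanr

import velotraj as vt
from velotraj.datasets import VelocityDataset
from velotraj.scoring import TrajectoryAlignment
from velotraj.transition import TransitionModel


def _model_with(neighbors, gamma):
    neighbors = np.asarray(neighbors)
    gamma = np.asarray(gamma, dtype=float)
    probs = np.full_like(gamma, 1.0 / gamma.shape[1])
    return TransitionModel(neighbors=neighbors, gamma=gamma, probs=probs, kernel_scale=0.1)


def _dataset_at(points):
    points = np.asarray(points, dtype=float)
    return VelocityDataset(
        expression=np.abs(points) + 1.0,
        velocity=np.zeros_like(points),
        pca_coords=points,
    )


class TestAlignmentScore:
    def test_parallel_partners_full_velocity_agreement(self):
        """All partner displacements parallel to the segment with gamma = 1
        give a score of exactly e."""
        ds = _dataset_at([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        model = _model_with([[1, 2], [0, 2], [0, 1]], [[1.0, 1.0]] * 3)
        traj = vt.Trajectory(steps=[[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        scores, p = vt.alignment_score(0, traj, ds, model)
        assert scores[1] == pytest.approx(np.e)

    def test_orthogonal_segment_scores_zero(self):
        ds = _dataset_at([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        model = _model_with([[1, 2], [0, 2], [0, 1]], [[1.0, 1.0]] * 3)
        traj = vt.Trajectory(steps=[[0.0, -1.0], [0.0, 0.0], [0.0, 1.0]])
        scores, p = vt.alignment_score(0, traj, ds, model)
        assert scores[1] == pytest.approx(0.0, abs=1e-12)

    def test_two_partner_hand_evaluation(self):
        # partner 1: displacement along the segment, gamma 0
        # partner 2: displacement at 60 degrees, gamma 1
        half, s3 = 0.5, np.sqrt(3) / 2
        ds = _dataset_at([[0.0, 0.0], [1.0, 0.0], [half, s3]])
        model = _model_with([[1, 2], [0, 2], [0, 1]], [[0.0, 1.0], [0, 0], [0, 0]])
        traj = vt.Trajectory(steps=[[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        scores, p = vt.alignment_score(0, traj, ds, model)
        expected = (1.0 * np.exp(0) + 0.5 * np.exp(1)) / 2
        assert scores[1] == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(1.1796, abs=1e-4)

    def test_boundary_steps_use_single_segment(self):
        ds = _dataset_at([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        model = _model_with([[1, 2], [0, 2], [0, 1]], [[1.0, 1.0]] * 3)
        traj = vt.Trajectory(steps=[[0.0, 0.0], [1.0, 0.0]])
        scores, p = vt.alignment_score(0, traj, ds, model)
        assert scores[0] == pytest.approx(np.e)  # forward segment only
        assert scores[1] == pytest.approx(np.e)  # backward segment only


def _alignment(rows, cols, vals, n_cells, n_steps):
    scores = sp.csr_matrix((vals, (rows, cols)), shape=(n_cells, n_steps))
    counts = np.diff(scores.indptr)
    p = np.full(n_cells, np.nan)
    p[counts > 0] = np.asarray(scores.sum(axis=1)).ravel()[counts > 0] / counts[counts > 0]
    return TrajectoryAlignment(scores=scores, p=p, compositional=None)


class TestPseudotime:
    def test_single_step(self):
        pt = vt.pseudotime(_alignment([0], [3], [2.0], 2, 5))
        assert pt[0] == 3.0
        assert np.isnan(pt[1])

    def test_equal_scores_unweighted_mean(self):
        pt = vt.pseudotime(_alignment([0, 0], [2, 4], [1.5, 1.5], 1, 6))
        assert pt[0] == 3.0

    def test_weighted_mean(self):
        pt = vt.pseudotime(_alignment([0, 0], [0, 10], [1.0, 3.0], 1, 11))
        assert pt[0] == pytest.approx(7.5)

    def test_invariant_to_rescaling(self):
        a1 = _alignment([0, 0, 0], [1, 4, 7], [0.2, 0.5, 1.1], 1, 9)
        a2 = _alignment([0, 0, 0], [1, 4, 7], [0.6, 1.5, 3.3], 1, 9)
        assert vt.pseudotime(a1)[0] == pytest.approx(vt.pseudotime(a2)[0])

    def test_within_step_range(self, rng):
        n, L = 30, 12
        rows = np.repeat(np.arange(n), 3)
        cols = rng.integers(0, L, 3 * n)
        vals = rng.uniform(0.1, 2.0, 3 * n)
        pt = vt.pseudotime(_alignment(rows, cols, vals, n, L))
        assert np.all((pt >= 0) & (pt <= L - 1))


class TestFateAndPotential:
    def test_symmetric(self):
        np.testing.assert_allclose(vt.fate_score([[2.0, 2.0]]), [[0.5, 0.5]])

    def test_single_trajectory(self):
        np.testing.assert_allclose(vt.fate_score([[3.0]]), [[1.0]])

    def test_hand_normalization(self):
        np.testing.assert_allclose(vt.fate_score([[1.0, 3.0]]), [[0.25, 0.75]])

    def test_rows_on_simplex(self, rng):
        P = rng.uniform(0, 2, (20, 4))
        fates = vt.fate_score(P)
        np.testing.assert_allclose(fates.sum(axis=1), 1.0, atol=1e-8)

    def test_unaligned_cells_nan(self):
        fates = vt.fate_score([[np.nan, np.nan], [1.0, 1.0]])
        assert np.isnan(fates[0]).all()
        np.testing.assert_allclose(fates[1], [0.5, 0.5])

    def test_potential_hand_case(self):
        fates = np.array([[1.0, 0.0], [0.5, 0.5], [0.75, 0.25]])
        pot = vt.differentiation_potential(fates)
        h3 = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        np.testing.assert_allclose(pot, [0.0, 1.0, h3 / np.log(2)], atol=1e-12)
        assert pot[2] == pytest.approx(0.8113, abs=1e-4)

    def test_potential_degenerate_all_zero(self):
        with pytest.warns(UserWarning, match="entropies equal"):
            pot = vt.differentiation_potential(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(pot, 0.0)

    def test_potential_bounds(self, rng):
        fates = vt.fate_score(rng.uniform(0, 1, (50, 3)))
        pot = vt.differentiation_potential(fates)
        assert np.nanmin(pot) >= 0 and np.nanmax(pot) <= 1


class TestEuclideanPseudotime:
    traj = vt.Trajectory(steps=[[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])

    def test_cell_on_consensus_point(self):
        ds = _dataset_at([[2.0, 0.0]])
        assert vt.euclidean_pseudotime(self.traj, ds)[0] == 2.0

    def test_tie_breaks_to_lower_segment(self):
        ds = _dataset_at([[1.0, 0.5]])  # equidistant to segments ending at 1 and 2
        assert vt.euclidean_pseudotime(self.traj, ds)[0] == 1.0

    def test_matches_bruteforce_point_segment(self, rng):
        steps = rng.normal(size=(8, 3))
        traj = vt.Trajectory(steps=steps)
        pts = rng.normal(size=(40, 3))
        ds = _dataset_at(pts)
        got = vt.euclidean_pseudotime(traj, ds)

        def seg_dist(p, a, b):
            v = b - a
            t = np.clip(np.dot(p - a, v) / np.dot(v, v), 0, 1)
            return np.linalg.norm(p - (a + t * v))

        for c, p in enumerate(pts):
            dists = np.array([seg_dist(p, steps[i], steps[i + 1]) for i in range(7)])
            # a point projecting onto a shared vertex ties two segments
            # exactly; accept any distance-minimizing segment
            assert dists[int(got[c]) - 1] == pytest.approx(dists.min(), abs=1e-9)


class TestRollingRate:
    def test_exact_linear(self, rng):
        a = np.sort(rng.uniform(0, 10, 200))
        slopes = vt.rolling_rate_comparison(a, 2.0 * a, window=50)
        np.testing.assert_allclose(slopes, 2.0, atol=1e-10)

    def test_near_identity_with_noise(self, rng):
        a = np.sort(rng.uniform(0, 10, 300))
        b = a + rng.normal(0, 1e-4, 300)
        slopes = vt.rolling_rate_comparison(a, b, window=50)
        np.testing.assert_allclose(slopes, 1.0, atol=1e-2)

    def test_matches_linregress_oracle(self, rng):
        a = np.sort(rng.uniform(0, 5, 120))
        b = np.where(a < 2.5, a, 3 * a - 5) + rng.normal(0, 0.01, 120)
        window, half, n = 50, 25, 120
        slopes = vt.rolling_rate_comparison(a, b, window=window)
        for pos in (0, 30, 60, 119):
            lo = max(0, min(pos - half, n - window))
            expected = linregress(a[lo : lo + window], b[lo : lo + window]).slope
            assert slopes[pos] == pytest.approx(expected)

    def test_window_too_large(self):
        with pytest.raises(ValueError, match="window"):
            vt.rolling_rate_comparison(np.arange(10.0), np.arange(10.0), window=50)


class TestCompositionalClusters:
    def _grid_dataset(self, labels):
        n = len(labels)
        pts = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        return VelocityDataset(
            expression=pts + 1,
            velocity=np.zeros_like(pts),
            pca_coords=pts,
            cluster_labels=np.asarray(labels),
        )

    def test_single_cluster_trajectory(self):
        ds = self._grid_dataset(["a"] * 10)
        traj = vt.Trajectory(steps=[[2.0, 0.0], [6.0, 0.0]])
        comp = vt.compositional_clusters(traj, ds, neighborhood_size=4)
        assert comp.clusters == ["a"]

    def test_mixed_neighborhood_both_compositional(self):
        # neighborhood composition 40/60 crosses the 0.3 default for both
        ds = self._grid_dataset(["a"] * 4 + ["b"] * 6)
        traj = vt.Trajectory(steps=[[4.0, 0.0], [5.0, 0.0]])
        comp = vt.compositional_clusters(traj, ds, neighborhood_size=10)
        assert comp.clusters == ["a", "b"]

    def test_threshold_one_requires_purity(self):
        ds = self._grid_dataset(["a"] * 4 + ["b"] * 6)
        traj = vt.Trajectory(steps=[[4.0, 0.0], [5.0, 0.0]])
        comp = vt.compositional_clusters(traj, ds, neighborhood_size=10, threshold=1.0)
        assert comp.clusters == []


class TestOnSyntheticRuns:
    def test_linear_pseudotime_tracks_truth(self, linear_run):
        dataset, truth, result = linear_run
        pt = result.cell_scores["pseudotime"].to_numpy()
        ok = ~np.isnan(pt)
        assert ok.sum() > 0.8 * dataset.n_cells
        rho = spearmanr(pt[ok], truth.true_time[ok]).statistic
        assert rho >= 0.9

    def test_bifurcation_fate_commitment(self, bifurcating_run):
        dataset, truth, result = bifurcating_run
        regions = [t.terminal_region for t in result.trajectories]
        fates = result.cell_scores[
            [f"fate_{j}" for j in range(len(result.trajectories))]
        ].to_numpy()
        post = truth.true_time > 0.6  # clearly beyond the branch point
        for branch, region in ((1, "b1_t4"), (2, "b2_t4")):
            j = regions.index(region)
            own = fates[post & (truth.true_branch == branch), j]
            assert np.nanmedian(own) >= 0.8

    def test_two_speed_process_rate_association(self):
        """Slower transcriptional change shows lower cohesiveness * magnitude
        and a lower local geometric progression rate (sign test on the
        planted halves)."""
        mag = lambda t: np.where(t < 0.5, 1.0, 0.5)
        ds, truth = vt.generate(
            vt.TopologySpec(
                kind="linear",
                n_cells=500,
                seed=3,
                velocity_magnitude=mag,
                velocity_noise_sd=0.3,
            )
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = vt.run_pipeline(ds, vt.RunConfig(seed=3))
        traj = result.trajectories[0]
        pt = result.cell_scores["pseudotime"].to_numpy()
        ok = ~np.isnan(pt)
        # arc-length transform of the segment-index baseline: geometric
        # progress along the trajectory per velocity-pseudotime step
        seglen = np.linalg.norm(traj.segments, axis=1)
        cumlen = np.concatenate([[0], np.cumsum(seglen)])
        arc = cumlen[vt.euclidean_pseudotime(traj, ds).astype(int)]
        slope = vt.rolling_rate_comparison(pt, np.where(ok, arc, np.nan), window=50)
        speed = result.cell_scores["cohesiveness"].to_numpy() * np.linalg.norm(
            ds.velocity, axis=1
        )
        sel = ok & ~np.isnan(slope)
        fast = sel & (truth.true_time < 0.5)
        slow = sel & (truth.true_time >= 0.5)
        assert speed[fast].mean() > speed[slow].mean()
        assert slope[fast].mean() > slope[slow].mean()
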