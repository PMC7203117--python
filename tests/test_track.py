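"""Tracker: windowed estimators, Gaussian likelihood, Munkres optimality, linking."""

import itertools

import numpy as np
import pytest

from trajstyle.simulate import MotilityParams, simulate_track
from trajstyle.track import (
    CostMatrix,
    DriftVolatility,
    Track,
    TrackerConfig,
    assign,
    build_cost_matrix,
    displacement_likelihood,
    estimate_drift_volatility,
    link_video,
)


def brute_force_min_cost(C):
    """Minimum-cost perfect matching of a square matrix by full enumeration."""
    n = C.shape[0]
    best = np.inf
    best_match = []
    for perm in itertools.permutations(range(n)):
        cost = sum(C[i, perm[i]] for i in range(n))
        if cost < best:
            best, best_match = cost, sorted(enumerate(perm))
    return best, best_match


class TestDriftVolatilityEstimator:
    def test_constant_displacements(self):
        tr = Track(0, np.arange(4), [0, 2, 4, 6], [0, -1, -2, -3])
        dv = estimate_drift_volatility(tr, T=10)
        assert (dv.mu_x, dv.mu_y) == (2.0, -1.0)
        assert (dv.var_x, dv.var_y) == (0.0, 0.0)

    def test_hand_computed_window(self):
        # displacements (0,0) and (2,0): mean 1, population variance 1
        tr = Track(0, [0, 1, 2], [0, 0, 2], [0, 0, 0])
        dv = estimate_drift_volatility(tr, T=2)
        assert dv.mu_x == 1.0 and dv.var_x == 1.0
        assert dv.window_T == 2

    def test_window_uses_most_recent_displacements(self):
        tr = Track(0, np.arange(5), [0, 100, 101, 102, 103], [0, 0, 0, 0, 0])
        dv = estimate_drift_volatility(tr, T=3)
        assert dv.mu_x == 1.0 and dv.var_x == 0.0

    def test_cold_start_flagged(self):
        tr = Track(0, [0], [5.0], [5.0])
        dv = estimate_drift_volatility(tr, coldstart_sigma=2.0)
        assert dv.cold_start and dv.mu_x == 0.0 and dv.var_x == 4.0

    def test_monte_carlo_recovery(self):
        tr = simulate_track(
            MotilityParams(drift_x=0.5, volatility_x=1.0, volatility_y=1.0),
            (0, 0), 1000, np.random.default_rng(11),
        )
        dv = estimate_drift_volatility(tr, T=1000)
        assert abs(dv.mu_x - 0.5) < 3 / np.sqrt(1000)
        from scipy.stats import chi2

        lo, hi = chi2.ppf([0.005, 0.995], 1000) / 1000
        assert lo < dv.var_x < hi


class TestDisplacementLikelihood:
    def test_peak_density_is_inverse_two_pi(self):
        dv = DriftVolatility(0.3, -0.2, 1.0, 1.0, 5)
        assert displacement_likelihood(0.3, -0.2, dv) == pytest.approx(1 / (2 * np.pi))

    def test_integrates_to_one(self):
        dv = DriftVolatility(1.0, -2.0, 1.5**2, 0.8**2, 5)
        sx, sy = 1.5, 0.8
        gx = np.linspace(1.0 - 6 * sx, 1.0 + 6 * sx, 601)
        gy = np.linspace(-2.0 - 6 * sy, -2.0 + 6 * sy, 601)
        vals = np.array(
            [[displacement_likelihood(x, y, dv) for x in gx] for y in gy]
        )
        integral = np.trapezoid(np.trapezoid(vals, gx, axis=1), gy)
        assert abs(integral - 1.0) < 1e-3

    def test_symmetry_about_mean(self):
        dv = DriftVolatility(0.5, 0.0, 2.0, 3.0, 5)
        a = displacement_likelihood(0.5 + 1.3, 0.7, dv)
        b = displacement_likelihood(0.5 - 1.3, -0.7, dv)
        assert a == pytest.approx(b)

    def test_nonfinite_rejected(self):
        dv = DriftVolatility(0, 0, 1, 1, 5)
        with pytest.raises(ValueError):
            displacement_likelihood(np.nan, 0.0, dv)


class TestCostMatrix:
    def test_cost_at_predicted_mean_is_two_pi(self):
        dv = DriftVolatility(1.0, 0.0, 1.0, 1.0, 5)
        cm = build_cost_matrix([[0.0, 0.0]], [[1.0, 0.0]], [dv])
        assert cm.entries[0, 0] == pytest.approx(2 * np.pi)

    def test_cost_monotone_in_deviation(self):
        dv = DriftVolatility(0.0, 0.0, 1.0, 1.0, 5)
        dets = [[d, 0.0] for d in (0.0, 0.5, 1.0, 2.0, 4.0)]
        cm = build_cost_matrix([[0.0, 0.0]], dets, [dv])
        assert np.all(np.diff(cm.entries[0]) > 0)

    def test_empty_inputs_give_empty_matrix(self):
        cm = build_cost_matrix(np.empty((0, 2)), np.empty((0, 2)), [])
        assert cm.entries.shape == (0, 0)
        matches, ur, uc = assign(cm)
        assert matches == [] and ur == [] and uc == []


class TestAssignment:
    def test_identity_dominant(self):
        cm = CostMatrix(np.array([[1.0, 10.0], [10.0, 1.0]]),
                        np.full(2, 1e6), np.full(2, 1e6))
        matches, ur, uc = assign(cm)
        assert matches == [(0, 0), (1, 1)] and not ur and not uc

    def test_all_above_gate_unmatched(self):
        cm = CostMatrix(np.full((2, 3), 50.0), np.full(2, 10.0), np.full(3, 10.0))
        matches, ur, uc = assign(cm)
        assert matches == [] and ur == [0, 1] and uc == [0, 1, 2]

    @pytest.mark.parametrize("trial", range(20))
    def test_square_instances_match_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 7))
        C = rng.uniform(0.1, 10.0, (n, n))
        cm = CostMatrix(C, np.full(n, 1e9), np.full(n, 1e9))
        matches, _, _ = assign(cm)
        total = sum(C[i, j] for i, j in matches)
        best, _ = brute_force_min_cost(C)
        assert total == pytest.approx(best)

    @pytest.mark.parametrize("trial", range(10))
    def test_rectangular_with_gate_matches_brute_force(self, trial):
        rng = np.random.default_rng(300 + trial)
        C = rng.uniform(0.1, 10.0, (5, 6))
        gate = 6.0
        cm = CostMatrix(C, np.full(5, gate), np.full(6, gate))
        matches, _, _ = assign(cm)
        # objective with unmatched penalty = gate per unmatched row and column
        def objective(mset):
            unmatched_rows = 5 - len(mset)
            unmatched_cols = 6 - len(mset)
            return (sum(C[i, j] for i, j in mset)
                    + gate * (unmatched_rows + unmatched_cols))

        best = min(
            objective([(i, c) for i, c in enumerate(perm) if c is not None])
            for perm in itertools.permutations(list(range(6)) + [None] * 5, 5)
            if all(
                C[i, c] <= gate for i, c in enumerate(perm) if c is not None
            )
        )
        assert objective(matches) == pytest.approx(best)


class TestLinkVideo:
    def _well_separated(self, n_cells=5, n_frames=30, sigma=0.5, spacing=60, seed=5):
        rng = np.random.default_rng(seed)
        tracks = []
        k = int(np.ceil(np.sqrt(n_cells)))
        for i in range(n_cells):
            start = ((i % k) * spacing + 30, (i // k) * spacing + 30)
            tracks.append(
                simulate_track(
                    MotilityParams(volatility_x=sigma, volatility_y=sigma),
                    start, n_frames - 1, rng, track_id=i,
                )
            )
        per_frame = {
            f: np.array([[tr.xs[f], tr.ys[f]] for tr in tracks])
            for f in range(n_frames)
        }
        return tracks, per_frame

    @staticmethod
    def link_accuracy(gt_tracks, est_tracks):
        truth = {}
        for tr in gt_tracks:
            for f, x, y in zip(tr.frames, tr.xs, tr.ys):
                truth[(int(f), round(float(x), 6), round(float(y), 6))] = tr.track_id
        correct = total = 0
        for tr in est_tracks:
            for a in range(len(tr) - 1):
                ka = (int(tr.frames[a]), round(float(tr.xs[a]), 6), round(float(tr.ys[a]), 6))
                kb = (int(tr.frames[a + 1]), round(float(tr.xs[a + 1]), 6), round(float(tr.ys[a + 1]), 6))
                total += 1
                if truth.get(ka) is not None and truth.get(ka) == truth.get(kb):
                    correct += 1
        gt_links = sum(len(tr) - 1 for tr in gt_tracks)
        return correct / gt_links if gt_links else 1.0, total

    def test_recovers_ground_truth_links(self):
        gt, per_frame = self._well_separated()
        est = link_video(per_frame)
        assert len(est) == 5
        acc, _ = self.link_accuracy(gt, est)
        assert acc == 1.0

    def test_single_frame_gives_length_one_tracks(self):
        est = link_video({0: np.array([[1.0, 2.0], [5.0, 6.0]])})
        assert len(est) == 2 and all(len(t) == 1 for t in est)

    def test_moderate_density_high_fidelity(self):
        gt, per_frame = self._well_separated(
            n_cells=20, n_frames=100, sigma=1.0, spacing=40, seed=9
        )
        est = link_video(per_frame)
        acc, _ = self.link_accuracy(gt, est)
        assert acc >= 0.99

    def test_permutation_invariant_membership(self):
        gt, per_frame = self._well_separated(n_cells=6, n_frames=20, seed=13)
        rng = np.random.default_rng(0)
        shuffled = {
            f: dets[rng.permutation(len(dets))] for f, dets in per_frame.items()
        }
        a = link_video(per_frame)
        b = link_video(shuffled)

        def canon(tracks):
            return sorted(
                tuple(zip(tr.frames.tolist(),
                          np.round(tr.xs, 9).tolist(),
                          np.round(tr.ys, 9).tolist()))
                for tr in tracks
            )

        assert canon(a) == canon(b)

    def test_gap_in_frames_terminates_tracks(self):
        d = np.array([[10.0, 10.0]])
        est = link_video({0: d, 1: d + 0.1, 5: d, 6: d + 0.1})
        assert len(est) == 2 and all(len(t) == 2 for t in est)
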