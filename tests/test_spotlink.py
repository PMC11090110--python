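"""Detection and linking: sub-pixel accuracy, gap closing, assignment optimality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from smflux import simulate, spotlink
from smflux.spotlink import Spot


PX = spotlink.DEFAULT_PIXEL_UM


class TestDetect:
    def test_constant_image_yields_nothing(self):
        img = np.full((32, 32), 7.0)
        assert spotlink.detect_spots(img, 0.8, threshold=0.1) == []

    def test_single_rendered_spot_subpixel_accuracy(self, single_spot_movie):
        stack, truth = single_spot_movie
        spots = spotlink.detect_spots(stack[0], 0.8, threshold=1.0)
        assert len(spots) == 1
        err = np.hypot(spots[0].x - truth.x_um[0], spots[0].y - truth.y_um[0])
        assert err < 0.5 * PX

    def test_two_well_separated_spots(self):
        truth = pd.DataFrame({
            "frame": [0, 0], "id": [0, 1],
            "x_um": [1.5, 4.5], "y_um": [2.0, 2.0], "I": [500.0, 500.0],
        })
        stack = simulate.render_movie(truth, shape=(40, 40))
        assert len(spotlink.detect_spots(stack[0], 0.8, threshold=1.0)) == 2

    def test_noisy_field_recovers_all_spots(self, rng):
        n = 10
        pts = []
        while len(pts) < n:  # resolvable ground truth: >= 1 um apart
            p = rng.uniform(1.5, 6.0, size=2)
            if all(np.hypot(*(p - q)) > 1.0 for q in pts):
                pts.append(p)
        xy = np.array(pts)
        truth = pd.DataFrame({
            "frame": 0, "id": np.arange(n),
            "x_um": xy[:, 0], "y_um": xy[:, 1], "I": 2000.0,
        })
        stack = simulate.render_movie(
            truth, shape=(52, 52),
            noise_model={"background": 20.0, "read_sd": 2.0}, seed=1,
        )
        spots = spotlink.detect_spots(stack[0], 0.8, threshold=8.0)
        assert len(spots) == n
        for tx, ty in xy:  # every truth spot matched within half a pixel
            d = min(np.hypot(s.x - tx, s.y - ty) for s in spots)
            assert d < 0.5 * PX

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            spotlink.detect_spots(np.zeros((3, 4, 5)), 0.8)


def _brute_force_cost(prev, curr, radius):
    """Minimum total cost over all gated assignments, birth/death at radius^2."""
    gate = radius * radius
    best = None
    n, m = len(prev), len(curr)
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                cost = (n - k) * gate + (m - k) * gate
                ok = True
                for r, c in zip(rows, cols):
                    d2 = (prev[r][0] - curr[c][0]) ** 2 + (prev[r][1] - curr[c][1]) ** 2
                    if d2 > gate:
                        ok = False
                        break
                    cost += d2
                if ok and (best is None or cost < best):
                    best = cost
    return best


class TestLink:
    def test_persistent_spot_single_full_trajectory(self):
        frames = {f: [Spot(frame=f, x=1.0 + 0.01 * f, y=2.0, I=1.0)] for f in range(20)}
        trajs = spotlink.link_spots(frames, radius=0.5, max_gap=0.1, dt=0.1)
        assert len(trajs) == 1
        assert len(trajs[0]) == 20

    def test_one_frame_gap_is_closed(self):
        frames = {f: [Spot(frame=f, x=1.0, y=1.0, I=1.0)] for f in range(10) if f != 4}
        trajs = spotlink.link_spots(frames, radius=0.5, max_gap=0.1, dt=0.1)
        assert len(trajs) == 1
        assert trajs[0].gaps == [4]

    def test_two_frame_gap_is_not_closed(self):
        frames = {f: [Spot(frame=f, x=1.0, y=1.0, I=1.0)]
                  for f in range(10) if f not in (4, 5)}
        trajs = spotlink.link_spots(frames, radius=0.5, max_gap=0.1, dt=0.1)
        assert len(trajs) == 2

    def test_distant_spots_never_swap(self, rng):
        # two walkers always > 2 um apart stay in separate trajectories
        steps = rng.normal(0, 0.05, size=(30, 2, 2))
        pos = np.cumsum(steps, axis=0) + np.array([[1.0, 1.0], [6.0, 6.0]])
        frames = {
            f: [Spot(frame=f, x=float(pos[f, i, 0]), y=float(pos[f, i, 1]), I=1.0)
                for i in range(2)]
            for f in range(30)
        }
        trajs = spotlink.link_spots(frames, radius=0.5, max_gap=0.1, dt=0.1)
        assert len(trajs) == 2
        for tr in trajs:
            xs = tr.xy[:, 0]
            assert (xs < 4).all() or (xs > 4).all()

    def test_assignment_matches_exhaustive_search(self, rng):
        # frame-pair assignment cost equals the brute-force optimum (<= 4 spots)
        radius = 0.5
        for _ in range(25):
            n, m = rng.integers(1, 5), rng.integers(1, 5)
            prev = rng.uniform(0, 2, size=(n, 2))
            curr = rng.uniform(0, 2, size=(m, 2))
            frames = {
                0: [Spot(frame=0, x=float(x), y=float(y)) for x, y in prev],
                1: [Spot(frame=1, x=float(x), y=float(y)) for x, y in curr],
            }
            trajs = spotlink.link_spots(frames, radius=radius, max_gap=0.0, dt=0.1)
            gate = radius**2
            links = sum(1 for t in trajs if len(t) == 2)
            cost = sum(
                ((t.xy[1] - t.xy[0]) ** 2).sum() for t in trajs if len(t) == 2
            )
            cost += gate * (n - links) + gate * (m - links)
            expected = _brute_force_cost(prev, curr, radius)
            assert cost == pytest.approx(expected, abs=1e-9)

    def test_linking_is_permutation_invariant(self, rng):
        spots = [
            [Spot(frame=f, x=float(x), y=float(y), I=1.0)
             for x, y in rng.uniform(0, 3, size=(4, 2))]
            for f in range(6)
        ]
        frames_a = {f: list(s) for f, s in enumerate(spots)}
        frames_b = {f: list(reversed(s)) for f, s in enumerate(spots)}
        ta = spotlink.link_spots(frames_a, radius=0.5, max_gap=0.1, dt=0.1)
        tb = spotlink.link_spots(frames_b, radius=0.5, max_gap=0.1, dt=0.1)
        key = lambda trs: sorted(tuple(map(tuple, t.xy)) for t in trs)  # noqa: E731
        assert key(ta) == key(tb)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            spotlink.link_spots({}, radius=0.0)


class TestEndToEnd:
    def test_noiseless_movie_recovers_ground_truth(self):
        cfg = simulate.TrajectorySimConfig(
            n_traj=4, n_frames=15, dt=0.1, states=[(0.05, 1.0)], loc_sigma=0.0,
            bleach_rate=0.0, fov=(5.0, 5.0), brightness=2000.0, seed=21,
        )
        trajs = simulate.simulate_trajectories(cfg)
        truth = simulate.trajectories_truth_frame(trajs, cfg.dt)
        truth[["x_um", "y_um"]] += 1.0  # keep away from the border
        stack = simulate.render_movie(truth, shape=(48, 48), n_frames=15)
        by_frame = {
            f: spotlink.detect_spots(stack[f], 0.8, threshold=1.0, frame=f)
            for f in range(15)
        }
        found = spotlink.link_spots(by_frame, radius=0.5, max_gap=0.1, dt=0.1)
        assert len(found) == 4
        # match each truth track to its closest recovered track
        for tr in trajs:
            ref = tr.xy + 1.0
            errs = [np.abs(f.xy - ref).max() for f in found if len(f) == len(tr)]
            assert min(errs) < 0.5 * PX


class TestDensity:
    @pytest.mark.parametrize(
        "n,area,expected", [(30, 600.0, 0.05), (150, 600.0, 0.25), (0, 500.0, 0.0)]
    )
    def test_counts_per_area(self, n, area, expected):
        assert spotlink.density_from_counts(n, area) == pytest.approx(expected)

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            spotlink.density_from_counts(10, 0.0)


def test_csv_roundtrip(rng):
    cfg = simulate.TrajectorySimConfig(n_traj=5, n_frames=10, seed=3)
    trajs = simulate.simulate_trajectories(cfg)
    df = spotlink.trajectories_to_frame(trajs, cfg.dt)
    back = spotlink.frame_to_trajectories(df)
    assert len(back) == len(trajs)
    for a, b in zip(trajs, back):
        assert np.allclose(a.xy, b.xy)
        assert np.array_equal(a.frames, b.frames)
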