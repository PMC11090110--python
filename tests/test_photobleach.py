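"""smPB corrections, spot selection, change-point detection, ensemble fits."""

import itertools

import numpy as np
import pytest

from smflux import photobleach, simulate
from smflux.photobleach import IntensityTrace


PX = 0.167


class TestIlluminationField:
    def test_flat_movie_gives_unit_field(self):
        tail = np.full((10, 64, 64), 50.0)
        field = photobleach.illumination_field(tail)
        assert np.allclose(field, 1.0)

    def test_recovers_synthetic_gaussian_profile(self):
        ny = nx = 96
        yy, xx = np.mgrid[0:ny, 0:nx]
        profile = np.exp(-((xx - 48) ** 2 + (yy - 48) ** 2) / (2 * 40.0**2))
        tail = np.broadcast_to(100.0 * profile, (10, ny, nx))
        field = photobleach.illumination_field(tail)
        expected = profile / profile.mean()
        rms = np.sqrt(((field - expected) ** 2).mean()) / expected.mean()
        assert rms < 0.02

    def test_round_trip_correction(self):
        ny = nx = 64
        yy, xx = np.mgrid[0:ny, 0:nx]
        profile = 1.0 + 0.5 * np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * 20.0**2))
        flat = np.full((ny, nx), 10.0)
        movie = np.broadcast_to(flat * profile, (10, ny, nx))
        field = photobleach.illumination_field(movie)
        corrected = movie[0] / field
        assert np.allclose(corrected, corrected.mean(), rtol=0.03)

    def test_all_zero_tail_rejected(self):
        with pytest.raises(ValueError):
            photobleach.illumination_field(np.zeros((5, 32, 32)))


class TestSelectSpots:
    def _image_with_spots(self, positions_um, amp=50.0, shape=(64, 64), seed=0):
        import pandas as pd

        truth = pd.DataFrame({
            "frame": 0, "id": range(len(positions_um)),
            "x_um": [p[0] for p in positions_um],
            "y_um": [p[1] for p in positions_um],
            "I": amp * 100,
        })
        return simulate.render_movie(
            truth, shape=shape, noise_model={"background": 20.0, "read_sd": 1.0},
            seed=seed,
        )[0]

    @staticmethod
    def _near(kept, pos, tol=0.5):
        return any(np.hypot(x - pos[0], y - pos[1]) < tol for x, y in kept)

    def test_isolated_central_spot_kept(self):
        img = self._image_with_spots([(5.0, 5.0)])
        kept = photobleach.select_spots(img)
        assert self._near(kept, (5.0, 5.0), tol=2 * PX)

    def test_close_pair_both_removed(self):
        img = self._image_with_spots([(5.0, 5.0), (5.5, 5.0)])  # 0.5 um apart
        kept = photobleach.select_spots(img)
        assert not self._near(kept, (5.0, 5.0))
        assert not self._near(kept, (5.5, 5.0))

    def test_edge_spot_removed(self):
        img = self._image_with_spots([(0.3, 5.0)])
        assert not self._near(photobleach.select_spots(img), (0.3, 5.0))


class TestLocalBackground:
    def test_border_ranking_definition(self):
        patch = np.zeros((7, 7))
        border_idx = [(r, c) for r in range(7) for c in range(7)
                      if r in (0, 6) or c in (0, 6)]
        for val, (r, c) in enumerate(border_idx, start=1):
            patch[r, c] = val
        patch[1:6, 1:6] = 100.0
        assert photobleach.local_background(patch) == pytest.approx(2.5)

    def test_uniform_patch_zero_corrected_intensity(self):
        patch = np.full((7, 7), 3.7)
        assert photobleach.corrected_spot_intensity(patch) == pytest.approx(0.0)

    def test_border_permutation_invariance(self, rng):
        patch = rng.uniform(0, 10, size=(7, 7))
        ref = photobleach.local_background(patch)
        for _ in range(5):
            p = patch.copy()
            border = [(r, c) for r in range(7) for c in range(7)
                      if r in (0, 6) or c in (0, 6)]
            vals = [p[rc] for rc in border]
            rng.shuffle(vals)
            for rc, v in zip(border, vals):
                p[rc] = v
            assert photobleach.local_background(p) == pytest.approx(ref)

    def test_rendered_spot_recovers_integrated_brightness(self):
        import pandas as pd

        truth = pd.DataFrame(
            {"frame": [0], "id": [0], "x_um": [2.0], "y_um": [2.0], "I": [300.0]}
        )
        stack = simulate.render_movie(truth, psf_sigma=0.1, shape=(24, 24)) + 7.0
        r = c = round(2.0 / PX)
        est = photobleach.corrected_spot_intensity(stack[0, r - 3:r + 4, c - 3:c + 4])
        assert est == pytest.approx(300.0, rel=0.02)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            photobleach.local_background(np.zeros((5, 5)))


def _trace(y, dt=0.5):
    return IntensityTrace(intensity=np.asarray(y, dtype=float), frame_dt=dt)


class TestChangepoints:
    def test_noiseless_single_step(self):
        y = np.concatenate([np.full(40, 8.0), np.zeros(40)])
        r = photobleach.find_changepoints(_trace(y), 0.95)
        assert r.n_steps == 1
        assert r.step_frames[0] == 40
        assert r.I0 == pytest.approx(8.0)
        assert r.T_pb == pytest.approx(40 * 0.5)
        assert r.bleached

    def test_noiseless_two_steps(self):
        y = np.concatenate([np.full(30, 8.0), np.full(30, 4.0), np.zeros(30)])
        r = photobleach.find_changepoints(_trace(y), 0.95)
        assert r.n_steps == 2
        assert list(r.step_frames) == [30, 60]
        assert np.allclose(r.step_sizes, [-4.0, -4.0])

    def test_upward_shifts_are_discarded(self):
        y = np.concatenate([np.full(30, 4.0), np.full(30, 8.0), np.zeros(30)])
        r = photobleach.find_changepoints(_trace(y), 0.95)
        assert np.all(r.step_sizes < 0)
        assert 30 not in r.step_frames

    def test_unbleached_trace_flagged(self):
        y = np.concatenate([np.full(40, 8.0), np.full(40, 4.0)])
        r = photobleach.find_changepoints(_trace(y + np.sin(np.arange(80)) * 0.0), 0.95)
        assert not r.bleached

    def test_short_trace_returns_no_steps(self):
        r = photobleach.find_changepoints(_trace([5.0, 5.0, 5.0, 5.0, 5.0]), 0.95)
        assert r.n_steps == 0

    def test_monomer_ensemble_mostly_single_step(self, monomer_traces):
        traces, truth, cfg = monomer_traces
        results = [photobleach.find_changepoints(t, 0.95) for t in traces]
        one_step = np.mean([r.n_steps == 1 for r in results])
        assert one_step >= 0.90

    def test_false_positive_rate_bounded(self, rng):
        # pure-noise traces: per-trace FP rate <= 1 - confidence
        n_fp = 0
        for _ in range(1000):
            tr = _trace(rng.normal(5.0, 1.0, 200))
            if len(photobleach.find_changepoints(tr, 0.95).segments) > 1:
                n_fp += 1
        assert n_fp / 1000 <= 0.05

    def test_matches_exhaustive_segmentation_oracle(self, rng):
        # ML placement agreement on short traces with 2 known steps
        def rss(y, bps):
            edges = [0] + list(bps) + [len(y)]
            return sum(((y[a:b] - y[a:b].mean()) ** 2).sum()
                       for a, b in zip(edges[:-1], edges[1:]))

        n = 60
        agree = total = 0
        for _ in range(40):
            s1, s2 = sorted(rng.choice(np.arange(6, 54), 2, replace=False))
            if s2 - s1 < 6:
                continue
            total += 1
            y = np.concatenate([
                np.full(s1, 8.0), np.full(s2 - s1, 4.0), np.zeros(n - s2)
            ]) + rng.normal(0, 0.4, n)
            r = photobleach.find_changepoints(_trace(y), 0.95)
            best = min(
                itertools.combinations(range(3, n - 2), 2),
                key=lambda ab: rss(y, ab) if ab[1] - ab[0] >= 3 else np.inf,
            )
            if tuple(r.step_frames) == best:
                agree += 1
        assert total >= 25
        assert agree / total >= 0.9


class TestEnsemble:
    def test_recovers_generative_parameters(self, monomer_traces):
        traces, truth, cfg = monomer_traces
        results = [photobleach.find_changepoints(t, 0.95) for t in traces]
        ens = photobleach.fit_ensemble(results, t_min=2.5 * cfg.frame_dt)
        assert ens.I_m == pytest.approx(4.4, abs=0.2)
        assert ens.tau_pb == pytest.approx(14.7, abs=1.5)

    def test_identical_brightness_degenerate_gaussian(self):
        y = np.concatenate([np.full(30, 6.0), np.zeros(30)])
        results = [photobleach.find_changepoints(_trace(y), 0.95) for _ in range(60)]
        ens = photobleach.fit_ensemble(results)
        assert ens.I_m == pytest.approx(6.0)
        assert ens.I_sd == pytest.approx(0.0, abs=1e-12)

    def test_too_few_traces_rejected(self):
        y = np.concatenate([np.full(30, 6.0), np.zeros(30)])
        results = [photobleach.find_changepoints(_trace(y), 0.95) for _ in range(10)]
        with pytest.raises(ValueError):
            photobleach.fit_ensemble(results)
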