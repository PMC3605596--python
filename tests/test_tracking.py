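"""Spot detection, localization precision and trajectory-linking tests."""

import numpy as np
import pytest

from tirftrack.mobility import fit_dlat, msd_curve
from tirftrack.simulate import MovieConfig, simulate_movie
from tirftrack.tracking import (DetectParams, LinkParams, Spot, Track,
                                default_max_displacement, detect_movie,
                                detect_spots, link_tracks, measure_fwhm)


def _spot(frame, x, y, intensity=100.0):
    return Spot(frame=frame, x=x, y=y, integrated_intensity=intensity,
                local_background=0.0)


class TestDetectSpots:
    def test_blank_frames_rarely_trigger(self, rng):
        """At a 5 SD threshold, noise-only frames yield no spots >=99% of the time."""
        hits = 0
        n = 400
        for _ in range(n):
            frame = rng.normal(20, 3, size=(60, 60))
            hits += len(detect_spots(frame, 0.1, DetectParams())) > 0
        assert hits / n <= 0.01

    def test_localization_precision_25nm(self):
        """Centroid localization RMS error stays within 25 nm at working SNR."""
        sq_err, n = 0.0, 0
        for seed in range(200):
            cfg = MovieConfig(field_width=3, field_height=3, n_frames=3,
                              receptor_density=1 / 9.0, d_lat=0.0,
                              bleach_rate=0.0, rng_seed=seed)
            stack, gt = simulate_movie(cfg)
            p = gt.data.iloc[0]
            if not (0.6 < p.x_um < 2.4 and 0.6 < p.y_um < 2.4):
                continue
            for f in range(stack.n_frames):
                spots = detect_spots(stack.frames[f], stack.pixel_size, frame=f)
                if len(spots) == 1:
                    sq_err += (spots[0].x - p.x_um) ** 2 + (spots[0].y - p.y_um) ** 2
                    n += 1
        assert n > 150
        assert np.sqrt(sq_err / n) <= 0.025

    def test_well_separated_pair_gives_two_spots(self, rng):
        cfg = MovieConfig(field_width=4, field_height=4, n_frames=1,
                          receptor_density=0.0, rng_seed=0)
        stack, _ = simulate_movie(cfg)
        frame = stack.frames[0].astype(float)
        from tirftrack.simulate import FWHM_TO_SIGMA, _render_spots
        img = np.zeros_like(frame)
        _render_spots(img, np.array([10.0, 20.0]), np.array([15.0, 15.0]),
                      np.array([500.0, 500.0]), 0.3 * FWHM_TO_SIGMA / 0.1)
        noisy = rng.poisson(img) + frame
        spots = detect_spots(noisy, 0.1)
        assert len(spots) == 2

    def test_detection_count_unbiased_at_sparse_density(self):
        """Mean detected count tracks the true count at rho ~ 0.2 um^-2."""
        cfg = MovieConfig(field_width=20, field_height=20, n_frames=100,
                          receptor_density=0.2, d_lat=0.15, bleach_rate=0.0,
                          rng_seed=31)
        stack, gt = simulate_movie(cfg)
        counts = np.array([len(s) for s in detect_movie(stack)], float)
        n_true = gt.data.particle_id.nunique()
        # compare within the searchable (border-eroded) area, allowing the
        # small pair-coalescence loss expected at a 0.4 um merge radius
        eff = (20 - 0.4) ** 2 / 400.0
        expected = n_true * eff
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        tolerance = 2 * se + 0.5 * n_true * 0.2 * np.pi * 0.4**2
        assert abs(counts.mean() - expected) < tolerance


class TestMeasureFwhm:
    def test_synthetic_psf_width(self):
        """Fitted FWHM of rendered spots is 0.30 +/- 0.02 um."""
        vals = []
        for seed in range(60):
            cfg = MovieConfig(field_width=3, field_height=3, n_frames=1,
                              receptor_density=1 / 9.0, d_lat=0.0,
                              bleach_rate=0.0, rng_seed=seed)
            stack, gt = simulate_movie(cfg)
            p = gt.data.iloc[0]
            if not (0.8 < p.x_um < 2.2 and 0.8 < p.y_um < 2.2):
                continue
            c, r = int(round(p.x_um / 0.1)), int(round(p.y_um / 0.1))
            vals.append(measure_fwhm(stack.frames[0][r - 6:r + 7, c - 6:c + 7], 0.1))
        assert np.mean(vals) == pytest.approx(0.30, abs=0.02)

    def test_exact_gaussian_fwhm(self):
        yy, xx = np.indices((15, 15))
        sigma_px = 0.1274 / 0.1
        img = 100 * np.exp(-((xx - 7.2) ** 2 + (yy - 6.9) ** 2) / (2 * sigma_px**2))
        assert measure_fwhm(img + 10, 0.1) == pytest.approx(0.30, abs=1e-3)

    def test_single_pixel_spike_flagged(self):
        img = np.ones((11, 11))
        img[5, 5] = 500.0
        assert np.isnan(measure_fwhm(img, 0.1))


class TestLinkTracks:
    def test_persistent_spot_single_track(self):
        spots = [[_spot(f, 2.0, 3.0)] for f in range(50)]
        tracks = link_tracks(spots, LinkParams())
        assert len(tracks) == 1
        assert len(tracks[0]) == 50

    def test_no_duplicate_assignment_within_frame(self, rng):
        spots = []
        for f in range(30):
            spots.append([_spot(f, 1.0 + 0.01 * rng.normal(), 1.0),
                          _spot(f, 1.3 + 0.01 * rng.normal(), 1.0)])
        tracks = link_tracks(spots, LinkParams())
        for tr in tracks:
            frames = tr.frames
            assert len(np.unique(frames)) == len(frames)
        total = sum(len(t) for t in tracks)
        assert total == 60

    def test_link_identity_accuracy_against_ground_truth(self, small_movie):
        """>=90% of frame-to-frame links join the same true particle."""
        cfg, stack, gt = small_movie
        tracks = link_tracks(detect_movie(stack), LinkParams())
        gtf = {f: g[["particle_id", "x_um", "y_um"]].to_numpy()
               for f, g in gt.data.groupby("frame")}
        good = total = 0
        for tr in tracks:
            ids = []
            for s in tr.spots:
                arr = gtf[s.frame]
                d = np.hypot(arr[:, 1] - s.x, arr[:, 2] - s.y)
                ids.append(int(arr[np.argmin(d), 0]))
            ids = np.asarray(ids)
            good += int(np.sum(ids[1:] == ids[:-1]))
            total += len(ids) - 1
        assert total > 100
        assert good / total >= 0.90

    def test_track_ends_at_bleach_frame(self):
        """A mid-movie bleach terminates the track within one frame."""
        for seed in range(40):
            cfg = MovieConfig(field_width=4, field_height=4, n_frames=60,
                              receptor_density=1 / 16.0, d_lat=0.05,
                              bleach_rate=0.5, rng_seed=seed)
            stack, gt = simulate_movie(cfg)
            g = gt.data.sort_values("frame")
            bleach_frames = g[g.bleached].frame
            if len(bleach_frames) == 0 or bleach_frames.iloc[0] < 10:
                continue
            p = g.iloc[0]
            if not (0.6 < p.x_um < 3.4 and 0.6 < p.y_um < 3.4):
                continue
            tracks = link_tracks(detect_movie(stack), LinkParams())
            assert tracks, "bright pre-bleach spot must be tracked"
            longest = max(tracks, key=len)
            assert abs(longest.end_frame - (bleach_frames.iloc[0] - 1)) <= 1
            return
        pytest.fail("no usable bleaching movie found")

    def test_immobile_spots_have_flat_msd(self):
        """Nonspecific immobile spots reproduce the static control: D < 0.005."""
        cfg = MovieConfig(field_width=15, field_height=15, n_frames=60,
                          receptor_density=0.2, d_lat=0.15, bleach_rate=0.0,
                          immobile_fraction=1.0, rng_seed=17)
        stack, _ = simulate_movie(cfg)
        tracks = link_tracks(detect_movie(stack), LinkParams())
        est = fit_dlat(msd_curve(tracks, cfg.frame_interval, max_lag=6))
        assert est.d_lat < 0.005

    def test_short_tracks_discarded(self):
        spots = [[_spot(f, 1.0, 1.0)] for f in range(3)]
        assert link_tracks(spots, LinkParams(min_length=5)) == []

    def test_empty_input(self):
        assert link_tracks([], LinkParams()) == []

    def test_default_gate_covers_brownian_steps(self):
        # >99% of 2D Brownian steps at D_max lie inside the default gate
        gate = default_max_displacement(1.0, 0.02)
        assert gate == pytest.approx(3 * np.sqrt(4 * 1.0 * 0.02))


class TestTrackValidation:
    def test_non_monotone_frames_rejected(self):
        tr = Track(0, [_spot(3, 1, 1), _spot(3, 1, 1)])
        with pytest.raises(ValueError):
            tr.validate()
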