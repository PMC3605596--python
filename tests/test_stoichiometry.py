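"""Intensity-trace extraction, step detection and trajectory-type tests."""

import numpy as np
import pytest

from tirftrack.simulate import MovieConfig, MovieStack, simulate_movie
from tirftrack.stoichiometry import (IntensityTrace, StepFit,
                                     classify_trajectory, coincidence_null,
                                     detect_steps, extract_intensity_trace,
                                     intensity_histogram, median_smooth)
from tirftrack.tracking import LinkParams, detect_movie, link_tracks


def _trace(values):
    v = np.asarray(values, dtype=float)
    return IntensityTrace(np.arange(len(v)), v)


class TestExtractIntensityTrace:
    def test_all_zero_movie_gives_zero_trace(self):
        stack = MovieStack(np.zeros((5, 30, 30), dtype=np.uint16), 0.1, 0.02)
        from tirftrack.tracking import Spot, Track
        tr = Track(0, [Spot(f, 1.5, 1.5, 0.0, 0.0) for f in range(5)])
        trace = extract_intensity_trace(stack, tr, extend=0)
        assert np.allclose(trace.values, 0.0)

    def test_monomer_trace_matches_photon_budget(self):
        """Mean counts/pixel over the 5x5 window is ~photons/25 within 2 SE."""
        cfg = MovieConfig(field_width=5, field_height=5, n_frames=60,
                          receptor_density=1 / 25.0, d_lat=0.05,
                          bleach_rate=0.0, rng_seed=14)
        stack, gt = simulate_movie(cfg)
        tracks = link_tracks(detect_movie(stack), LinkParams(min_length=20))
        assert tracks
        trace = extract_intensity_trace(stack, max(tracks, key=len), extend=0)
        vals = trace.values[trace.valid]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # the 5x5 window captures ~90% of the PSF; ring background
        # subtraction removes a little more of the tails
        expected = cfg.photons_per_spot / 25.0
        assert vals.mean() > 0.75 * expected
        assert abs(vals.mean() - 0.85 * expected) < max(4 * se, 0.1 * expected)

    def test_dimer_trace_doubles_monomer(self):
        """A coincident pair reads ~2x the single-fluorophore level."""
        base = MovieConfig(field_width=5, field_height=5, n_frames=40,
                           receptor_density=1 / 25.0, d_lat=0.0,
                           bleach_rate=0.0, rng_seed=6)
        stack1, gt1 = simulate_movie(base)
        p = gt1.data.iloc[0]
        from tirftrack.simulate import FWHM_TO_SIGMA, _render_spots
        # add a second coincident emitter on top of the first
        frames = stack1.frames.astype(float)
        for f in range(base.n_frames):
            extra = np.zeros_like(frames[f])
            _render_spots(extra, np.array([p.x_um / 0.1]), np.array([p.y_um / 0.1]),
                          np.array([base.photons_per_spot]),
                          base.psf_fwhm * FWHM_TO_SIGMA / 0.1)
            frames[f] += np.random.default_rng(f).poisson(extra)
        stack2 = MovieStack(frames.astype(np.uint16), 0.1, 0.02)
        from tirftrack.tracking import Spot, Track
        tr = Track(0, [Spot(f, p.x_um, p.y_um, 0.0, 0.0) for f in range(40)])
        t1 = extract_intensity_trace(stack1, tr, extend=0)
        t2 = extract_intensity_trace(stack2, tr, extend=0)
        ratio = t2.values[t2.valid].mean() / t1.values[t1.valid].mean()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_edge_window_flagged_invalid(self):
        stack = MovieStack(np.zeros((3, 30, 30), dtype=np.uint16), 0.1, 0.02)
        from tirftrack.tracking import Spot, Track
        tr = Track(0, [Spot(f, 0.05, 1.5, 0.0, 0.0) for f in range(3)])
        trace = extract_intensity_trace(stack, tr, extend=0)
        assert not trace.valid.any()


class TestMedianSmooth:
    def test_single_frame_spike_removed(self):
        sm = median_smooth(_trace([5, 5, 50, 5, 5]))
        assert np.allclose(sm.values, 5.0)

    def test_monotone_sequence_unchanged(self):
        v = np.arange(10, dtype=float)
        assert np.allclose(median_smooth(_trace(v)).values, v)

    def test_genuine_step_preserved(self):
        sm = median_smooth(_trace([0, 0, 0, 10, 10, 10]))
        assert np.allclose(sm.values, [0, 0, 0, 10, 10, 10])

    def test_idempotent_without_spikes(self, rng):
        v = np.concatenate([np.full(20, 10.0), np.full(20, 0.0)])
        once = median_smooth(_trace(v))
        twice = median_smooth(once)
        assert np.allclose(once.values, twice.values)


class TestDetectSteps:
    def test_noiseless_single_step_exact_frame(self):
        fit = detect_steps(_trace([10.0] * 15 + [0.0] * 15))
        assert list(fit.transitions) == [15]
        assert fit.levels == pytest.approx([10.0, 0.0])

    def test_two_step_staircase_recovery(self):
        """Both transitions found within +/-2 frames in >=95% of noisy traces."""
        rng = np.random.default_rng(7)
        ok = 0
        n = 400
        for _ in range(n):
            v = np.concatenate([np.full(20, 40.0), np.full(20, 20.0),
                                np.full(20, 0.0)])
            v += rng.normal(0, 4.0, len(v))  # noise = 20% of step height
            fit = detect_steps(median_smooth(_trace(v)), threshold_sd=4.0)
            t = fit.transitions
            ok += (len(t) == 2 and abs(t[0] - 20) <= 2 and abs(t[1] - 40) <= 2)
        assert ok / n >= 0.95

    def test_constant_noise_rarely_triggers(self):
        """<=1% of pure-noise traces produce any transition at 4 SD."""
        rng = np.random.default_rng(8)
        fp = 0
        n = 500
        for _ in range(n):
            fit = detect_steps(_trace(rng.normal(10, 2, 60)), threshold_sd=4.0)
            fp += len(fit.transitions) > 0
        assert fp / n <= 0.01

    def test_shift_invariance(self, rng):
        v = np.concatenate([np.full(25, 30.0), np.full(25, 10.0)])
        v += rng.normal(0, 2.0, len(v))
        f1 = detect_steps(_trace(v))
        f2 = detect_steps(_trace(v + 1000.0))
        assert np.array_equal(f1.transitions, f2.transitions)
        assert f2.levels - f1.levels == pytest.approx(1000.0)

    def test_short_trace_single_level(self):
        fit = detect_steps(_trace([3.0, 3.5, 2.5]))
        assert len(fit.transitions) == 0
        assert fit.levels == pytest.approx([3.0])


class TestClassifyTrajectory:
    @pytest.mark.parametrize(
        "transitions, levels, expected",
        [
            ([20], [20.0, 0.0], "type1"),       # one drop to background
            ([15, 30], [40.0, 20.0, 0.0], "type2"),  # two sequential drops
            ([15, 30], [20.0, 40.0, 0.0], "type3"),  # rise then fall
            ([10, 20, 30], [20.0, 40.0, 20.0, 0.0], "other-dimer"),
            ([10], [40.0, 0.0], "other-dimer"),  # simultaneous double drop
        ],
    )
    def test_canonical_patterns(self, transitions, levels, expected):
        fit = StepFit(np.array(transitions), np.array(levels))
        assert classify_trajectory(fit, 20.0).label == expected

    def test_higher_oligomer_flagged_unclassified(self):
        fit = StepFit(np.array([10]), np.array([60.0, 0.0]))
        t = classify_trajectory(fit, 20.0)
        assert t.label == "unclassified"
        assert t.higher_oligomer

    def test_ambiguous_level_unclassified(self):
        fit = StepFit(np.array([10]), np.array([30.0, 0.0]))  # 1.5 units
        assert classify_trajectory(fit, 20.0).label == "unclassified"

    def test_split_level_merged(self):
        # a marginal transition inside one level must not change the type
        fit = StepFit(np.array([10, 20]), np.array([20.0, 21.0, 0.0]))
        assert classify_trajectory(fit, 20.0).label == "type1"

    def test_invalid_unit_rejected(self):
        with pytest.raises(ValueError):
            classify_trajectory(StepFit(np.array([]), np.array([1.0])), 0.0)

    def test_higher_oligomer_rare_in_dimer_only_movies(self):
        """With dimers as the largest species, <1% of traces flag >=3 units."""
        cfg = MovieConfig(field_width=15, field_height=15, n_frames=120,
                          receptor_density=1.0, d_lat=0.15, bleach_rate=0.3,
                          dimer_on_rate=0.15, dimer_off_rate=1.0, rng_seed=33)
        stack, _ = simulate_movie(cfg)
        tracks = link_tracks(detect_movie(stack),
                             LinkParams(max_displacement=0.33, min_length=10,
                                        max_gap=1))
        unit = cfg.photons_per_spot * 0.85 / 25.0
        flags = 0
        for tr in tracks:
            fit = detect_steps(median_smooth(extract_intensity_trace(stack, tr)))
            flags += classify_trajectory(fit, unit).higher_oligomer
        assert len(tracks) >= 100
        assert flags / len(tracks) < 0.01


class TestIntensityHistogram:
    def test_pure_monomer_small_tail(self, rng):
        vals = rng.normal(20, 2, 2000)
        h = intensity_histogram(vals)
        assert h.mode == pytest.approx(20, rel=0.1)
        assert h.tail_fraction <= 0.05

    def test_injected_dimer_fraction_recovered(self, rng):
        """20% of spots at twice the unit level shows up as a ~20% tail."""
        vals = np.concatenate([rng.normal(20, 2, 1600), rng.normal(40, 3, 400)])
        h = intensity_histogram(vals)
        assert h.tail_fraction == pytest.approx(0.20, abs=0.05)

    def test_all_equal_zero_tail(self):
        h = intensity_histogram(np.full(300, 7.0), bins=10)
        assert h.tail_fraction == 0.0

    def test_too_few_measurements_rejected(self):
        with pytest.raises(ValueError):
            intensity_histogram(np.ones(50))


class TestCoincidenceNull:
    def test_zero_density_zero_fraction(self):
        res = coincidence_null(0.01, 0.15, 0.3, n_tracks=100, seed=1)
        assert res.fraction == 0.0

    def test_fraction_monotone_in_density(self):
        fr = [coincidence_null(rho, 0.15, 0.3, track_length_frames=50,
                               min_dwell_s=0.3, n_tracks=400, seed=2).fraction
              for rho in (0.5, 1.5, 3.0)]
        assert fr[0] <= fr[1] <= fr[2]

    def test_chance_overlap_below_observed_dimer_rate(self):
        """At the measured density/mobility, sustained chance coincidences
        account for well under the ~10% of tracks scored as dimer types."""
        res = coincidence_null(1.5, 0.15, 0.3, track_length_frames=50,
                               frame_interval=0.02, min_dwell_s=0.5,
                               n_tracks=800, seed=3)
        assert res.fraction < 0.10
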