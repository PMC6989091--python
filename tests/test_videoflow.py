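"""Kymograph velocimetry, PTV, contraction and diameter analyses."""

import numpy as np
import pytest

from cilioflow import hydro, synth, transport as tr, videoflow as vf
from cilioflow.synth import _render_spots

PX, DT = 0.189, 0.1


def _video_from(stack):
    return vf.BeadVideo(np.asarray(stack, dtype=float), PX, DT)


def _line_kymo(slopes_px_per_frame, nt=80, nx=300, width_sigma=1.0, x0=None, value=2.0):
    """Kymograph with rendered straight traces of given slopes (px/frame)."""
    img = np.ones((nt, nx))
    t = np.arange(nt)
    X = np.arange(nx)
    if x0 is None:
        x0 = np.linspace(30, nx - 30, len(slopes_px_per_frame))
    for s, xs in zip(slopes_px_per_frame, x0):
        xc = xs + s * t
        for ti in t:
            if 0 <= xc[ti] < nx:
                img[ti] += value * np.exp(-0.5 * ((X - xc[ti]) / width_sigma) ** 2)
    return vf.Kymograph(img, row=0, pixel_size_um=PX, frame_interval_s=DT)


class TestPreprocess:
    def test_identity_is_bitwise_equal(self):
        rng = np.random.default_rng(0)
        video = _video_from(rng.random((5, 32, 40)))
        out = vf.preprocess_video(video)
        assert out.stack is video.stack or np.array_equal(out.stack, video.stack)

    def test_rotation_composition(self):
        rng = np.random.default_rng(1)
        video = _video_from(rng.random((3, 33, 41)))
        twice = vf.preprocess_video(vf.preprocess_video(video, 90.0), 90.0)
        once = vf.preprocess_video(video, 180.0)
        assert twice.stack.shape == once.stack.shape
        assert np.allclose(twice.stack, once.stack, atol=1e-8)

    def test_tilted_canal_realigned_within_one_degree(self):
        """Planted 10 deg tilt is estimated and removed to <1 deg residual."""
        stack, _ = synth.make_canal_phantom(
            8.9, seed=7, tilt_deg=10.0, noise=0.5, shape_px=(160, 320)
        )
        mean_img = stack.max(axis=0)[None]
        tilt = vf.estimate_canal_tilt(mean_img[0])
        video = _video_from(np.repeat(mean_img, 2, axis=0))
        aligned = vf.preprocess_video(video, rotation_deg=tilt)
        residual = vf.estimate_canal_tilt(aligned.stack[0])
        assert abs(residual) < 1.0

    def test_bad_crop_rejected(self):
        video = _video_from(np.zeros((3, 20, 20)))
        with pytest.raises(ValueError, match="crop"):
            vf.preprocess_video(video, crop=(0, 25, 0, 10))


class TestDenoise:
    def test_clean_frames_pass_through(self):
        yy, xx = np.mgrid[:80, :80]
        frame = 100 + 50 * np.exp(-((yy - 40) ** 2 + (xx - 40) ** 2) / 50)
        video = _video_from(np.stack([frame] * 3))
        out = vf.denoise(video)
        corr = np.corrcoef(out.stack[0].ravel(), frame.ravel())[0, 1]
        assert corr > 0.99

    def test_planted_bead_snr_improves(self):
        """Beads at SNR 3 gain SNR after wavelet filtering."""
        rng = np.random.default_rng(2)
        ny = nx = 128
        spots_y, spots_x = [30.0, 64.0, 100.0], [40.0, 90.0, 60.0]
        clean = 100 + _render_spots(ny, nx, spots_y, spots_x, 30.0, 1.2)
        noisy = clean + rng.normal(0, 10.0, (ny, nx))  # peak SNR 3
        out = vf.denoise(_video_from(np.stack([noisy] * 2)))

        def snr(img):
            peaks = [img[int(y), int(x)] - np.median(img) for y, x in zip(spots_y, spots_x)]
            bg = img[5:25, 5:25]
            return np.mean(peaks) / bg.std()

        assert snr(out.stack[0]) >= snr(noisy) + 1
        assert snr(out.stack[0]) >= 4

    def test_pure_noise_variance_contracts(self):
        rng = np.random.default_rng(3)
        noisy = rng.normal(100, 8, (2, 96, 96))
        out = vf.denoise(_video_from(noisy))
        assert out.stack.var() < noisy.var()

    def test_small_frames_skipped_with_warning(self):
        video = _video_from(np.zeros((2, 32, 32)))
        with pytest.warns(UserWarning, match="too small"):
            out = vf.denoise(video)
        assert np.array_equal(out.stack, video.stack)


class TestKymograph:
    def test_constant_video_normalizes_to_ones(self):
        video = _video_from(np.full((20, 9, 50), 7.0))
        kymo = vf.build_kymograph(video, row=4)
        assert np.allclose(kymo.data, 1.0)

    def test_single_bead_traces_a_line_of_planted_slope(self):
        nt, ny, nx = 60, 9, 200
        stack = np.full((nt, ny, nx), 10.0)
        for t in range(nt):
            stack[t] += _render_spots(ny, nx, [4.0], [20 + 2.0 * t], 50, 1.2)
        kymo = vf.build_kymograph(_video_from(stack), row=4)
        peaks = np.argmax(kymo.data, axis=1)
        slope = np.polyfit(np.arange(nt), peaks, 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)

    def test_photobleaching_removed_by_column_normalization(self):
        """A static pattern with exponential decay flattens after normalization."""
        nt, nx = 50, 64
        pattern = 10 + 5 * np.sin(np.linspace(0, 6 * np.pi, nx))
        decay = np.exp(-0.02 * np.arange(nt))
        stack = (decay[:, None] * pattern[None, :])[:, None, :].repeat(5, axis=1)
        kymo = vf.build_kymograph(_video_from(stack), row=2)
        # contrast of each row of the kymograph is time-independent
        assert kymo.data.std(axis=1).std() < 1e-3

    def test_border_row_shrinks_window_with_warning(self):
        video = _video_from(np.random.default_rng(0).random((10, 6, 30)))
        with pytest.warns(UserWarning, match="border"):
            vf.build_kymograph(video, row=0)

    def test_even_window_rejected(self):
        video = _video_from(np.zeros((5, 9, 20)))
        with pytest.raises(ValueError, match="odd"):
            vf.build_kymograph(video, row=4, window=2)


class TestTraceExtraction:
    def test_blank_kymograph_yields_no_events(self):
        kymo = vf.Kymograph(np.ones((60, 100)), 0, PX, DT)
        assert vf.extract_traces(kymo) == []

    def test_diagonal_line_velocity_is_exact(self):
        """A 1 px/frame diagonal of single pixels has orientation exactly
        45 deg by symmetry of its second moments: velocity px/dt exactly."""
        img = np.ones((60, 100))
        t = np.arange(50)
        img[t + 5, t + 20] = 5.0
        kymo = vf.Kymograph(img, 0, PX, DT)
        (ev,) = vf.extract_traces(kymo)
        assert ev.velocity_um_s == pytest.approx(PX / DT, rel=1e-9)

    def test_two_px_per_frame_line(self):
        """Planted slope 2 px/frame -> 2 x 0.189/0.1 = 3.78 um/s."""
        kymo = _line_kymo([2.0], nt=60)
        (ev,) = vf.extract_traces(kymo)
        assert ev.velocity_um_s == pytest.approx(3.78, rel=0.01)
        assert ev.eccentricity > 0.9

    def test_rostral_trace_is_negative(self):
        kymo = _line_kymo([-1.5], nt=60, x0=[200])
        (ev,) = vf.extract_traces(kymo)
        assert ev.velocity_um_s == pytest.approx(-1.5 * PX / DT, rel=0.01)

    def test_stuck_bead_and_flicker_rejected(self):
        """Vertical lines (stuck beads) and horizontal lines (illumination
        flickers) are removed by the orientation filters."""
        img = np.ones((80, 120))
        img[:, 60] = 5.0  # stuck bead: same x at all times
        img[40, :] = 5.0  # global flicker: one bright frame
        kymo = vf.Kymograph(img, 0, PX, DT)
        assert vf.extract_traces(kymo) == []

    def test_exactly_k_valid_lines_survive_the_filters(self):
        """k good traces among distractors -> exactly k events."""
        kymo = _line_kymo([1.0, 2.0, -1.2], nt=80, nx=450, x0=[30, 150, 430])
        img = kymo.data
        img[:, 120] = 4.0  # stuck bead (clear of the traces)
        img[5, 200:340] += 4.0  # illumination flicker segment
        img[70:73, 390:394] += 4.0  # small blob (<15 px after threshold)
        events = vf.extract_traces(vf.Kymograph(img, 0, PX, DT))
        assert len(events) == 3
        got = sorted(e.velocity_um_s for e in events)
        want = sorted(s * PX / DT for s in (1.0, 2.0, -1.2))
        assert got == pytest.approx(want, rel=0.02)


class TestVelocityProfileAggregation:
    def test_identical_velocities_have_zero_sem(self):
        events = [
            vf.TraceEvent(2.5, row=3, time_s=i, n_pixels=20, eccentricity=0.95,
                          orientation_rad=0.9)
            for i in range(4)
        ]
        prof = vf.velocity_profile(events, n_rows=5)
        assert prof.mean[3] == pytest.approx(2.5)
        assert prof.sem[3] == pytest.approx(0.0, abs=1e-12)
        assert prof.n[3] == 4

    def test_caudal_ventral_sign_convention(self, planted_bead_analysis):
        """Beads planted flowing caudally in the ventral half give positive
        row means there."""
        prof = planted_bead_analysis["velocity_profile"]
        n_rows = prof.rows.size
        ventral_third = prof.mean[2 : n_rows // 3]
        assert np.nanmean(ventral_third) > 0

    def test_end_to_end_planted_profile_recovery(self, planted_bead_analysis):
        """The full chain recovers a planted 5 um/s biparabolic profile:
        extrema within 15%, zero crossing at 0.5 +- 0.05, null mean flow."""
        marks = planted_bead_analysis["landmarks"]
        v_ref = 4.950625  # fv d^2/(64 mu) for the planted profile, um/s
        assert marks["defined"]
        assert marks["vmax_um_s"] == pytest.approx(v_ref, rel=0.15)
        assert -marks["vmin_um_s"] == pytest.approx(v_ref, rel=0.15)
        assert marks["rel_zero"] == pytest.approx(0.5, abs=0.05)
        assert abs(marks["profile_mean_um_s"]) <= 0.3

    def test_all_positive_profile_has_no_zero_crossing(self):
        events = [
            vf.TraceEvent(1.0 + 0.1 * r, row=r, time_s=t, n_pixels=20,
                          eccentricity=0.95, orientation_rad=0.5)
            for r in range(8)
            for t in range(6)
        ]
        prof = vf.velocity_profile(events, n_rows=8)
        marks = vf.profile_landmarks(prof)
        assert not marks["defined"]


class TestFlowVsTime:
    def test_steady_bidirectional_flow_averages_to_zero(self, planted_bead_analysis):
        """All-row averaging of a zero-net-flux flow gives ~null mean."""
        events = planted_bead_analysis["events"]
        centers, mean, counts = vf.flow_vs_time(events, bin_width_s=5.0)
        assert np.abs(np.nanmean(mean)) < 0.8

    def test_planted_pulse_creates_positive_excursion(self):
        events = [
            vf.TraceEvent(0.05 * s, row=r, time_s=t + 0.01 * r, n_pixels=20,
                          eccentricity=0.95, orientation_rad=0.1 * s)
            for r in range(5)
            for t, s in [(1.0, 1), (2.0, -1), (5.0, 40), (5.3, 44), (8.0, 1)]
        ]
        centers, mean, counts = vf.flow_vs_time(events, bin_width_s=1.0)
        pulse_bin = np.argmin(np.abs(centers - 5.5))
        quiet_bin = np.argmin(np.abs(centers - 1.5))
        assert mean[pulse_bin] > 1.0
        assert abs(mean[quiet_bin]) < 0.5

    def test_empty_events_empty_series(self):
        centers, mean, counts = vf.flow_vs_time([], bin_width_s=1.0)
        assert centers.size == mean.size == counts.size == 0


class TestContractions:
    def test_constant_series_has_no_events(self):
        assert vf.detect_contractions(np.full(100, 5.0)) == []

    def test_planted_square_pulse_strength_is_exact(self):
        """|dI/dt| = 10 over 5 frames -> one event of strength 50."""
        times, intensity, _ = synth.make_contraction_series(
            [{"time_s": 5.0, "amplitude": 10.0, "duration_frames": 5}], seed=0
        )
        (ev,) = vf.detect_contractions(intensity, threshold=4.0, frame_interval_s=0.1)
        assert ev.strength == pytest.approx(50.0)
        assert ev.duration_frames == 5
        assert ev.onset_time_s == pytest.approx(5.0, abs=0.1)

    def test_two_pulses_with_subthreshold_gap_stay_separate(self):
        times, intensity, _ = synth.make_contraction_series(
            [
                {"time_s": 5.0, "amplitude": 8.0, "duration_frames": 3},
                {"time_s": 6.0, "amplitude": 12.0, "duration_frames": 2},
            ],
            seed=0,
        )
        events = vf.detect_contractions(intensity, threshold=4.0, frame_interval_s=0.1)
        assert len(events) == 2

    def test_post_contraction_flux_sign_and_truncation(self):
        events_spec = [
            {"time_s": 4.0, "amplitude": 10.0, "duration_frames": 3,
             "flow_peak_um_s": 5.0},
            {"time_s": 28.5, "amplitude": 10.0, "duration_frames": 3,
             "flow_peak_um_s": 5.0},
        ]
        times, intensity, flow = synth.make_contraction_series(events_spec, seed=0)
        dets = vf.detect_contractions(intensity, 4.0, frame_interval_s=0.1)
        res = vf.post_contraction_flux(times, flow, dets, window_s=2.5)
        assert res[0]["flow_integral"] != 0
        assert not res[0]["truncated"]
        assert res[1]["truncated"]
        # the counter-flow tail alone integrates opposite to the pulse
        i0 = int(4.0 / 0.1) + 3
        tail = np.trapezoid(flow[i0 : i0 + 25], times[i0 : i0 + 25])
        assert tail < 0

    def test_zero_flow_integrates_to_zero(self):
        dets = [vf.ContractionEvent(10, 1.0, 3, 30.0)]
        res = vf.post_contraction_flux(np.arange(0, 10, 0.1), np.zeros(100), dets)
        assert res[0]["flow_integral"] == pytest.approx(0.0)


class TestParticleTracking:
    def _drift_video(self, positions, velocity_px, nt=40, ny=60, nx=160, noise=3.0):
        rng = np.random.default_rng(5)
        stack = np.full((nt, ny, nx), 100.0)
        for t in range(nt):
            ys = [p[0] for p in positions]
            xs = [p[1] + velocity_px * t for p in positions]
            stack[t] += _render_spots(ny, nx, ys, xs, 30, 1.2)
            stack[t] += rng.normal(0, noise, (ny, nx))
        return _video_from(stack)

    def test_single_bead_drift_velocity_recovered(self):
        video = self._drift_video([(30.0, 20.0)], 1.0)
        (traj,) = vf.track_particles(video)
        assert len(traj["frames"]) == 40
        assert traj["velocity_um_s"] == pytest.approx(1.0 * PX / DT, rel=0.01)

    def test_no_beads_no_trajectories(self):
        rng = np.random.default_rng(6)
        video = _video_from(rng.normal(100, 1.0, (20, 40, 40)))
        assert vf.track_particles(video) == []

    def test_crossing_beads_keep_identity(self):
        """Total-squared-displacement assignment resolves the crossing the
        same way as brute-force enumeration of the two matchings."""
        nt, ny, nx = 40, 60, 160
        stack = np.full((nt, ny, nx), 100.0)
        rng = np.random.default_rng(7)
        for t in range(nt):
            stack[t] += _render_spots(
                ny, nx, [25.0, 35.0], [20 + 1.5 * t, 120 - 1.5 * t], 30, 1.2
            )
            stack[t] += rng.normal(0, 2, (ny, nx))
        trajs = vf.track_particles(_video_from(stack))
        assert len(trajs) == 2
        vels = sorted(t["velocity_um_s"] for t in trajs)
        assert vels[0] == pytest.approx(-1.5 * PX / DT, rel=0.05)
        assert vels[1] == pytest.approx(+1.5 * PX / DT, rel=0.05)
        # brute-force oracle: continuing straight is the cheaper matching
        a_next, b_next = 20 + 1.5 * nt / 2, 120 - 1.5 * nt / 2
        keep = 2 * 1.5**2
        swap = 2 * abs(a_next - b_next) ** 2 + keep
        assert keep < swap

    def test_ptv_agrees_with_kymograph_velocimetry(self):
        """On low-density noiseless drift data both methods agree within 5%."""
        nt, ny, nx = 60, 15, 300
        stack = np.full((nt, ny, nx), 10.0)
        for t in range(nt):
            stack[t] += _render_spots(ny, nx, [7.0], [30 + 2.0 * t], 50, 1.2)
        video = _video_from(stack)
        (traj,) = vf.track_particles(video, detection_threshold=20.0)
        kymo = vf.build_kymograph(video, row=7)
        (ev,) = vf.extract_traces(kymo)
        assert traj["velocity_um_s"] == pytest.approx(ev.velocity_um_s, rel=0.05)


class TestCanalDiameter:
    def test_phantom_width_recovered(self):
        stack, planted = synth.make_canal_phantom(8.9, seed=1)
        got = vf.measure_canal_diameter(stack, 0.189)
        assert got == pytest.approx(planted, abs=0.5)

    def test_tilt_invariance(self):
        flat, _ = synth.make_canal_phantom(8.9, seed=2, tilt_deg=0.0)
        tilted, _ = synth.make_canal_phantom(8.9, seed=2, tilt_deg=15.0)
        d0 = vf.measure_canal_diameter(flat, 0.189)
        d15 = vf.measure_canal_diameter(tilted, 0.189)
        assert d0 == pytest.approx(d15, abs=0.6)

    def test_monotone_in_planted_width(self):
        d4 = vf.measure_canal_diameter(synth.make_canal_phantom(4.0, seed=3)[0], 0.189)
        d9 = vf.measure_canal_diameter(synth.make_canal_phantom(9.0, seed=3)[0], 0.189)
        assert d4 < d9

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            vf.measure_canal_diameter(np.zeros((5, 32, 32)), 0.189)


@pytest.fixture(scope="module")
def front_series():
    D = tr.stokes_einstein(20e-9)
    d = 8.9e-6
    tau = d * d / D
    idx = np.arange(8, 150, 4)
    f0 = tr.simulate_transport(None, D, d=d, t_end=30 * tau, nx=1024, ny=32,
                               n_save=150)
    f1 = tr.simulate_transport(
        tr.biparabolic_profile(20 * D / d, d), D, t_end=30 * tau, nx=4096,
        ny=40, n_save=150
    )
    s0, t0 = synth.make_front_series(f0, seed=8, frame_indices=idx)
    s1, t1 = synth.make_front_series(f1, seed=8, frame_indices=idx)
    return (s0, t0), (s1, t1)


class TestBeadFront:
    def test_no_flow_front_is_diffusive(self, front_series):
        (s0, t0), _ = front_series
        fronts, slope = vf.track_bead_front(s0, t0, pixel_size_um=1.5, row=20)
        assert slope == pytest.approx(0.5, abs=0.1)

    def test_flow_front_leads_no_flow_front(self, front_series):
        (s0, t0), (s1, t1) = front_series
        f0, _ = vf.track_bead_front(s0, t0, pixel_size_um=1.5, row=20)
        f1, _ = vf.track_bead_front(s1, t1, pixel_size_um=1.5, row=20)
        sel = ~np.isnan(f0) & ~np.isnan(f1)
        assert np.all(f1[sel][5:] >= f0[sel][5:])
        assert np.nanmax(f1 - f0) > 0

    def test_zero_concentration_gives_nan(self):
        stack = np.zeros((4, 40, 60))
        fronts, slope = vf.track_bead_front(stack, np.arange(1.0, 5.0), 1.5, row=20)
        assert np.all(np.isnan(fronts))
        assert np.isnan(slope)
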