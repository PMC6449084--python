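"""Ground-truth integrity of the synthetic generators."""

import numpy as np
import pytest
from scipy import stats

from zfswim.calcium import gcamp_kernel
from zfswim.ephys import windowed_sd, input_resistance, cycle_recruitment
from zfswim.synth import SynthConfig, make_kinematics
from zfswim.synth.calcium import CellSpec, make_calcium_movie
from zfswim.synth.fictive import FictiveEpisodeSpec, make_fictive_trace
from zfswim.synth.generate import draw_first_bend_amplitudes
from zfswim.synth.render import BodyModel, render_frames, render_silhouette
from zfswim.synth.vm import make_vm_sweep, threshold_rule


class TestKinematicsGenerator:
    def test_zero_rate_gives_silent_record(self, config):
        cfg = SynthConfig(episode_rate_hz=0.0)
        kin, truth = make_kinematics(cfg, duration_s=5.0, seed=0)
        assert np.all(kin.K == 0)
        assert truth.episodes == []

    def test_forced_scoot_amplitude_is_exact(self, config):
        kin, truth = make_kinematics(
            config, duration_s=2.0, seed=0,
            episodes=[{"onset_s": 0.5, "category": "scoot", "amplitude_deg": 20.0}],
        )
        assert len(truth.episodes) == 1
        ep = truth.episodes[0]
        sel = (kin.t >= ep.onset_s) & (kin.t <= ep.offset_s)
        assert abs(np.max(np.abs(kin.K[sel])) - 20.0) < 1e-6
        # every bend peak is recorded and lands exactly on the grid
        for t_pk, amp in zip(ep.bend_peak_times_s, ep.bend_amplitudes_deg):
            i = int(round(t_pk * config.frame_rate_hz))
            assert abs(abs(kin.K[i]) - amp) < 1e-9

    def test_nonpositive_duration_rejected(self, config):
        with pytest.raises(ValueError):
            make_kinematics(config, duration_s=0.0, seed=0)

    def test_bad_mixture_weights_rejected(self):
        cfg = SynthConfig()
        with pytest.raises(ValueError):
            SynthConfig(categories={
                k: v for k, v in cfg.categories.items()
            } | {"scoot": type(cfg.categories["scoot"])(
                0.9, 20.0, 4.5, (26.0, 34.0), (16, 24))})

    def test_category_proportions_match_weights(self, config):
        """Empirical proportions at n=1000 stay inside exact binomial 99% CIs."""
        amps, labels = draw_first_bend_amplitudes(config, 1000, seed=7)
        n = len(labels)
        for cat, w in zip(config.spontaneous_categories, config.spontaneous_weights):
            k = int(np.sum(labels == cat))
            lo = stats.binom.ppf(0.005, n, w)
            hi = stats.binom.ppf(0.995, n, w)
            assert lo <= k <= hi, f"{cat}: {k} outside [{lo}, {hi}]"

    def test_amplitude_mixture_goodness_of_fit(self, config):
        """Pooled first-bend amplitudes pass a KS test against the
        configured three-component mixture at n=5000."""
        amps, _ = draw_first_bend_amplitudes(config, 5000, seed=3)
        cats = config.spontaneous_categories
        w = np.asarray(config.spontaneous_weights)
        w = w / w.sum()

        def mix_cdf(x):
            return sum(
                wi * stats.norm.cdf(x, config.categories[c].amp_mean_deg,
                                    config.categories[c].amp_sd_deg)
                for wi, c in zip(w, cats)
            )

        p = stats.kstest(amps, mix_cdf).pvalue
        assert p > 0.01

    def test_reproducibility_bit_identical(self, config):
        a = make_kinematics(config, duration_s=20.0, seed=5)
        b = make_kinematics(config, duration_s=20.0, seed=5)
        assert np.array_equal(a[0].K, b[0].K)
        assert np.array_equal(a[0].head_xy, b[0].head_xy)
        assert [e.onset_s for e in a[1].episodes] == [e.onset_s for e in b[1].episodes]

    def test_episodes_non_overlapping_and_ordered(self, spontaneous_record):
        _, truth = spontaneous_record
        eps = truth.episodes
        assert all(b.onset_s >= a.offset_s for a, b in zip(eps, eps[1:]))
        assert all(e.first_bend_amplitude_deg > 0 for e in eps)


class TestRenderer:
    def test_noiseless_stationary_frames_identical(self, stationary_stack):
        _, stack, _, _ = stationary_stack
        assert np.array_equal(stack.frames[0], stack.frames[-1])

    def test_noisy_temporal_mean_matches_noiseless(self, noiseless_config):
        """Per-pixel temporal mean over 1000 frames is within 3 standard
        errors of the noiseless frame."""
        cfg = SynthConfig()  # default sensor noise
        kin, _ = make_kinematics(cfg, duration_s=2.0, seed=1, episodes=[])
        noisy, _ = render_frames(kin, None, cfg, seed=4)
        kin0, _ = make_kinematics(noiseless_config, duration_s=0.002, seed=1, episodes=[])
        clean, _ = render_frames(kin0, None, noiseless_config, seed=0)
        se = cfg.sensor_noise_sd / np.sqrt(noisy.n_frames)
        dev = np.abs(noisy.frames.mean(axis=0) - clean.frames[0])
        assert np.mean(dev <= 3 * se) > 0.99

    def test_silhouette_matches_bruteforce_rasterization(self, stationary_stack):
        """The rendered frame equals an independent per-pixel loop
        rasterisation of the body model (distance to midline polyline,
        width/intensity lookup, coverage blend), and the ≥50%-coverage
        pixel sets agree."""
        kin, stack, midlines, bg = stationary_stack
        cfg = SynthConfig(sensor_noise_sd=0.0)
        body = BodyModel(length_mm=cfg.fish_length_mm)
        frame = stack.frames[0]

        pts = midlines[0] / cfg.pixel_size_mm
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0], np.cumsum(seg)])
        s_pt = arc / arc[-1]
        y0 = int(pts[:, 1].min() - 12)
        y1 = int(pts[:, 1].max() + 12)
        x0 = int(pts[:, 0].min() - 12)
        x1 = int(pts[:, 0].max() + 12)
        oracle = np.full_like(frame, cfg.background_level)
        inside_oracle = np.zeros_like(frame, dtype=bool)
        for y in range(y0, y1):
            for x in range(x0, x1):
                best, best_s = np.inf, 0.0
                for i in range(len(pts) - 1):
                    a, b = pts[i], pts[i + 1]
                    ab = b - a
                    tt = np.clip(np.dot([x - a[0], y - a[1]], ab) / np.dot(ab, ab), 0, 1)
                    d = np.hypot(x - (a[0] + tt * ab[0]), y - (a[1] + tt * ab[1]))
                    if d < best:
                        best, best_s = d, s_pt[i] + tt * (s_pt[i + 1] - s_pt[i])
                hw = body.half_width(np.array([best_s]))[0] / cfg.pixel_size_mm
                alpha = np.clip(hw - best + 0.5, 0.0, 1.0)
                fish_val = body.surface_intensity(np.array([best_s]))[0]
                oracle[y, x] = (1 - alpha) * cfg.background_level + alpha * fish_val
                inside_oracle[y, x] = best <= hw
        # pixel-exact agreement proves both the geometry (distance and
        # arc-position lookups) and the coverage blending
        assert np.allclose(frame, oracle, atol=1e-6)
        assert inside_oracle.sum() > 300  # the body covers a plausible area

    def test_out_of_frame_fish_raises(self, noiseless_config):
        kin, _ = make_kinematics(noiseless_config, duration_s=0.002, seed=1, episodes=[])
        kin.head_xy[:] = (0.2, 0.2)  # mm, almost at the corner
        with pytest.raises(ValueError):
            render_frames(kin, None, noiseless_config, seed=0)


class TestFictiveGenerator:
    def test_empty_schedule_is_pure_noise(self, config):
        trace, labels = make_fictive_trace([], config.fictive_fs_hz, 0.05, seed=0,
                                           duration_s=2.0)
        assert labels == []
        p = windowed_sd(trace.left, trace.fs, 0.010)
        w = int(round(0.010 * trace.fs))
        # E[sample SD] of Gaussian noise = c4(w) * sigma with the exact
        # small-sample correction c4 = sqrt(2/(n-1)) * G(n/2)/G((n-1)/2)
        from scipy.special import gammaln

        c4 = np.sqrt(2.0 / (w - 1)) * np.exp(gammaln(w / 2) - gammaln((w - 1) / 2))
        assert abs(p[w:-w].mean() - c4 * 0.05) < 0.002

    def test_burst_count_matches_schedule(self, config):
        spec = FictiveEpisodeSpec(0.5, 1.0, 20.0, 1.0, 1.0, "weak")
        trace, _ = make_fictive_trace([spec], config.fictive_fs_hz, 0.0, seed=0,
                                      duration_s=2.0)
        # count left bursts directly on the noiseless waveform (close the
        # sub-ms zeros of the rectified carrier before counting onsets)
        from scipy.ndimage import maximum_filter1d

        active = maximum_filter1d(
            (np.abs(trace.left) > 0.01).astype(int), int(0.003 * trace.fs)
        )
        n_bursts = int((np.diff(active) == 1).sum())
        assert abs(n_bursts - 20) <= 1

    def test_overlapping_schedule_rejected(self, config):
        a = FictiveEpisodeSpec(0.5, 1.0, 20.0, 1.0, 1.0, "weak")
        b = FictiveEpisodeSpec(1.0, 1.0, 20.0, 1.0, 1.0, "weak")
        with pytest.raises(ValueError):
            make_fictive_trace([a, b], config.fictive_fs_hz, 0.0, seed=0)

    def test_antiphase_sides(self, config):
        spec = FictiveEpisodeSpec(0.1, 0.5, 20.0, 1.0, 1.0, "weak")
        trace, _ = make_fictive_trace([spec], config.fictive_fs_hz, 0.0, seed=0)
        # left and right bursts never overlap in time
        both = (np.abs(trace.left) > 0.01) & (np.abs(trace.right) > 0.01)
        assert not both.any()


class TestCalciumGenerator:
    def test_zero_amplitude_movie_is_baseline(self, config):
        sig = np.zeros(500)
        sig[100:150] = 1.0
        movie, truth = make_calcium_movie(
            [CellSpec((0, 1, 1), "s", 0.0)], {"s": (sig, 100.0)}, config, seed=0,
            shape_zyx=(1, 4, 4), noise_sd=0.0,
        )
        assert not truth.any()
        assert np.allclose(movie.data, config.baseline_f0)

    def test_noiseless_responder_matches_kernel_convolution(self, config):
        fs = 100.0
        sig = np.zeros(2000)
        sig[200:260] = 1.0
        movie, truth = make_calcium_movie(
            [CellSpec((0, 2, 2), "s", 50.0)], {"s": (sig, fs)}, config, seed=0,
            shape_zyx=(1, 5, 5), noise_sd=0.0,
        )
        from zfswim.calcium import extract_dff

        roi = np.zeros((1, 5, 5), dtype=bool)
        roi[0, 2, 2] = True
        tr = extract_dff(movie, roi)
        # expected: amplitude × unit-peak kernel response / F0
        t_k = np.arange(0, 8.0, 1.0 / fs)
        h = gcamp_kernel(t_k, config.tau_rise_s, config.tau_decay_s)
        conv = np.convolve(sig, h)[: len(sig)]
        conv /= conv.max()
        expected_peak = 50.0 * 1.0 / tr.F0
        assert abs(tr.dff.max() - expected_peak) < 1e-6

    def test_cell_outside_volume_rejected(self, config):
        sig = np.ones(100)
        with pytest.raises(ValueError):
            make_calcium_movie([CellSpec((5, 0, 0), "s", 1.0)], {"s": (sig, 100.0)},
                               config, seed=0, shape_zyx=(1, 4, 4))


class TestVmGenerator:
    def test_silent_rule_produces_no_activity(self):
        cycles = [(0.5, 30.0), (0.6, 30.0)]
        sweep = make_vm_sweep(cycles, lambda f: 0.0, seed=0)
        cyc = [(t, t + 1 / f, f) for t, f in cycles]
        rec = cycle_recruitment(sweep, cyc, episode_onset_s=0.5)
        assert all(r.n_spikes == 0 for r in rec)
        assert all(abs(r.max_depolarization_mv) < 0.5 for r in rec)

    def test_rule_firing_only_above_35hz(self):
        cycles = [(0.5, 20.0), (0.6, 50.0)]
        sweep = make_vm_sweep(cycles, threshold_rule(), seed=0)
        cyc = [(t, t + 1 / f, f) for t, f in cycles]
        rec = cycle_recruitment(sweep, cyc, episode_onset_s=0.5)
        assert rec[0].speed_class == "slow" and rec[0].n_spikes == 0
        assert rec[1].speed_class == "fast" and rec[1].n_spikes > 0

    def test_input_resistance_recovered_by_ohms_law(self):
        """Hyperpolarising 50 pA steps on a passive 100 MΩ membrane."""
        steps = [(-50.0, 0.2 + 0.4 * i, 0.2) for i in range(5)]
        sweep = make_vm_sweep([], lambda f: 0.0, seed=1, current_steps=steps,
                              duration_s=2.4, noise_sd_mv=0.1)
        assert abs(input_resistance(sweep) - 100.0) / 100.0 < 0.02

    def test_unordered_cycles_rejected(self):
        with pytest.raises(ValueError):
            make_vm_sweep([(0.6, 30.0), (0.5, 30.0)], lambda f: 0.0, seed=0)
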