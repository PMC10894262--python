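"""Synthetic strip simulator: kinetics oracle, rendering, panels, determinism."""

import numpy as np
import pytest

import lfaseq as L
from lfaseq.simulate import region_contrast


def line_cols(layout):
    half = layout.line_width_px // 2
    lo = layout.test_line_center_px - half
    return lo, lo + layout.line_width_px


NOISELESS = L.NoiseSpec(pixel_sigma=0.0, illum_gain_sigma=0.0, seed=0)


class TestExpectedLineContrast:
    def test_zero_at_arrival_and_for_blank(self, kinetics):
        assert L.expected_line_contrast(kinetics, 5.0,
                                        kinetics.arrival_time_s) == 0.0
        assert L.expected_line_contrast(kinetics, 0.0, 600.0) == 0.0

    def test_saturation_limit(self):
        kin = L.KineticParams(sat_amplitude_A_max=0.8, half_sat_conc_K=5.0,
                              dev_rate_k=0.05)
        assert L.expected_line_contrast(kin, 5.0, 1e9) == pytest.approx(0.4)

    def test_monotone_in_time_and_concentration(self, kinetics):
        times = np.linspace(0, 300, 40)
        vals = [L.expected_line_contrast(kinetics, 3.0, t) for t in times]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        concs = np.linspace(0, 100, 40)
        vals = [L.expected_line_contrast(kinetics, c, 120.0) for c in concs]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self, kinetics):
        with pytest.raises(ValueError):
            L.expected_line_contrast(kinetics, -1.0, 10.0)
        with pytest.raises(ValueError):
            L.expected_line_contrast(kinetics, 1.0, -10.0)


class TestSimulateSequence:
    def test_blank_strip_has_no_test_line(self, layout, kinetics, acq):
        seq, truth = L.simulate_sequence(layout, kinetics, 0.0, acq, NOISELESS)
        lo, hi = line_cols(layout)
        checked = 0
        for frame, t in zip(seq.frames, seq.timestamps_s):
            # compare only when the neighborhood is uniformly wet or dry
            # (the advancing front briefly straddles these columns)
            front = layout.test_line_center_px * np.sqrt(
                t / kinetics.arrival_time_s)
            if lo - layout.line_width_px <= front < hi:
                continue
            # test-line band indistinguishable from neighboring membrane
            assert np.array_equal(frame[:, lo:hi],
                                  frame[:, lo - layout.line_width_px:lo])
            checked += 1
        assert checked >= 10
        assert truth.level == 0
        assert truth.class_label is L.ClassLabel.NEGATIVE

    def test_no_signal_before_arrival(self, layout, kinetics):
        """Frames at 10/20/30 s carry no test-line signal (arrival ~30 s)."""
        acq = L.AcquisitionSpec(duration_s=30 + 1e-6, interval_s=10)
        with pytest.raises(ValueError):
            # arrival >= duration is an unusable acquisition
            L.simulate_sequence(layout, kinetics, 5.0,
                                L.AcquisitionSpec(duration_s=30, interval_s=10),
                                NOISELESS, level=4)
        seq, _ = L.simulate_sequence(layout, kinetics, 50.0, acq, NOISELESS,
                                     level=8)
        blank, _ = L.simulate_sequence(layout, kinetics, 0.0, acq, NOISELESS)
        # identical to a blank strip frame-for-frame while t <= arrival
        assert np.array_equal(seq.frames, blank.frames)

    def test_noiseless_contrast_matches_oracle(self, layout, kinetics, acq):
        """Measured ROI contrast equals the closed form within quantization.

        The background-subtracted estimator is exact once its flanking
        reference bands are uniformly wet, i.e. after the front passes them.
        """
        ladder = L.serial_dilution(50, 2, 8)
        lo, hi = line_cols(layout)
        bands_wet_px = hi + 12  # right reference band fully wetted
        t_wet = kinetics.arrival_time_s * (
            bands_wet_px / layout.test_line_center_px) ** 2
        for c in (50.0, 3.125, 0.390625):
            seq, _ = L.simulate_sequence(layout, kinetics, c, acq, NOISELESS,
                                         ladder=ladder)
            checked = 0
            for frame, t in zip(seq.frames, seq.timestamps_s):
                if t < t_wet:
                    continue
                expected = L.expected_line_contrast(kinetics, c, t)
                assert region_contrast(frame, lo, hi) == \
                    pytest.approx(expected, abs=1.0 / 255)
                checked += 1
            assert checked >= 8

    def test_monte_carlo_mean_matches_oracle(self, layout, kinetics, acq):
        """Mean noisy ROI contrast over 200 seeds within 3 SEM of closed form."""
        c = kinetics.half_sat_conc_K
        lo, hi = line_cols(layout)
        vals = []
        for seed in range(200):
            seq, _ = L.simulate_sequence(layout, kinetics, c, acq,
                                         L.NoiseSpec(seed=seed), level=4)
            vals.append(region_contrast(seq.frames[-1], lo, hi))
        vals = np.asarray(vals)
        oracle = L.expected_line_contrast(kinetics, c, acq.duration_s)
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - oracle) <= 3 * sem

    def test_monotone_in_concentration_and_time(self, layout, kinetics, acq):
        lo, hi = line_cols(layout)
        ladder = L.serial_dilution(50, 2, 8)
        t_wet = kinetics.arrival_time_s * ((hi + 12)
                                           / layout.test_line_center_px) ** 2
        finals = []
        for c in ladder.concentrations:
            seq, _ = L.simulate_sequence(layout, kinetics, c, acq, NOISELESS,
                                         ladder=ladder)
            finals.append(region_contrast(seq.frames[-1], lo, hi))
            series = [region_contrast(f, lo, hi)
                      for f, t in zip(seq.frames, seq.timestamps_s)
                      if t >= t_wet]
            assert len(series) >= 8
            assert all(b - a > -1.0 / 255 for a, b in zip(series, series[1:]))
        assert all(a > b for a, b in zip(finals, finals[1:]))

    def test_control_line_develops_for_every_record(self, layout, kinetics,
                                                    acq):
        half = layout.line_width_px // 2
        lo = layout.control_line_center_px - half
        for c, level in [(0.0, 0), (0.390625, 1), (50.0, 8)]:
            seq, _ = L.simulate_sequence(layout, kinetics, c, acq, NOISELESS,
                                         level=level)
            contrast = region_contrast(seq.frames[-1], lo,
                                       lo + layout.line_width_px)
            assert contrast >= 0.5 * kinetics.control_amplitude

    def test_bit_identical_under_seed(self, layout, kinetics, acq):
        a, _ = L.simulate_sequence(layout, kinetics, 6.25, acq,
                                   L.NoiseSpec(seed=42), level=5)
        b, _ = L.simulate_sequence(layout, kinetics, 6.25, acq,
                                   L.NoiseSpec(seed=42), level=5)
        c, _ = L.simulate_sequence(layout, kinetics, 6.25, acq,
                                   L.NoiseSpec(seed=43), level=5)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_positive_concentration_needs_level_or_ladder(self, layout,
                                                          kinetics, acq):
        with pytest.raises(ValueError):
            L.simulate_sequence(layout, kinetics, 5.0, acq, NOISELESS)


class TestSimulatePanel:
    def test_record_count_and_blank_labels(self, layout, kinetics, acq):
        ladder = L.serial_dilution(50, 2, 8)
        manifest = L.simulate_panel(ladder, 3, 6, layout, kinetics, acq,
                                    L.NoiseSpec(seed=1))
        assert len(manifest) == 8 * 3 + 6
        blanks = [r for r in manifest.records if r.concentration == 0]
        assert len(blanks) == 6
        assert all(r.level == 0 and r.class_label is L.ClassLabel.NEGATIVE
                   for r in blanks)

    def test_total_frames_cross_module(self, layout, kinetics, acq):
        ladder = L.serial_dilution(50, 2, 4)
        manifest = L.simulate_panel(ladder, 2, 2, layout, kinetics, acq,
                                    L.NoiseSpec(seed=1))
        per_record = len(L.frame_grid(acq.duration_s, acq.interval_s))
        assert L.count_frames(manifest) == len(manifest) * per_record

    def test_panel_written_to_disk_round_trips(self, tmp_path, layout,
                                               kinetics, acq):
        from lfaseq.io import read_sequence
        ladder = L.serial_dilution(50, 2, 2)
        manifest = L.simulate_panel(ladder, 1, 1, layout, kinetics, acq,
                                    L.NoiseSpec(seed=2), out_dir=tmp_path)
        for record in manifest.records:
            seq = read_sequence(tmp_path / record.image_dir,
                                record.timestamps_s)
            assert np.array_equal(seq.frames, record.sequence.frames)

    def test_deterministic_under_seed(self, layout, kinetics, acq):
        ladder = L.serial_dilution(50, 2, 3)
        a = L.simulate_panel(ladder, 2, 1, layout, kinetics, acq,
                             L.NoiseSpec(seed=9))
        b = L.simulate_panel(ladder, 2, 1, layout, kinetics, acq,
                             L.NoiseSpec(seed=9))
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.sequence.frames, rb.sequence.frames)
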