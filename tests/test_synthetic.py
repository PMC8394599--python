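"""Synthetic-data generator: shapes, cohort statistics, raw sessions."""

import numpy as np
import pytest
from scipy import stats as sst

from ansq.errors import ConfigError
from ansq.matching import transform_template
from ansq.preprocess import (compute_heart_rate, compute_map_series,
                             detect_r_peaks, notch_filter)
from ansq.protocol import TEST_DEFINITIONS
from ansq.synthetic import (SHAPES, canonical_template,
                            canonical_template_keys, make_session_manifest,
                            make_template_shape, simulate_cohort,
                            simulate_raw_session, simulate_response)


class TestShapes:
    def test_catalog_covers_gated_cells(self):
        assert len(SHAPES) == 20
        assert len(canonical_template_keys()) == 19
        # every shape belongs to a defined test/epoch
        for test, epoch, _mod in SHAPES:
            names = [e.name for e in TEST_DEFINITIONS[test].epochs]
            assert epoch in names

    def test_physiologic_directions(self):
        g = make_template_shape
        assert g("squat", "squat", "MAP").max() > 0.1          # pressor
        assert g("diving_reflex", "mask_on", "HR").min() < -0.1  # bradycardia
        assert g("cold_pressor", "hand_in", "MAP").max() > 0.1
        assert g("deep_breathing", "first_2min", "RMSSD").max() > 0.2

    def test_gamma_pulse_peak(self):
        spec = SHAPES[("squat", "squat", "MAP")]
        t = np.linspace(0.0, 60.0, 6001)
        f = spec.evaluate(t)
        assert f.max() == pytest.approx(abs(spec.amp), rel=1e-4)
        assert t[np.argmax(f)] == pytest.approx(spec.tau, abs=0.02)
        np.testing.assert_array_equal(spec.evaluate(np.array([-1.0, 0.0])), 0.0)

    def test_unknown_cell_is_error(self):
        with pytest.raises(ConfigError):
            make_template_shape("squat", "squat", "EDA")

    def test_canonical_template_gated_in(self, squat_map_template):
        assert squat_map_template.sig is True
        assert squat_map_template.t[0] == 0.0


class TestSimulateResponse:
    def test_identity_parameters_reproduce_template(self, squat_map_template):
        tr = simulate_response(squat_map_template)
        np.testing.assert_allclose(tr.y, squat_map_template.f)

    def test_known_transform(self, squat_map_template):
        tr = simulate_response(squat_map_template, duration=2.0, delay=1.0,
                               amplitude=1.5, offset=0.1)
        expect = transform_template(squat_map_template, 0.5, 1.0, 1.5, 0.1)
        np.testing.assert_allclose(tr.y, expect)

    def test_noise_variance_chi2_bound(self, squat_map_template, rng):
        sigma = 0.05
        n_tot = 0
        ss = 0.0
        for _ in range(20):
            tr = simulate_response(squat_map_template, noise_sigma=sigma,
                                   rng=rng)
            r = tr.y - squat_map_template.f
            ss += float(r @ r)
            n_tot += r.size
        # pooled SSE/sigma^2 ~ chi2(n_tot); accept the central 99.9% band
        lo, hi = sst.chi2.ppf([0.0005, 0.9995], n_tot)
        assert lo < ss / sigma**2 < hi

    def test_nonpositive_duration_rejected(self, squat_map_template):
        with pytest.raises(Exception):
            simulate_response(squat_map_template, duration=0.0)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(cells=[("squat", "squat", "MAP"),
                                  ("squat", "squat", "RMSSD")], seed=3)


class TestSimulateCohort:
    def test_structure_counts(self, cohort):
        traces, truth = cohort
        assert len(traces) == 21 * 4 * 2
        assert len(truth.subjects) == 21
        assert len(truth.cells) == 21 * 4 * 2
        sexes = [s["sex"] for s in truth.subjects.values()]
        assert sexes.count("M") == 16 and sexes.count("F") == 5

    def test_session_time_of_day(self, cohort):
        traces, _ = cohort
        for tr in traces:
            assert tr.time_of_day == ("AM" if tr.session <= 2 else "PM")

    def test_truth_parameter_ranges(self, cohort):
        _, truth = cohort
        for (sid, sess, test, epoch, mod), p in truth.cells.items():
            assert 0.5 <= p["duration"] <= 2.0
            assert abs(p["delay"]) <= 6.0  # 10% of the 60 s epoch
            assert p["amplitude"] >= 0.1

    def test_sympathetic_amplitude_tracks_bmi(self):
        traces, truth = simulate_cohort(
            cells=[("squat", "squat", "MAP")], subject_amp_sd=0.0,
            session_amp_sd=0.0, seed=5)
        bmi = np.array([truth.subjects[s]["bmi"] for s in truth.subjects])
        amp = np.array([truth.subjects[s]["amp_sympathetic"]
                        for s in truth.subjects])
        coef = np.polyfit(bmi, amp, 1)[0]
        assert coef == pytest.approx(0.05, rel=1e-6)

    def test_noise_sigma_convention(self, cohort):
        _, truth = cohort
        by_cell = truth.params["noise_sigma_by_cell"]
        peak = float(np.max(np.abs(canonical_template(
            "squat", "squat", "MAP").f)))
        assert by_cell["squat/squat/MAP"] == pytest.approx(0.1 * peak)

    def test_deterministic_for_seed(self):
        kw = dict(cells=[("squat", "squat", "MAP")], n_subjects=3,
                  sessions_per_subject=2)
        t1, _ = simulate_cohort(seed=9, **kw)
        t2, _ = simulate_cohort(seed=9, **kw)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.y, b.y)
        t3, _ = simulate_cohort(seed=10, **kw)
        assert not np.array_equal(t1[0].y, t3[0].y)

    def test_ampm_gain_applied(self):
        _, truth = simulate_cohort(
            cells=[("squat", "squat", "MAP")], n_subjects=4,
            subject_amp_sd=0.0, session_amp_sd=0.0,
            ampm_amp_gain={"PM": {"S": 1.5}}, seed=2)
        for (sid, sess, *_), p in truth.cells.items():
            ref = truth.cells[(sid, 1, "squat", "squat", "MAP")]
            if sess > 2:
                assert p["amplitude"] == pytest.approx(
                    1.5 * ref["amplitude"], rel=1e-9)


class TestManifestLayout:
    def test_full_session_valid_and_complete(self):
        m = make_session_manifest()
        assert set(m.tests_present()) == set(TEST_DEFINITIONS)
        times = [t for _, _, t in m.events]
        assert times == sorted(times)

    def test_baseline_spacing(self):
        m = make_session_manifest(tests=["squat", "cold_pressor"])
        assert m.phase_time("squat", "stand_pre") == 130.0
        # squat runs 180 s, then another 130 s rest
        assert m.phase_time("cold_pressor", "hand_in") == 130.0 + 180.0 + 130.0


@pytest.fixture(scope="module")
def quiet():
    m = make_session_manifest(tests=["squat"])
    rec = simulate_raw_session({}, m)
    return m, rec


class TestRawSession:
    def test_channels_present(self, quiet):
        _, rec = quiet
        assert {"ECG", "BP", "RESP", "EDA", "PUPIL", "GAZE"} <= set(rec.channels)
        assert rec.fs == 1000.0

    def test_quiet_session_ibi_1000ms(self, quiet):
        _, rec = quiet
        beats = detect_r_peaks(rec.channels["ECG"], rec.fs)
        ibi = np.diff(beats.r_peak_times) * 1000.0
        assert np.abs(ibi - 1000.0).max() <= 2.0

    def test_quiet_session_map_90(self, quiet):
        _, rec = quiet
        beats = detect_r_peaks(rec.channels["ECG"], rec.fs)
        m = compute_map_series(rec.channels["BP"], rec.fs, beats)
        assert np.abs(m.v - 90.0).max() <= 1.0

    def test_injected_map_response_visible(self):
        m = make_session_manifest(tests=["squat"])
        truth = {("squat", "squat", "MAP"):
                 dict(duration=1.0, delay=0.0, amplitude=1.0, offset=0.0)}
        rec = simulate_raw_session(truth, m)
        beats = detect_r_peaks(rec.channels["ECG"], rec.fs)
        mp = compute_map_series(rec.channels["BP"], rec.fs, beats)
        t_sq = m.phase_time("squat", "squat")
        during = mp.v[(mp.t > t_sq + 10) & (mp.t < t_sq + 20)]
        before = mp.v[mp.t < t_sq - 10]
        # canonical squat MAP peak is +18% of the 90 mmHg operating point
        assert during.max() - before.mean() > 0.1 * 90.0

    def test_line_noise_removed_by_notch(self):
        m = make_session_manifest(tests=["squat"])
        clean = simulate_raw_session({}, m, seed=1)
        noisy = simulate_raw_session({}, m, line_noise_mv=0.2, seed=1)
        ecg_f = notch_filter(noisy.channels["ECG"], noisy.fs)
        hr_c = compute_heart_rate(detect_r_peaks(clean.channels["ECG"], 1000.0))
        hr_n = compute_heart_rate(detect_r_peaks(ecg_f, 1000.0))
        n = min(hr_c.v.size, hr_n.v.size)
        rel = np.abs(hr_n.v[:n] - hr_c.v[:n]) / hr_c.v[:n]
        assert rel.max() <= 0.01

    def test_deterministic(self):
        m = make_session_manifest(tests=["squat"])
        a = simulate_raw_session({}, m, base_rmssd_ms=20.0, seed=7)
        b = simulate_raw_session({}, m, base_rmssd_ms=20.0, seed=7)
        np.testing.assert_array_equal(a.channels["ECG"], b.channels["ECG"])
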