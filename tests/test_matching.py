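"""Template-transform fitting: objective, optimizer, and oracles."""

from types import SimpleNamespace

import numpy as np
import pytest

from ansq.errors import DataError
from ansq.matching import (MatchConfig, MatchResult, brute_force_fit,
                           deep_breathing_cohort_features,
                           deep_breathing_feature, fit_template,
                           objective_value, transform_template)
from ansq.template import Template
from conftest import make_trace


class TestTransform:
    def test_identity_transform(self, squat_map_template):
        tpl = squat_map_template
        g = transform_template(tpl, 1.0, 0.0, 1.0, 0.0)
        np.testing.assert_allclose(g, tpl.f)

    def test_scale_and_offset(self, squat_map_template):
        tpl = squat_map_template
        g = transform_template(tpl, 1.0, 0.0, 2.0, 0.3)
        np.testing.assert_allclose(g, 2.0 * tpl.f + 0.3)

    def test_b_shifts_right(self, squat_map_template):
        tpl = squat_map_template
        g = transform_template(tpl, 1.0, 2.0, 1.0, 0.0)
        # g(x) = f(x - 2): the response is delayed by 2 s
        k = int(2.0 * 4)  # samples at 4 Hz
        np.testing.assert_allclose(g[k:], tpl.f[:-k], atol=1e-12)

    def test_a_compresses_duration(self, squat_map_template):
        tpl = squat_map_template
        g = transform_template(tpl, 2.0, 0.0, 1.0, 0.0)
        # g(x) = f(2x): the template is swept twice as fast
        i_peak_g = np.argmax(g)
        i_peak_f = np.argmax(tpl.f)
        assert tpl.t[i_peak_g] == pytest.approx(tpl.t[i_peak_f] / 2, abs=0.5)

    def test_nonpositive_a_rejected(self, squat_map_template):
        with pytest.raises(DataError):
            transform_template(squat_map_template, 0.0, 0.0, 1.0, 0.0)


class TestObjective:
    def test_worked_example_sse_over_var(self):
        # template values ±sqrt(0.02): VAR(g) = 0.02; residual 0.1 at each
        # of four samples: SSE = 0.04; objective = 0.04/0.02 = 2
        s = np.sqrt(0.02)
        tpl = Template(t=np.arange(4.0), f=np.array([s, -s, s, -s]),
                       test="squat", epoch="squat", modality="MAP", sig=True)
        tr = make_trace(tpl, y=tpl.f + 0.1)
        assert objective_value(tpl, tr, 1.0, 0.0, 1.0, 0.0) == \
            pytest.approx(2.0, rel=1e-12)

    def test_perfect_match_is_zero(self, squat_map_template):
        tpl = squat_map_template
        tr = make_trace(tpl)
        assert objective_value(tpl, tr, 1.0, 0.0, 1.0, 0.0) == 0.0

    def test_offset_equivariance(self, squat_map_template):
        # shifting the trace and d by the same delta leaves J unchanged
        tpl = squat_map_template
        rng = np.random.default_rng(7)
        y = tpl.f + rng.normal(0, 0.02, tpl.f.size)
        j0 = objective_value(tpl, make_trace(tpl, y=y), 1.2, 1.0, 0.9, 0.05)
        j1 = objective_value(tpl, make_trace(tpl, y=y + 0.37),
                             1.2, 1.0, 0.9, 0.05 + 0.37)
        assert j1 == pytest.approx(j0, rel=1e-9)

    def test_flat_candidate_is_inf(self, squat_map_template):
        tpl = squat_map_template
        tr = make_trace(tpl)
        assert objective_value(tpl, tr, 1.0, 0.0, 0.0, 0.1) == float("inf")

    def test_restricted_to_observed_samples(self, squat_map_template):
        tpl = squat_map_template
        y = tpl.f.copy()
        ex = np.zeros(y.size, bool)
        ex[-40:] = True
        y[ex] = 99.0  # garbage in the extrapolated tail must be ignored
        tr = make_trace(tpl, y=y)
        tr.extrapolated = ex
        assert objective_value(tpl, tr, 1.0, 0.0, 1.0, 0.0) == \
            pytest.approx(0.0, abs=1e-12)


class TestFit:
    def test_identity_recovered(self, squat_map_template):
        tpl = squat_map_template
        res = fit_template(tpl, make_trace(tpl))
        assert res.a == pytest.approx(1.0, abs=1e-3)
        assert res.b == pytest.approx(0.0, abs=1e-2)
        assert res.c == pytest.approx(1.0, abs=1e-3)
        assert res.d == pytest.approx(0.0, abs=1e-4)
        assert res.objective < 1e-6

    def test_known_draw_recovered(self, squat_map_template):
        tpl = squat_map_template
        truth = dict(a=1.3, b=2.0, c=1.5, d=0.05)
        y = transform_template(tpl, **truth)
        res = fit_template(tpl, make_trace(tpl, y=y))
        assert res.a == pytest.approx(1.3, rel=0.01)
        assert res.b == pytest.approx(2.0, abs=0.25)
        assert res.c == pytest.approx(1.5, rel=0.01)
        assert res.d == pytest.approx(0.05, abs=0.01)

    def test_gated_template_refused(self, squat_map_template):
        tpl = squat_map_template
        tpl.sig = False
        with pytest.raises(DataError, match="significance gate"):
            fit_template(tpl, make_trace(tpl))

    def test_h_conventions(self, squat_map_template):
        tpl = squat_map_template
        y = transform_template(tpl, 2.0, 0.0, 1.0, 0.0)
        tr = make_trace(tpl, y=y)
        res_dur = fit_template(tpl, tr)
        assert res_dur.H == pytest.approx(0.5, rel=0.02)  # H = 1/a
        res_lit = fit_template(tpl, tr,
                               MatchConfig(convention="literal_a"))
        assert res_lit.H == pytest.approx(2.0, rel=0.02)  # H = a

    def test_beats_brute_force_on_grid(self, squat_map_template, rng):
        tpl = squat_map_template
        y = transform_template(tpl, 1.4, 1.5, 1.2, 0.02)
        y = y + rng.normal(0, 0.02, y.size)
        tr = make_trace(tpl, y=y)
        res = fit_template(tpl, tr)
        oracle = brute_force_fit(
            tpl, tr,
            a_grid=np.linspace(0.5, 2.5, 21),
            b_grid=np.linspace(-4.0, 4.0, 33),
            c_grid=np.linspace(0.5, 2.0, 31),
            d_grid=np.linspace(-0.1, 0.1, 21),
        )
        assert res.objective <= oracle.objective + 1e-9

    def test_poor_fit_flag(self, squat_map_template, rng):
        tpl = squat_map_template
        y = rng.normal(0, 0.3, tpl.f.size)  # pure noise, no template shape
        with pytest.warns(UserWarning, match="inverted response"):
            res = fit_template(tpl, make_trace(tpl, y=y))
        assert res.poor_fit

    def test_too_few_samples(self, squat_map_template):
        tpl = squat_map_template
        tr = make_trace(tpl)
        tr.extrapolated = np.ones(tr.t.size, bool)
        tr.extrapolated[:5] = False
        with pytest.raises(DataError, match="few"):
            fit_template(tpl, tr)


class TestMatchResult:
    def test_amplitude_identity(self):
        r = MatchResult(a=1.0, b=0.0, c=0.9, d=0.1, H=1.0, objective=0.0)
        assert r.Vs == 0.9 and r.Vo == pytest.approx(0.1)
        assert r.V == pytest.approx(1.0)

    def test_nonpositive_a_rejected(self):
        with pytest.raises(DataError):
            MatchResult(a=-1.0, b=0.0, c=1.0, d=0.0, H=1.0, objective=0.0)

    def test_negative_objective_rejected(self):
        with pytest.raises(DataError):
            MatchResult(a=1.0, b=0.0, c=1.0, d=0.0, H=1.0, objective=-0.5)


def _hr_sine(amp=5.0, base=70.0, dur=120.0, fs=4.0, f_breath=0.1):
    t = np.arange(0.0, dur + 1e-9, 1.0 / fs)
    return SimpleNamespace(t=t, v=base + amp * np.sin(2 * np.pi * f_breath * t))


class TestDeepBreathing:
    def test_raw_excursion_of_paced_sine(self):
        # 6 breaths/min, +-5 bpm -> each 10 s cycle swings 10 bpm
        feat = deep_breathing_feature(_hr_sine(amp=5.0))
        assert feat == pytest.approx(10.0, rel=0.01)

    def test_respiration_segmentation(self):
        hr = _hr_sine(amp=5.0)
        resp = SimpleNamespace(t=hr.t, v=np.sin(2 * np.pi * 0.1 * hr.t))
        feat = deep_breathing_feature(hr, resp=resp)
        assert feat == pytest.approx(10.0, rel=0.02)

    def test_cohort_normalization(self):
        feat = deep_breathing_feature(_hr_sine(amp=5.0), cohort_mean_p2p=20.0)
        assert feat == pytest.approx(0.5, rel=0.01)

    def test_too_few_cycles(self):
        with pytest.raises(DataError, match="cycles"):
            deep_breathing_feature(_hr_sine(dur=30.0), duration=30.0)

    def test_cohort_features_mean_one(self):
        feats = deep_breathing_cohort_features({"a": 4.0, "b": 6.0})
        assert feats == {"a": pytest.approx(0.8), "b": pytest.approx(1.2)}

    def test_cohort_of_one_is_unity(self):
        assert deep_breathing_cohort_features({"solo": 12.3})["solo"] == \
            pytest.approx(1.0)

    def test_empty_cohort_is_error(self):
        with pytest.raises(DataError):
            deep_breathing_cohort_features({})
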