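"""Core wave math: the Moebius phase map, fiducial marks and features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmmecg.model import (
    TWO_PI,
    FiducialMarks,
    ModelParams,
    WaveParams,
    circular_distance,
    crest_trough_times,
    fiducial_mark,
    fmm_wave,
    is_circular_order,
    is_positive_wave,
    model_mean,
    phase_transform,
    wave_distance,
    wrap_angle,
)

wave_strategy = st.builds(
    WaveParams,
    A=st.floats(0.1, 5.0),
    alpha=st.floats(0.0, TWO_PI, exclude_max=True),
    beta=st.floats(0.0, TWO_PI, exclude_max=True),
    omega=st.floats(0.02, 1.0),
)


class TestPhaseTransform:
    def test_fixed_points(self):
        assert phase_transform(1.7, 1.7, 0.3) == pytest.approx(0.0)
        assert phase_transform(1.7 + math.pi, 1.7, 0.5) == pytest.approx(math.pi)
        assert phase_transform(math.pi / 2, 0.0, 1.0) == pytest.approx(math.pi / 2)

    def test_identity_at_omega_one(self):
        t = np.linspace(0, TWO_PI, 257, endpoint=False)
        assert np.allclose(phase_transform(t, 0.0, 1.0), t, atol=1e-12)

    def test_monotone_over_one_cycle(self):
        alpha = 2.3
        t = alpha + np.linspace(1e-6, TWO_PI - 1e-6, 4001)
        phi = phase_transform(t, alpha, 0.07)
        assert np.all(np.diff(phi) > 0)

    @given(s=st.floats(1e-3, math.pi - 1e-3), alpha=st.floats(0, TWO_PI),
           omega=st.floats(0.02, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_odd_symmetry_about_alpha(self, s, alpha, omega):
        fwd = phase_transform(alpha + s, alpha, omega)
        bwd = phase_transform(alpha - s, alpha, omega)
        assert wrap_angle(fwd + bwd) == pytest.approx(0.0, abs=1e-9) or \
            wrap_angle(fwd + bwd) == pytest.approx(TWO_PI, abs=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            phase_transform(np.nan, 0.0, 0.5)
        with pytest.raises(ValueError):
            phase_transform(0.0, 0.0, 0.0)


class TestFmmWave:
    @pytest.mark.parametrize("t, w, expected", [
        (0.0, WaveParams(1, 0.0, 0.0, 1.0), 1.0),
        (2.0, WaveParams(1, 2.0, math.pi / 3, 0.1), 0.5),
        # frozen high-precision evaluation of the wave formula
        (1.3, WaveParams(2, 0.8, 4.0, 0.25), -1.1042170345166596),
    ])
    def test_values(self, t, w, expected):
        assert fmm_wave(t, w) == pytest.approx(expected, abs=1e-12)

    def test_sinusoidal_limit(self):
        """omega = 1 reduces the wave to a pure sinusoid."""
        t = np.linspace(0, TWO_PI, 2048, endpoint=False)
        w = WaveParams(A=1.7, alpha=2.2, beta=0.9, omega=1.0)
        expected = 1.7 * np.cos(0.9 + t - 2.2)
        assert np.max(np.abs(fmm_wave(t, w) - expected)) < 1e-12


class TestModelMean:
    def test_flat_model(self):
        waves = {lab: WaveParams(0.0, 1.0, 1.0, 0.5) for lab in "PQRST"}
        p = ModelParams(M=3.0, waves=waves)
        t = np.linspace(0, TWO_PI, 64, endpoint=False)
        assert np.allclose(model_mean(t, p), 3.0)

    def test_additivity_single_wave(self):
        waves = {lab: WaveParams(0.0, 1.0, 1.0, 0.5) for lab in "PQRS"}
        waves["T"] = WaveParams(2.0, 1.2, 3.0, 0.3)
        p = ModelParams(M=-1.0, waves=waves)
        t = np.linspace(0, TWO_PI, 64, endpoint=False)
        assert np.allclose(model_mean(t, p), -1.0 + fmm_wave(t, waves["T"]))

    def test_missing_wave_errors(self):
        p = ModelParams(M=0.0, waves={"R": WaveParams(1, 0, 0, 0.5)})
        with pytest.raises(KeyError):
            model_mean(0.0, p)

    def test_normal_preset_peaks_at_r_crest(self, normal_preset):
        p = normal_preset.params
        t = np.linspace(0, TWO_PI, 512, endpoint=False)
        argmax_phase = t[np.argmax(model_mean(t, p))]
        t_u = crest_trough_times(p.waves["R"]).t_U
        assert circular_distance(argmax_phase, t_u) < TWO_PI / 512 + 1e-9


class TestFiducialMarks:
    def test_symmetric_crest_and_trough(self):
        assert crest_trough_times(WaveParams(1, 2.0, 0.0, 0.3)).t_U == pytest.approx(2.0)
        assert crest_trough_times(WaveParams(1, 2.0, math.pi, 0.3)).t_L == pytest.approx(2.0)

    def test_closed_form_example(self):
        # alpha=pi, beta=pi/2, omega=0.5 -> t_U = pi + 2*atan(2*tan(-pi/4))
        m = crest_trough_times(WaveParams(1, math.pi, math.pi / 2, 0.5))
        assert m.t_U == pytest.approx(0.9272952180016122, abs=1e-12)

    def test_agrees_with_dense_grid(self, rng):
        """Closed forms match brute-force argmax/argmin over one cycle."""
        t = np.linspace(0, TWO_PI, 200_000, endpoint=False)
        for _ in range(200):
            w = WaveParams(A=1.0, alpha=rng.uniform(0, TWO_PI),
                           beta=rng.uniform(0, TWO_PI), omega=rng.uniform(0.02, 1.0))
            vals = fmm_wave(t, w)
            marks = crest_trough_times(w)
            step = TWO_PI / t.size
            assert circular_distance(marks.t_U, t[np.argmax(vals)]) < 2 * step
            assert circular_distance(marks.t_L, t[np.argmin(vals)]) < 2 * step

    @given(w=wave_strategy)
    @settings(max_examples=150, deadline=None)
    def test_inversion_identity(self, w):
        """phi(t_U) = -beta and phi(t_L) = pi - beta, modulo the circle."""
        marks = crest_trough_times(w)
        phi_u = phase_transform(marks.t_U, w.alpha, w.omega)
        phi_l = phase_transform(marks.t_L, w.alpha, w.omega)
        assert circular_distance(phi_u, -w.beta) < 1e-8
        assert circular_distance(phi_l, math.pi - w.beta) < 1e-8

    def test_marks_validation(self):
        with pytest.raises(ValueError):
            FiducialMarks(t_U=1.0, t_L=1.0)

    def test_degenerate_omega_rejected(self):
        with pytest.raises(ValueError):
            WaveParams(1, 0, 0, 0.0)


class TestPolarity:
    @pytest.mark.parametrize("beta, positive", [
        (math.pi, True),          # symmetric crest
        (0.0, False),             # inverted wave
        (math.pi / 2 + 0.01, True),
        (3 * math.pi / 2 - 0.01, True),
        (math.pi / 2 - 0.01, False),
        (3 * math.pi / 2 + 0.01, False),
    ])
    def test_beta_rule(self, beta, positive):
        marks = fiducial_mark(WaveParams(1, 1.0, beta, 0.1))
        assert (marks.polarity == "positive") is positive
        expected_t = marks.t_U if positive else marks.t_L
        assert marks.t_FI == expected_t

    @given(w=wave_strategy)
    @settings(max_examples=100, deadline=None)
    def test_matches_rendered_shape(self, w):
        """Polarity agrees with whether the crest or the trough deviates
        further from the wave's own baseline (its circular mean level)."""
        t = np.linspace(0, TWO_PI, 20_000, endpoint=False)
        vals = fmm_wave(t, w)
        base = vals.mean()
        rendered_positive = (vals.max() - base) > (base - vals.min())
        # skip near-symmetric boundary shapes where the comparison is a tie
        if abs((vals.max() - base) - (base - vals.min())) > 1e-3 * w.A:
            assert is_positive_wave(w) == rendered_positive


class TestWaveDistance:
    @pytest.mark.parametrize("a, b, expected", [
        (0.7, 0.7, 0.0), (0.0, math.pi, 2.0), (math.pi / 2, 0.0, 1.0),
    ])
    def test_values(self, a, b, expected):
        assert wave_distance(a, b) == pytest.approx(expected)

    @given(a=st.floats(0, TWO_PI), b=st.floats(0, TWO_PI), rot=st.floats(0, TWO_PI))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_bounded_rotation_invariant(self, a, b, rot):
        d = wave_distance(a, b)
        assert 0.0 <= d <= 2.0
        assert d == pytest.approx(wave_distance(b, a))
        assert d == pytest.approx(wave_distance(a + rot, b + rot), abs=1e-9)


class TestCircularOrder:
    @pytest.mark.parametrize("alphas, expected", [
        ((0.1, 0.2, 0.3, 0.4, 0.5), True),
        ((0.1, 0.3, 0.2, 0.4, 0.5), False),
        ((6.0, 0.2, 1.0, 2.0, 4.0), True),
        ((1.0, 1.0, 2.0, 3.0, 4.0), True),  # ties allowed
    ])
    def test_cases(self, alphas, expected):
        assert is_circular_order(alphas) is expected

    @given(st.floats(0, TWO_PI), st.lists(st.floats(1e-4, 1.0), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_rotation_invariance(self, start, gaps):
        total = sum(gaps)
        alphas = np.cumsum([start] + [g / total * 6.0 for g in gaps])
        assert is_circular_order(wrap_angle(alphas))


class TestSerialization:
    def test_flat_dict_round_trip(self, normal_preset):
        p = normal_preset.params
        d = p.to_dict()
        assert set(d) == {"M"} | {f"{f}_{lab}" for lab in "PQRST"
                                  for f in ("A", "alpha", "beta", "omega")}
        q = ModelParams.from_dict(d)
        assert q == p
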