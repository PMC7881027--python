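"""MI estimator: backfitting, explained-variance bookkeeping, wave letter
identification and the end-to-end beat fit."""

import math
import random
from dataclasses import replace

import numpy as np
import pytest

from fmmecg.estimator import (
    FMMComponent,
    MIConfig,
    WaveIdentificationError,
    assign_waves,
    backfit_pass,
    explained_variance_profile,
    fit_beat,
    identify_R,
    marginal_pv,
    order_components,
)
from fmmecg.model import (
    TWO_PI,
    WaveParams,
    circular_distance,
    fmm_wave,
    is_circular_order,
)
from fmmecg.segmentation import BeatSignal
from fmmecg.simulator import simulate_beat
from fmmecg.wavefit import fit_single_fmm

T300 = TWO_PI * np.arange(300) / 300
ZERO = WaveParams(0.0, 0.0, 0.0, 1.0)


def _residual_rss(times, values, comps):
    total = np.sum([fmm_wave(times, c.w) for c in comps], axis=0)
    resid = values - total
    return float(np.sum((resid - resid.mean()) ** 2))


class TestBackfitPass:
    def test_single_slot_equals_single_fit(self):
        y = 1.0 + fmm_wave(T300, WaveParams(1.2, 2.0, 3.0, 0.1))
        comps = backfit_pass(T300, y, [FMMComponent(ZERO)])
        _, w, _ = fit_single_fmm(T300, y)
        assert comps[0].w == w

    def test_two_waves_noiseless(self):
        w1 = WaveParams(1.0, 2.0, 3.0, 0.15)
        w2 = WaveParams(0.6, 4.5, 3.1, 0.4)
        y = fmm_wave(T300, w1) + fmm_wave(T300, w2)
        comps = [FMMComponent(ZERO), FMMComponent(ZERO)]
        for _ in range(5):
            comps = backfit_pass(T300, y, comps)
        _, r2_cum = explained_variance_profile(T300, y, comps)
        assert r2_cum[-1] > 0.999

    def test_pass_monotone(self, rng):
        y = rng.normal(size=300) + fmm_wave(T300, WaveParams(1, 2, 3, 0.2))
        comps = [FMMComponent(ZERO) for _ in range(3)]
        comps = backfit_pass(T300, y, comps)
        rss1 = _residual_rss(T300, y, comps)
        comps = backfit_pass(T300, y, comps)
        rss2 = _residual_rss(T300, y, comps)
        assert rss2 <= rss1 + 1e-10


class TestExplainedVariance:
    def test_single_component_explains_everything(self):
        w = WaveParams(1.0, 2.0, 3.0, 0.2)
        y = fmm_wave(T300, w)
        pv, r2 = explained_variance_profile(T300, y, [FMMComponent(w)])
        assert pv == pytest.approx([1.0])

    def test_zero_amplitude_component_adds_nothing(self):
        w = WaveParams(1.0, 2.0, 3.0, 0.2)
        y = fmm_wave(T300, w)
        pv, _ = explained_variance_profile(T300, y, [FMMComponent(w), FMMComponent(ZERO)])
        assert pv[1] == pytest.approx(0.0, abs=1e-15)

    def test_matches_direct_truncation_recomputation(self, rng):
        waves = [WaveParams(1.0, 1.0, 3.0, 0.2), WaveParams(0.5, 3.0, 0.3, 0.1),
                 WaveParams(0.3, 5.0, 2.0, 0.5)]
        y = np.sum([fmm_wave(T300, w) for w in waves], axis=0) + 0.05 * rng.normal(size=300)
        comps = [FMMComponent(w) for w in waves]
        pv, r2_cum = explained_variance_profile(T300, y, comps)
        tss = float(np.sum((y - y.mean()) ** 2))
        for k in range(1, 4):
            partial = np.sum([fmm_wave(T300, w) for w in waves[:k]], axis=0)
            resid = y - partial
            expected = 1.0 - float(np.sum((resid - resid.mean()) ** 2)) / tss
            assert r2_cum[k - 1] == pytest.approx(expected, abs=1e-12)
        assert sum(pv) == pytest.approx(r2_cum[-1], abs=1e-12)

    def test_zero_variance_input_errors(self):
        with pytest.raises(ValueError):
            explained_variance_profile(T300, np.ones(300), [FMMComponent(ZERO)])


def _scored(times, values, comps):
    comps = order_components(times, values, comps)
    pv, _ = explained_variance_profile(times, values, comps)
    loo = marginal_pv(times, values, comps)
    for c, p, m in zip(comps, pv, loo):
        c.pv, c.pv_marginal = p, m
    return comps


class TestIdentifyR:
    def _components_from(self, params, extra=2):
        comps = [FMMComponent(params.waves[lab]) for lab in "PQRST"]
        comps += [FMMComponent(ZERO) for _ in range(extra)]
        return comps

    def test_normal_preset_r_found(self, normal_preset, normal_beat_clean):
        y = normal_beat_clean.values
        comps = _scored(normal_beat_clean.times, y, self._components_from(normal_preset.params))
        idx = identify_R(comps, normal_beat_clean.qrs_phase, MIConfig())
        assert comps[idx].w == normal_preset.params.waves["R"]

    def test_all_broad_components_fail(self, normal_preset, normal_beat_clean):
        cfg = MIConfig()
        comps = self._components_from(normal_preset.params)
        comps = [FMMComponent(replace(c.w, omega=0.5)) if c.w.A > 0 else c for c in comps]
        comps = _scored(normal_beat_clean.times, normal_beat_clean.values, comps)
        with pytest.raises(WaveIdentificationError):
            identify_R(comps, normal_beat_clean.qrs_phase, cfg)

    def test_larger_fitted_peak_wins(self):
        """Two filter-passing candidates: the one with the larger fitted
        model value at its crest is chosen."""
        big = WaveParams(1.0, 5.655, math.pi, 0.05)
        small = WaveParams(0.5, 5.455, math.pi, 0.05)
        y = fmm_wave(T300, big) + fmm_wave(T300, small)
        comps = _scored(T300, y, [FMMComponent(big), FMMComponent(small)])
        idx = identify_R(comps, qrs_phase=0.8 * math.pi, cfg=MIConfig())
        assert comps[idx].w.A == pytest.approx(1.0)


class TestAssignWaves:
    def test_clean_canonical_components(self, normal_preset, normal_beat_clean):
        t, y = normal_beat_clean.times, normal_beat_clean.values
        comps = [FMMComponent(normal_preset.params.waves[lab]) for lab in "PQRST"]
        comps += [FMMComponent(ZERO), FMMComponent(ZERO)]
        comps = _scored(t, y, comps)
        idx = identify_R(comps, normal_beat_clean.qrs_phase, MIConfig())
        out = assign_waves(comps, idx, normal_beat_clean.qrs_phase, MIConfig())
        got = {c.label: c.w for c in out if c.label in "PQRST"}
        assert set(got) == set("PQRST")
        for lab in "PQRST":
            assert got[lab] == normal_preset.params.waves[lab]

    def test_noise_component_never_lettered(self, normal_preset, normal_beat_clean):
        t, y = normal_beat_clean.times, normal_beat_clean.values
        noise_wave = WaveParams(0.003, 5.9, 0.3, 0.01)  # tiny sharp blip
        comps = [FMMComponent(normal_preset.params.waves[lab]) for lab in "PQRST"]
        comps.append(FMMComponent(noise_wave))
        comps = _scored(t, y, comps)
        idx = identify_R(comps, normal_beat_clean.qrs_phase, MIConfig())
        out = assign_waves(comps, idx, normal_beat_clean.qrs_phase, MIConfig())
        blip = next(c for c in out if c.w == noise_wave)
        assert blip.label == "noise"

    def test_label_permutation_safety(self, normal_preset, normal_beat_clean):
        """Shuffling the input component order never changes the final
        letter -> parameter map."""
        t, y = normal_beat_clean.times, normal_beat_clean.values
        base = [FMMComponent(normal_preset.params.waves[lab]) for lab in "PQRST"]
        base += [FMMComponent(ZERO), FMMComponent(ZERO)]
        reference = None
        rnd = random.Random(3)
        for _ in range(4):
            shuffled = [replace(c) for c in base]
            rnd.shuffle(shuffled)
            comps = _scored(t, y, shuffled)
            idx = identify_R(comps, normal_beat_clean.qrs_phase, MIConfig())
            out = assign_waves(comps, idx, normal_beat_clean.qrs_phase, MIConfig())
            got = {c.label: c.w for c in out if c.label in "PQRST"}
            if reference is None:
                reference = got
            assert got == reference


class TestFitBeat:
    def test_noiseless_normal_recovery(self, normal_preset, normal_fit_clean):
        fit = normal_fit_clean
        assert fit.status == "OK"
        assert fit.r2 > 0.999
        for lab in "PQRST":
            tw, ew = normal_preset.params.waves[lab], fit.params.waves[lab]
            assert circular_distance(ew.alpha, tw.alpha) < 0.02
            assert circular_distance(ew.beta, tw.beta) < 0.05
            assert ew.A == pytest.approx(tw.A, rel=0.02)
            assert ew.omega == pytest.approx(tw.omega, rel=0.10)

    def test_noisy_normal_beat(self, normal_preset):
        sigma = 0.02 * normal_preset.params.waves["R"].A
        beat = simulate_beat(normal_preset.params, sigma, n=500, seed=11)
        fit = fit_beat(beat)
        assert fit.status == "OK"
        assert fit.r2 >= 0.98

    def test_pure_noise_never_ok(self):
        t = TWO_PI * np.arange(200) / 200
        for seed in range(5):
            y = np.random.default_rng(seed).normal(size=200)
            beat = BeatSignal(times=t, values=y, fs=200.0, qrs_phase=0.8 * math.pi,
                              beat_id=f"noise{seed}")
            fit = fit_beat(beat)
            assert fit.status == "incomplete"

    def test_degenerate_beat_errors(self):
        t = TWO_PI * np.arange(100) / 100
        beat = BeatSignal(times=t, values=np.ones(100), fs=100.0, qrs_phase=1.0)
        with pytest.raises(ValueError):
            fit_beat(beat)

    def test_r2_trajectory_monotone(self, normal_fit_clean):
        hist = normal_fit_clean.r2_history
        assert len(hist) >= 1
        assert all(b >= a - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_pv_telescopes_to_full_r2(self, normal_beat_clean, normal_fit_clean):
        fit = normal_fit_clean
        total_pv = sum(c.pv for c in fit.components)
        assert total_pv == pytest.approx(fit.r2, abs=1e-10)

    def test_circular_order_on_ok_fit(self, normal_fit_clean):
        assert normal_fit_clean.status == "OK"
        assert is_circular_order(normal_fit_clean.params.alphas())

    def test_pipeline_scale_shift_equivariance(self, normal_preset):
        beat = simulate_beat(normal_preset.params, 0.02, n=300, seed=4)
        fit1 = fit_beat(beat)
        scaled = BeatSignal(times=beat.times, values=2.5 * beat.values - 1.0,
                            fs=beat.fs, qrs_phase=beat.qrs_phase, beat_id="scaled")
        fit2 = fit_beat(scaled)
        assert fit2.status == fit1.status == "OK"
        assert fit2.r2 == pytest.approx(fit1.r2, abs=1e-9)
        assert fit2.params.M == pytest.approx(2.5 * fit1.params.M - 1.0, abs=1e-6)
        for lab in "PQRST":
            w1, w2 = fit1.params.waves[lab], fit2.params.waves[lab]
            assert w2.A == pytest.approx(2.5 * w1.A, rel=1e-5)
            assert circular_distance(w1.alpha, w2.alpha) < 1e-6
            assert w2.omega == pytest.approx(w1.omega, abs=1e-6)
        assert fit2.sigma2 == pytest.approx(2.5 ** 2 * fit1.sigma2, rel=1e-6)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MIConfig(K_max=4)
        with pytest.raises(ValueError):
            MIConfig(max_iter=0)
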