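"""Synthetic beat and record generation from FMM beat parameters.

Beats are drawn exactly from the model: mean curve (intercept plus five FMM
waves) sampled on an equispaced phase grid, plus i.i.d. Gaussian noise.
Seven named morphology presets are provided — one typical pattern plus six
echoing common pathological morphologies (paced beat, right/left bundle
branch block, atrial/ventricular premature beats, and a noisy typical
beat).  The preset parameter VALUES are authored fixtures of this package,
designed so each pattern refits cleanly and the patterns are mutually
discriminable; they are not published clinical constants.

Presets are parameterised by each wave's fiducial (crest/trough) phase,
which is the natural language for authoring a morphology; the location
angle alpha is recovered from the closed-form fiducial equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    TWO_PI,
    WAVE_LABELS,
    ModelParams,
    WaveParams,
    fiducial_mark,
    is_positive_wave,
    model_mean,
    wrap_angle,
)
from .segmentation import BeatSignal, QrsAnnotations

__all__ = [
    "PatternPreset",
    "PATTERN_NAMES",
    "pattern_presets",
    "wave_from_mark",
    "simulate_beat",
    "SimulatedBeat",
    "simulate_dataset",
    "simulate_record",
    "true_marks_ms",
]

PATTERN_NAMES = ("NORMAL", "PACE", "RBBB", "APC", "PVC", "LBBB_LIKE", "NOISY")

#: Phase of the QRS annotation inside a segmented beat window
#: (40% of the window, in radians).
QRS_ANNOTATION_PHASE = 0.4 * TWO_PI


@dataclass(frozen=True)
class PatternPreset:
    """A named beat morphology: model parameters plus a default noise SD."""

    name: str
    params: ModelParams
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.params.is_complete:
            raise ValueError("preset must define all five waves")


def wave_from_mark(mark_phase: float, A: float, beta: float, omega: float) -> WaveParams:
    """Build a wave whose fiducial mark sits at ``mark_phase``.

    For a crest-shaped wave (``beta`` in (pi/2, 3*pi/2)) the crest phase is
    placed at ``mark_phase``; for a trough-shaped wave, the trough phase.
    Inverts the closed-form fiducial equations for alpha.
    """
    probe = WaveParams(A=max(A, 1e-12), alpha=0.0, beta=beta, omega=omega)
    if is_positive_wave(probe):
        x = -probe.beta / 2.0
    else:
        x = (math.pi - probe.beta) / 2.0
    shift = 2.0 * math.atan2(math.sin(x), omega * math.cos(x))
    return WaveParams(A=A, alpha=wrap_angle(mark_phase - shift), beta=beta, omega=omega)


def _preset(name, sigma, M, spec):
    """spec: {label: (mark fraction of window, A, beta, omega)} — fixture values."""
    waves = {
        lab: wave_from_mark(frac * TWO_PI, A, beta, omega)
        for lab, (frac, A, beta, omega) in spec.items()
    }
    return PatternPreset(name=name, params=ModelParams(M=M, waves=waves), sigma=sigma)


def pattern_presets() -> dict[str, PatternPreset]:
    """The seven fixed morphology presets (fixture values, not from any
    published table); stable across releases.

    Amplitudes are in millivolt-like units with the typical R wave at 1.0;
    each preset's default sigma is 2% of its R amplitude except NOISY (10%).
    """
    presets = [
        _preset("NORMAL", 0.020, 0.0, {
            "P": (0.24, 0.15, 3.00, 0.15),
            "Q": (0.37, 0.10, 0.10, 0.040),
            "R": (0.40, 1.00, 3.10, 0.050),
            "S": (0.43, 0.18, 6.20, 0.045),
            "T": (0.70, 0.35, 2.90, 0.25),
        }),
        _preset("PACE", 0.025, 0.0, {
            "P": (0.22, 0.08, 3.10, 0.18),
            "Q": (0.36, 0.20, 0.30, 0.080),
            "R": (0.40, 1.25, 2.60, 0.100),
            "S": (0.46, 0.55, 6.00, 0.110),
            "T": (0.72, 0.45, 2.20, 0.30),
        }),
        _preset("RBBB", 0.019, 0.0, {
            "P": (0.24, 0.15, 3.00, 0.14),
            "Q": (0.365, 0.15, 0.20, 0.070),
            "R": (0.40, 0.95, 3.00, 0.045),
            "S": (0.465, 0.50, 0.15, 0.130),   # broadened, deep S
            "T": (0.71, 0.30, 2.80, 0.26),
        }),
        _preset("APC", 0.021, 0.0, {
            "P": (0.30, 0.22, 2.40, 0.090),    # premature, atypical P
            "Q": (0.375, 0.09, 0.10, 0.040),
            "R": (0.40, 1.05, 3.10, 0.050),
            "S": (0.43, 0.16, 6.20, 0.050),
            "T": (0.68, 0.33, 2.90, 0.24),
        }),
        _preset("PVC", 0.028, 0.0, {
            "P": (0.20, 0.06, 3.00, 0.16),     # vestigial P
            "Q": (0.35, 0.20, 0.40, 0.080),
            "R": (0.41, 1.40, 2.30, 0.115),    # wide, bizarre QRS
            "S": (0.48, 0.70, 5.90, 0.100),
            "T": (0.75, 0.60, 2.00, 0.35),
        }),
        _preset("LBBB_LIKE", 0.017, 0.0, {
            "P": (0.25, 0.13, 3.10, 0.13),
            "Q": (0.36, 0.05, 0.20, 0.040),
            "R": (0.405, 0.85, 3.60, 0.115),   # broad, slurred R
            "S": (0.475, 0.35, 0.30, 0.090),
            "T": (0.73, 0.28, 3.20, 0.28),
        }),
        _preset("NOISY", 0.100, 0.0, {
            "P": (0.22, 0.14, 3.05, 0.16),
            "Q": (0.37, 0.09, 0.15, 0.045),
            "R": (0.40, 1.00, 3.05, 0.060),
            "S": (0.43, 0.17, 6.10, 0.050),
            "T": (0.69, 0.25, 2.85, 0.26),
        }),
    ]
    return {p.name: p for p in presets}


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_beat(p: ModelParams, sigma: float, n: int = 500, seed=0,
                  beat_id: str = "sim") -> BeatSignal:
    """One beat drawn from the model: mean curve plus N(0, sigma^2) noise.

    Samples lie on the equispaced phase grid ``2*pi*i/n``; the nominal beat
    duration is one second (``fs = n``).  Deterministic given ``seed``.
    """
    if n < 40:
        raise ValueError("n must be >= 40")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    times = TWO_PI * np.arange(n) / n
    mean = model_mean(times, p)
    noise = _rng(seed).normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    return BeatSignal(
        times=times,
        values=mean + noise,
        fs=float(n),
        qrs_phase=QRS_ANNOTATION_PHASE,
        beat_id=beat_id,
        window=(0, n),
    )


@dataclass(frozen=True)
class SimulatedBeat:
    """A simulated beat with its ground truth."""

    beat: BeatSignal
    pattern: str
    params: ModelParams
    sigma: float
    marks: dict  # label -> fiducial phase (radians)


def _true_marks(params: ModelParams) -> dict:
    return {lab: fiducial_mark(params.waves[lab]).t_FI for lab in WAVE_LABELS}


def simulate_dataset(patterns=None, beats_per_pattern: int = 20, sigma: float | None = None,
                     seed: int = 0, n: int = 500) -> list[SimulatedBeat]:
    """Labelled beats from the named presets.

    ``sigma=None`` uses each preset's own noise level; a float overrides all
    of them.  Per-beat seeds derive from ``seed`` through a spawn-key scheme
    (pattern index, beat index), so any element is reproducible on its own.
    """
    if beats_per_pattern < 1:
        raise ValueError("beats_per_pattern must be >= 1")
    presets = pattern_presets()
    patterns = list(patterns) if patterns is not None else list(PATTERN_NAMES)
    unknown = [p for p in patterns if p not in presets]
    if unknown:
        raise KeyError(f"unknown pattern names: {unknown}")
    out = []
    for pi, name in enumerate(patterns):
        preset = presets[name]
        sd = preset.sigma if sigma is None else float(sigma)
        for bi in range(beats_per_pattern):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(pi, bi)))
            beat = simulate_beat(preset.params, sd, n=n, seed=rng,
                                 beat_id=f"{name}:{bi}")
            out.append(SimulatedBeat(beat=beat, pattern=name, params=preset.params,
                                     sigma=sd, marks=_true_marks(preset.params)))
    return out


def simulate_record(preset: PatternPreset, n_beats: int, fs: float = 250.0,
                    rr_ms: float = 1000.0, seed: int = 0):
    """A continuous multi-beat record with QRS annotations.

    Beats of ``round(fs * rr_ms / 1000)`` samples are concatenated; each
    annotation sits at the 40% point of its beat window, so the record is a
    valid input for :func:`fmmecg.segmentation.segment_beats`.
    """
    if n_beats < 3:
        raise ValueError("need at least 3 beats")
    L = int(round(fs * rr_ms / 1000.0))
    phases = TWO_PI * np.arange(L) / L
    mean = model_mean(phases, preset.params)
    rng = _rng(seed)
    record = np.concatenate([
        mean + (rng.normal(0.0, preset.sigma, size=L) if preset.sigma > 0 else 0.0)
        for _ in range(n_beats)
    ])
    offset = int(round(0.4 * L))
    ann = QrsAnnotations(samples=tuple(i * L + offset for i in range(n_beats)), fs=fs)
    return record, ann


def true_marks_ms(preset: PatternPreset, n_beats: int, fs: float = 250.0,
                  rr_ms: float = 1000.0) -> list[dict]:
    """Ground-truth fiducial marks (ms from record start) for the interior
    beats of the matching :func:`simulate_record` output."""
    L = int(round(fs * rr_ms / 1000.0))
    marks = _true_marks(preset.params)
    out = []
    for i in range(1, n_beats - 1):
        out.append({lab: (i * L + ph * L / TWO_PI) / fs * 1000.0
                    for lab, ph in marks.items()})
    return out
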