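"""Core FMM wave mathematics: the single-wave function, the five-wave beat
model, closed-form fiducial marks and derived morphology features.

A single FMM (frequency-modulated Moebius) wave is

    W(t) = A * cos(beta + 2*arctan(omega * tan((t - alpha) / 2)))

with amplitude ``A >= 0``, location angle ``alpha``, shape/skewness angle
``beta`` and sharpness ``omega`` in ``(0, 1]``.  ``omega = 1`` is an exact
sinusoid; as ``omega -> 0`` the wave concentrates into a spike.  A heartbeat
is modelled as an intercept plus five such waves labelled P, Q, R, S, T whose
location angles are circularly ordered, mirroring the conduction sequence
from the sinus node through the atria to the ventricles.

Everything in this module is pure math on angles in ``[0, 2*pi)``; no
estimation happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "TWO_PI",
    "WAVE_LABELS",
    "WaveParams",
    "ModelParams",
    "FiducialMarks",
    "wrap_angle",
    "circular_distance",
    "phase_transform",
    "fmm_wave",
    "model_mean",
    "crest_trough_times",
    "fiducial_mark",
    "wave_distance",
    "is_circular_order",
]

TWO_PI = 2.0 * math.pi

#: Canonical wave labels in activation order.
WAVE_LABELS = ("P", "Q", "R", "S", "T")


def wrap_angle(theta):
    """Reduce an angle (scalar or array) to ``[0, 2*pi)``."""
    return np.mod(theta, TWO_PI)


def circular_distance(a, b):
    """Shortest arc length between two angles, in ``[0, pi]``."""
    d = np.abs(wrap_angle(np.asarray(a) - np.asarray(b)))
    return np.minimum(d, TWO_PI - d)


@dataclass(frozen=True)
class WaveParams:
    """Four-parameter description of one FMM wave.

    Attributes
    ----------
    A : float
        Amplitude in signal units, non-negative.
    alpha : float
        Location angle in radians, stored reduced to ``[0, 2*pi)``.
    beta : float
        Shape/skewness angle in radians, reduced to ``[0, 2*pi)``.
        Values near ``pi`` give a unimodal symmetric crest, values near
        ``0``/``2*pi`` the inverted (trough) wave.
    omega : float
        Sharpness in ``(0, 1]``; 1 is sinusoidal, small values are spikes.
    """

    A: float
    alpha: float
    beta: float
    omega: float

    def __post_init__(self):
        for name in ("A", "alpha", "beta", "omega"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"WaveParams.{name} must be finite, got {v!r}")
        if self.A < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.A}")
        if not (0.0 < self.omega <= 1.0):
            raise ValueError(f"omega must lie in (0, 1], got {self.omega}")
        object.__setattr__(self, "alpha", float(wrap_angle(self.alpha)))
        object.__setattr__(self, "beta", float(wrap_angle(self.beta)))
        object.__setattr__(self, "A", float(self.A))
        object.__setattr__(self, "omega", float(self.omega))


@dataclass(frozen=True)
class ModelParams:
    """Intercept plus the five labelled waves of a beat model.

    ``waves`` maps labels in ``{"P","Q","R","S","T"}`` to :class:`WaveParams`.
    A complete model carries all five labels; partial maps are allowed (an
    estimator may fail to identify a wave) but :func:`model_mean` requires a
    complete one.
    """

    M: float
    waves: Mapping[str, WaveParams] = field(default_factory=dict)

    def __post_init__(self):
        if not math.isfinite(self.M):
            raise ValueError("intercept M must be finite")
        bad = set(self.waves) - set(WAVE_LABELS)
        if bad:
            raise ValueError(f"unknown wave labels: {sorted(bad)}")
        object.__setattr__(self, "waves", dict(self.waves))

    @property
    def is_complete(self) -> bool:
        return all(lab in self.waves for lab in WAVE_LABELS)

    def alphas(self) -> tuple:
        """Location angles in P,Q,R,S,T order (complete models only)."""
        return tuple(self.waves[lab].alpha for lab in WAVE_LABELS)

    def to_dict(self) -> dict:
        """Flat serialisation: M, A_P, alpha_P, beta_P, omega_P, ..., omega_T."""
        out = {"M": self.M}
        for lab in WAVE_LABELS:
            if lab not in self.waves:
                continue
            w = self.waves[lab]
            out[f"A_{lab}"] = w.A
            out[f"alpha_{lab}"] = w.alpha
            out[f"beta_{lab}"] = w.beta
            out[f"omega_{lab}"] = w.omega
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParams":
        waves = {}
        for lab in WAVE_LABELS:
            if f"A_{lab}" in d:
                waves[lab] = WaveParams(
                    A=d[f"A_{lab}"],
                    alpha=d[f"alpha_{lab}"],
                    beta=d[f"beta_{lab}"],
                    omega=d[f"omega_{lab}"],
                )
        return cls(M=float(d["M"]), waves=waves)


@dataclass(frozen=True)
class FiducialMarks:
    """Crest/trough phases of one wave and the selected fiducial mark.

    ``t_U`` is the phase at which the wave attains its maximum over one
    cycle, ``t_L`` its minimum.  ``t_FI`` is ``t_U`` for a positive (crest)
    wave and ``t_L`` for a negative (trough) wave.
    """

    t_U: float
    t_L: float
    t_FI: float | None = None
    polarity: str | None = None  # "positive" | "negative"

    def __post_init__(self):
        if math.isclose(
            circular_distance(self.t_U, self.t_L), 0.0, abs_tol=1e-12
        ):
            raise ValueError("crest and trough phases must differ")


def phase_transform(t, alpha: float, omega: float):
    """Moebius phase map ``phi(t) = 2*arctan(omega * tan((t - alpha)/2))``.

    Evaluated through the two-argument arctangent so it is continuous and
    strictly increasing from 0 to ``2*pi`` as ``t`` sweeps one cycle from
    ``alpha``; in particular ``phi(alpha) = 0`` and ``phi(alpha + pi) = pi``
    for every ``omega``.

    Accepts scalars or arrays of ``t``.
    """
    if not (0.0 < omega <= 1.0):
        raise ValueError(f"omega must lie in (0, 1], got {omega}")
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite time values")
    u = np.mod((t - alpha) / 2.0, math.pi)
    phi = 2.0 * np.arctan2(omega * np.sin(u), np.cos(u))
    # atan2 lands in (-pi, pi]; u in [0, pi) makes phi in [0, 2*pi)
    phi = np.mod(phi, TWO_PI)
    return phi if phi.ndim else float(phi)


def fmm_wave(t, w: WaveParams):
    """Evaluate one FMM wave at phase(s) ``t``."""
    return w.A * np.cos(w.beta + phase_transform(t, w.alpha, w.omega))


def model_mean(t, p: ModelParams):
    """Mean beat signal: intercept plus the sum of the five waves.

    Raises ``KeyError`` if any of the five labels is missing from ``p``.
    """
    missing = [lab for lab in WAVE_LABELS if lab not in p.waves]
    if missing:
        raise KeyError(f"model is missing waves: {missing}")
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, p.M, dtype=float)
    for lab in WAVE_LABELS:
        out += fmm_wave(t, p.waves[lab])
    return out if out.ndim else float(out)


def _warp_inverse(x: float, omega: float) -> float:
    """Branch-safe ``2*arctan((1/omega) * tan(x))`` for the fiducial formulas."""
    return 2.0 * math.atan2(math.sin(x), omega * math.cos(x))


def crest_trough_times(w: WaveParams) -> FiducialMarks:
    """Closed-form crest (``t_U``) and trough (``t_L``) phases of a wave.

    ``t_U = alpha + 2*arctan((1/omega) * tan(-beta/2))`` and
    ``t_L = alpha + 2*arctan((1/omega) * tan((pi - beta)/2))``, evaluated via
    the two-argument arctangent so that the tangent singularities at
    ``beta = pi`` (for t_U) and ``beta = 0`` (for t_L) resolve by continuity.
    """
    if w.omega <= 0:
        raise ValueError("degenerate wave: omega must be positive")
    t_u = wrap_angle(w.alpha + _warp_inverse(-w.beta / 2.0, w.omega))
    t_l = wrap_angle(w.alpha + _warp_inverse((math.pi - w.beta) / 2.0, w.omega))
    return FiducialMarks(t_U=float(t_u), t_L=float(t_l))


def is_positive_wave(w: WaveParams) -> bool:
    """Polarity rule: a wave is a crest iff ``beta`` lies in ``(pi/2, 3*pi/2)``.

    ``beta`` near ``pi`` is the unimodal symmetric crest; near ``0``/``2*pi``
    the inverted wave.  The boundary cases (exactly asymmetric crest-and-
    trough shapes) are classified as negative.
    """
    return math.pi / 2.0 < w.beta < 3.0 * math.pi / 2.0


def fiducial_mark(w: WaveParams) -> FiducialMarks:
    """Crest/trough phases plus the selected fiducial mark of a wave.

    The fiducial mark is the crest phase for a positive wave and the trough
    phase for a negative one.
    """
    marks = crest_trough_times(w)
    if is_positive_wave(w):
        return FiducialMarks(marks.t_U, marks.t_L, t_FI=marks.t_U, polarity="positive")
    return FiducialMarks(marks.t_U, marks.t_L, t_FI=marks.t_L, polarity="negative")


def wave_distance(alpha1, alpha2):
    """Chordal distance ``1 - cos(alpha1 - alpha2)`` between two locations.

    Lies in ``[0, 2]``, is symmetric and invariant under common rotation;
    applied to ``alpha_Q`` and ``alpha_S`` it measures QRS duration.
    """
    return 1.0 - np.cos(np.asarray(alpha1, dtype=float) - np.asarray(alpha2, dtype=float))


def is_circular_order(alphas: Iterable[float]) -> bool:
    """True iff the five angles appear in the given order around the circle.

    Ties are allowed; the check is rotation-invariant.  Used for the
    constraint ``alpha_P <= alpha_Q <= alpha_R <= alpha_S <= alpha_T``
    traversed circularly.
    """
    a = np.asarray(list(alphas), dtype=float)
    if a.size != 5:
        raise ValueError(f"expected five angles, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite angles")
    offs = wrap_angle(a - a[0])
    return bool(np.all(np.diff(offs) >= 0.0))
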