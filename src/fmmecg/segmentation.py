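"""Beat segmentation: from a continuous record plus QRS annotations to
per-beat signals on the phase scale [0, 2*pi).

Each interior annotation ``t_qrs`` (one with both an earlier and a later
neighbour) defines a half-open sample window

    [round(t_qrs - 0.4 * RR-), round(t_qrs + 0.6 * RR+))

where ``RR-``/``RR+`` are the distances to the neighbouring annotations, so
consecutive windows tile the record.  The windowed samples are detrended
(straight line through the edge means, applied only when a baseline drift is
actually present) and mapped to equispaced phases on [0, 2*pi); the QRS
annotation maps to ``qrs_phase`` (0.8*pi for equal RR intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import TWO_PI

__all__ = [
    "BeatSignal",
    "QrsAnnotations",
    "beat_window",
    "to_phase_scale",
    "detrend",
    "segment_beats",
]

logger = logging.getLogger(__name__)

MIN_BEAT_SAMPLES = 40

#: Window extends 40% of the preceding RR before and 60% of the following
#: RR after the annotation.
_FRAC_BEFORE = 0.4
_FRAC_AFTER = 0.6


@dataclass(frozen=True)
class QrsAnnotations:
    """Externally supplied QRS annotation sample indices (never computed here)."""

    samples: tuple
    fs: float

    def __post_init__(self):
        s = tuple(int(x) for x in self.samples)
        if len(s) == 0:
            raise ValueError("no annotations")
        if any(x < 0 for x in s):
            raise ValueError("annotation samples must be non-negative")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("annotation samples must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        object.__setattr__(self, "samples", s)

    def __len__(self):
        return len(self.samples)


@dataclass(frozen=True)
class BeatSignal:
    """One beat's samples on the phase scale, with record provenance.

    ``times`` are equispaced phases in [0, 2*pi); ``window`` is the
    half-open (start, end) sample span in record coordinates, which together
    with ``fs`` inverts the phase map: a phase ``p`` corresponds to record
    time ``(window[0] + p * len / (2*pi)) / fs`` seconds.
    """

    times: np.ndarray
    values: np.ndarray
    fs: float
    qrs_phase: float
    beat_id: str = "beat"
    window: tuple = (0, 0)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size < MIN_BEAT_SAMPLES:
            raise ValueError(f"beat must have >= {MIN_BEAT_SAMPLES} samples")
        if not (0.0 <= self.qrs_phase < TWO_PI):
            raise ValueError("qrs_phase must lie in [0, 2*pi)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self):
        return self.times.size

    def phase_to_ms(self, phase) -> np.ndarray:
        """Map a phase in this beat to milliseconds from the record start."""
        n = self.times.size
        offset = np.asarray(phase, dtype=float) * n / TWO_PI
        return (self.window[0] + offset) / self.fs * 1000.0


def _round_half_even(x: float) -> int:
    return int(np.round(x))


def beat_window(ann: QrsAnnotations, i: int) -> tuple[int, int]:
    """Half-open sample window of interior beat ``i``.

    Requires both neighbours, so the first and last annotations are invalid.
    """
    if not (0 < i < len(ann) - 1):
        raise IndexError(f"beat {i} has no RR interval on both sides")
    t = ann.samples[i]
    rr_minus = t - ann.samples[i - 1]
    rr_plus = ann.samples[i + 1] - t
    start = _round_half_even(t - _FRAC_BEFORE * rr_minus)
    end = _round_half_even(t + _FRAC_AFTER * rr_plus)
    return start, end


def to_phase_scale(window_length: int, qrs_offset: int):
    """Equispaced phases on [0, 2*pi) and the annotation's phase.

    ``times[i] = 2*pi*i/window_length``; the endpoint 2*pi is excluded since
    the model is periodic.  Exactly invertible: sample offset =
    ``phase * window_length / (2*pi)``.
    """
    if window_length < MIN_BEAT_SAMPLES:
        raise ValueError(f"window must span >= {MIN_BEAT_SAMPLES} samples")
    if not (0 <= qrs_offset < window_length):
        raise ValueError("QRS offset outside window")
    times = TWO_PI * np.arange(window_length) / window_length
    qrs_phase = TWO_PI * qrs_offset / window_length
    return times, qrs_phase


def detrend(values, edge_frac: float = 0.05, trigger_sd_frac: float = 0.30):
    """Remove a linear baseline drift when one is present.

    The line through the mean of the first and last ``edge_frac`` of samples
    is subtracted, but only when the edge means differ by more than
    ``trigger_sd_frac`` times the window's standard deviation; otherwise the
    input is returned unchanged.  Idempotent to numerical precision.

    The trigger threshold is deliberately conservative: the edges of a clean
    beat legitimately differ a little (the T-wave tail decays into the next
    P wave), and subtracting a line through that difference distorts an
    undrifted signal.
    """
    v = np.asarray(values, dtype=float)
    if v.size < MIN_BEAT_SAMPLES:
        raise ValueError(f"need >= {MIN_BEAT_SAMPLES} samples")
    m = max(1, int(round(edge_frac * v.size)))
    e1 = float(v[:m].mean())
    e2 = float(v[-m:].mean())
    sd = float(v.std())
    if abs(e2 - e1) <= trigger_sd_frac * sd:
        return v.copy()
    x1 = (m - 1) / 2.0
    x2 = v.size - 1 - (m - 1) / 2.0
    slope = (e2 - e1) / (x2 - x1)
    line = e1 + slope * (np.arange(v.size) - x1)
    return v - line


def segment_beats(record, ann: QrsAnnotations, *, apply_detrend: bool = True,
                  record_id: str = "rec") -> list[BeatSignal]:
    """Split a record into interior beats on the phase scale.

    Beats whose window falls outside the record are skipped with a warning.
    """
    record = np.asarray(record, dtype=float)
    if len(ann) < 3:
        raise ValueError("need at least 3 annotations for one interior beat")
    beats = []
    for i in range(1, len(ann) - 1):
        start, end = beat_window(ann, i)
        if start < 0 or end > record.size:
            logger.warning("beat %d window [%d, %d) outside record; skipped", i, start, end)
            continue
        seg = record[start:end]
        if apply_detrend:
            seg = detrend(seg)
        times, qrs_phase = to_phase_scale(end - start, ann.samples[i] - start)
        beats.append(
            BeatSignal(
                times=times,
                values=seg,
                fs=ann.fs,
                qrs_phase=qrs_phase,
                beat_id=f"{record_id}:{i}",
                window=(start, end),
            )
        )
    return beats
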