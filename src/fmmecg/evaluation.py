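"""Goodness of fit, fiducial-mark detection scoring, parameter-recovery
summaries and the Fisher-LDA discrimination harness.

Detection scoring follows the beat-wise convention: a predicted mark within
+/-75 ms of a reference mark is a true positive; unmatched references are
false negatives and unmatched predictions false positives.  From the counts
the standard ratios are reported as percentages:

    Se  = TP / (TP + FN)          PPV = TP / (TP + FP)
    DER = (FP + FN) / (TP + FN)   F1  = 2 TP / (2 TP + FP + FN)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .model import WAVE_LABELS, ModelParams, wrap_angle

__all__ = [
    "DetectionCounts",
    "DetectionMetrics",
    "RecoveryReport",
    "r_squared",
    "match_marks",
    "detection_metrics",
    "round_half_up",
    "parameter_recovery_report",
    "lda_loocv",
    "wave_feature_matrix",
]

DEFAULT_TOL_MS = 75.0


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other):
        return DetectionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class DetectionMetrics:
    """Se, PPV, DER and F1 as percentages (unrounded)."""

    se: float
    ppv: float
    der: float
    f1: float

    def rounded(self, ndigits: int = 2) -> "DetectionMetrics":
        return DetectionMetrics(*(round_half_up(x, ndigits)
                                  for x in (self.se, self.ppv, self.der, self.f1)))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the usual convention in printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def r_squared(observed, fitted) -> float:
    """Coefficient of determination ``1 - RSS / TSS``."""
    y = np.asarray(observed, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if y.size != f.size:
        raise ValueError("observed and fitted must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        raise ValueError("observed series is constant")
    return 1.0 - float(np.sum((y - f) ** 2)) / tss


def match_marks(predicted, reference, tol_ms: float = DEFAULT_TOL_MS) -> DetectionCounts:
    """Greedy one-to-one nearest matching of predicted to reference marks.

    Candidate pairs within ``tol_ms`` are taken in order of increasing
    absolute offset; each mark participates in at most one match.
    """
    pred = sorted(float(x) for x in predicted)
    ref = sorted(float(x) for x in reference)
    pairs = sorted(
        (abs(p - r), i, j)
        for i, p in enumerate(pred)
        for j, r in enumerate(ref)
        if abs(p - r) <= tol_ms
    )
    used_p, used_r = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        tp += 1
    return DetectionCounts(tp=tp, fp=len(pred) - tp, fn=len(ref) - tp)


def detection_metrics(c: DetectionCounts) -> DetectionMetrics:
    """Se/PPV/DER/F1 percentages from TP/FP/FN counts."""
    if c.tp + c.fn == 0:
        raise ValueError("Se and DER undefined: TP + FN is zero")
    if c.tp + c.fp == 0:
        raise ValueError("PPV undefined: TP + FP is zero")
    se = 100.0 * c.tp / (c.tp + c.fn)
    ppv = 100.0 * c.tp / (c.tp + c.fp)
    der = 100.0 * (c.fp + c.fn) / (c.tp + c.fn)
    f1 = 100.0 * 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return DetectionMetrics(se=se, ppv=ppv, der=der, f1=f1)


def _circular_stats(errors) -> tuple[float, float]:
    """Circular mean and resultant-length SD of angular errors."""
    e = wrap_angle(np.asarray(errors, dtype=float))
    C = np.cos(e).mean()
    S = np.sin(e).mean()
    mean = math.atan2(S, C)
    rbar = min(1.0, math.hypot(C, S))
    sd = math.sqrt(max(0.0, -2.0 * math.log(rbar))) if rbar > 0 else math.inf
    return mean, sd


@dataclass(frozen=True)
class RecoveryReport:
    """Per-parameter bias/spread table.

    Rows are (wave, parameter); Euclidean parameters (A, and the intercept M
    under wave ``"-"``) report mean error and SD, circular parameters
    (alpha, beta) circular mean error and resultant-length circular SD,
    omega the relative error mean and SD.
    """

    table: pd.DataFrame

    def bias(self, wave: str, param: str) -> float:
        return float(self.table.loc[(wave, param), "bias"])

    def spread(self, wave: str, param: str) -> float:
        return float(self.table.loc[(wave, param), "spread"])


def parameter_recovery_report(truth, estimates) -> RecoveryReport:
    """Summarise estimate-minus-truth errors over paired beat models."""
    truth = list(truth)
    estimates = list(estimates)
    if len(truth) != len(estimates):
        raise ValueError("truth and estimates must be paired lists of equal length")
    rows = []
    m_err = [e.M - t.M for t, e in zip(truth, estimates)]
    rows.append(("-", "M", float(np.mean(m_err)), float(np.std(m_err))))
    for lab in WAVE_LABELS:
        pairs = [(t.waves[lab], e.waves[lab]) for t, e in zip(truth, estimates)
                 if lab in t.waves and lab in e.waves]
        if not pairs:
            continue
        a_err = [ew.A - tw.A for tw, ew in pairs]
        rows.append((lab, "A", float(np.mean(a_err)), float(np.std(a_err))))
        for param in ("alpha", "beta"):
            err = [getattr(ew, param) - getattr(tw, param) for tw, ew in pairs]
            mean, sd = _circular_stats(err)
            rows.append((lab, param, mean, sd))
        w_err = [(ew.omega - tw.omega) / tw.omega for tw, ew in pairs]
        rows.append((lab, "omega_rel", float(np.mean(w_err)), float(np.std(w_err))))
    table = pd.DataFrame(rows, columns=["wave", "param", "bias", "spread"])
    return RecoveryReport(table=table.set_index(["wave", "param"]))


def _fisher_lda_predict(Xtr, ytr, Xte, ridge: float = 1e-8):
    """Fisher LDA with pooled within-class covariance (ridge-stabilised)."""
    classes = sorted(set(ytr))
    n, p = Xtr.shape
    means = {}
    Sw = np.zeros((p, p))
    for c in classes:
        Xc = Xtr[ytr == c]
        mu = Xc.mean(axis=0)
        means[c] = mu
        d = Xc - mu
        Sw += d.T @ d
    Sw /= max(1, n - len(classes))
    Sw = Sw + ridge * (np.trace(Sw) / p + 1.0) * np.eye(p)
    priors = {c: np.mean(ytr == c) for c in classes}
    inv = np.linalg.solve
    scores = []
    for c in classes:
        w = inv(Sw, means[c])
        scores.append(Xte @ w - 0.5 * means[c] @ w + math.log(priors[c]))
    return [classes[i] for i in np.argmax(np.column_stack(scores), axis=1)]


def lda_loocv(features, labels) -> float:
    """Leave-one-out misclassification rate of Fisher LDA.

    ``features`` may contain NaN for missing values; each missing entry is
    imputed with the median of its sample's class, computed without the
    held-out sample (the per-unit median-imputation convention).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than 2 members")

    def impute(M, lab):
        M = M.copy()
        for c in np.unique(lab):
            rows = lab == c
            med = np.nanmedian(M[rows], axis=0)
            med = np.where(np.isnan(med), np.nanmedian(M, axis=0), med)
            block = M[rows]
            idx = np.where(np.isnan(block))
            block[idx] = med[idx[1]]
            M[rows] = block
        return M

    errors = 0
    n = X.shape[0]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr_raw, ytr = X[mask], y[mask]
        Xtr = impute(Xtr_raw, ytr)
        xte = X[i].copy()
        if np.isnan(xte).any():
            med = np.nanmedian(Xtr_raw[ytr == y[i]], axis=0)
            med = np.where(np.isnan(med), np.nanmedian(Xtr_raw, axis=0), med)
            xte[np.isnan(xte)] = med[np.isnan(xte)]
        pred = _fisher_lda_predict(Xtr, ytr, xte[None, :])[0]
        errors += int(pred != y[i])
    return errors / n


def wave_feature_matrix(models) -> tuple[np.ndarray, list[str]]:
    """Morphology feature matrix for discrimination: A, omega, beta per wave.

    One row per beat model, 15 columns (3 per wave in P..T order); waves a
    model is missing yield NaN, to be median-imputed by :func:`lda_loocv`.
    """
    cols = [f"{p}_{lab}" for lab in WAVE_LABELS for p in ("A", "omega", "beta")]
    rows = []
    for m in models:
        params = m.params if hasattr(m, "params") else m
        row = []
        for lab in WAVE_LABELS:
            w = params.waves.get(lab)
            row += [w.A, w.omega, w.beta] if w is not None else [np.nan] * 3
        rows.append(row)
    return np.asarray(rows, dtype=float), cols
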