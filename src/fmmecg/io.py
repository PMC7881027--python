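"""Plain-text readers and writers.

Records travel as CSV/TSV: either a single voltage column (sampling rate
supplied separately) or two columns ``time_s,voltage`` on a uniform grid.
Annotations are one integer sample index per line.  Fit results serialise
to a one-row-per-wave CSV plus a JSON with the full parameter vector.
Phases in analysis outputs are radians in [0, 2*pi); times in files are
seconds, milliseconds or sample indices, as named.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TWO_PI, WAVE_LABELS, ModelParams, fiducial_mark
from .segmentation import BeatSignal, QrsAnnotations

__all__ = [
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
    "fit_wave_table",
    "write_fit",
    "read_fit_json",
    "load_miconfig",
]

_REL_TOL_SPACING = 1e-6


def _load_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    first = path.read_text().lstrip().splitlines()
    if not first:
        raise ValueError(f"{path}: empty file")
    try:
        [float(x) for x in first[0].replace("\t", ",").split(",") if x.strip()]
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, sep=sep, header=header, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_signal(path, fs: float | None = None):
    """Read a voltage record; returns ``(values, fs)``.

    One column: ``fs`` must be given.  Two columns (time_s, voltage): ``fs``
    is derived from the spacing, which must be uniform to a relative
    tolerance of 1e-6.
    """
    path = Path(path)
    df = _load_table(path)
    if df.shape[1] == 1:
        if fs is None or fs <= 0:
            raise ValueError("single-column signal requires a positive fs")
        return df.iloc[:, 0].to_numpy(dtype=float), float(fs)
    if df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError(f"{path}: time column must be strictly increasing")
        if (dt.max() - dt.min()) > _REL_TOL_SPACING * dt.mean():
            raise ValueError(f"{path}: non-uniform sampling (jittered time column)")
        return v, 1.0 / float(dt.mean())
    raise ValueError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")


def write_signal(values, path) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.17g")


def read_annotations(path, fs: float) -> QrsAnnotations:
    """Read QRS annotation sample indices, one integer per line."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty annotation file")
    try:
        samples = tuple(int(ln) for ln in lines)
    except ValueError as err:
        raise ValueError(f"{path}: annotations must be integer sample indices") from err
    return QrsAnnotations(samples=samples, fs=fs)


def write_annotations(ann: QrsAnnotations, path) -> None:
    Path(path).write_text("\n".join(str(s) for s in ann.samples) + "\n")


def fit_wave_table(fit, beat: BeatSignal) -> pd.DataFrame:
    """One row per assigned wave: parameters, fiducial phases and their
    positions in milliseconds from the record start."""
    rows = []
    for lab in WAVE_LABELS:
        w = fit.params.waves.get(lab)
        if w is None:
            continue
        marks = fiducial_mark(w)
        rows.append({
            "beat_id": beat.beat_id,
            "label": lab,
            "A": w.A,
            "alpha": w.alpha,
            "beta": w.beta,
            "omega": w.omega,
            "t_U": marks.t_U,
            "t_L": marks.t_L,
            "t_FI": marks.t_FI,
            "t_FI_ms": float(beat.phase_to_ms(marks.t_FI)),
            "pv": fit.pv_by_wave.get(lab, float("nan")),
        })
    return pd.DataFrame(rows)


def write_fit(fit, beat: BeatSignal, path) -> None:
    """Write ``<path>.csv`` (per-wave rows) and ``<path>.json`` (full state)."""
    base = Path(path)
    fit_wave_table(fit, beat).to_csv(base.with_suffix(".csv"), index=False)
    doc = {
        "beat_id": beat.beat_id,
        "theta": fit.params.to_dict(),
        "r2": fit.r2,
        "sigma2": fit.sigma2,
        "pv_by_wave": fit.pv_by_wave,
        "status": fit.status,
        "n_iter": fit.n_iter,
        "window": list(beat.window),
        "fs": beat.fs,
    }
    base.with_suffix(".json").write_text(json.dumps(doc, indent=2))


def read_fit_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    doc["params"] = ModelParams.from_dict(doc["theta"])
    return doc


def load_miconfig(path) -> "MIConfig":
    """Load estimator settings from a YAML file mirroring MIConfig fields.

    Unknown keys are rejected so typos fail loudly; `r_beta_interval` may
    be given as a two-element list.
    """
    import dataclasses

    import yaml

    from .estimator import MIConfig

    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping of MIConfig fields")
    valid = {f.name for f in dataclasses.fields(MIConfig)}
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"{path}: unknown MIConfig fields {sorted(unknown)}")
    if "r_beta_interval" in doc:
        doc["r_beta_interval"] = tuple(doc["r_beta_interval"])
    return MIConfig(**doc)
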