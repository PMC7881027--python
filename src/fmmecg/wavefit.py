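"""Least-squares fitting of a single FMM wave (plus intercept).

This is the inner solver that the beat estimator's backfitting calls many
times per beat.  The key structural fact it exploits is that for fixed
location ``alpha`` and sharpness ``omega`` the wave

    M + A*cos(beta + phi(t; alpha, omega))
      = M + (A cos beta) * cos(phi) - (A sin beta) * sin(phi)

is *linear* in ``(M, A cos beta, -A sin beta)``, so the profile likelihood
over ``(alpha, omega)`` can be evaluated by ordinary least squares.  The fit
is a coarse grid search over ``(alpha, omega)`` followed by a Nelder-Mead
refinement, re-solving the linear subproblem at every probe point.

Because backfitting re-enters this solver with the same time grid over and
over, the grid's regressor Gram matrices are precomputed once per time grid
(:class:`DesignGrid`) which turns each grid search into two matrix-vector
products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .model import TWO_PI, WaveParams, phase_transform, wrap_angle

__all__ = ["GridConfig", "DesignGrid", "linear_substep", "fit_single_fmm", "refine_joint"]

_OMEGA_FLOOR = 1e-3  # refinement clamp; grid itself starts at 0.01


@dataclass(frozen=True)
class GridConfig:
    """Search grid for the (alpha, omega) profile.

    48 equispaced locations cover the circle; the omega ladder spans
    spike-like QRS sharpness (0.01-0.1) through sinusoidal (1.0).
    """

    alpha_grid_size: int = 48
    omega_grid: Sequence[float] = (0.01, 0.02, 0.05, 0.1, 0.15, 0.25, 0.5, 1.0)
    refine: bool = True

    def __post_init__(self):
        if self.alpha_grid_size < 8:
            raise ValueError("alpha_grid_size must be >= 8")
        og = tuple(float(w) for w in self.omega_grid)
        if not og or any(not (0.0 < w <= 1.0) for w in og):
            raise ValueError("omega grid values must lie in (0, 1]")
        object.__setattr__(self, "omega_grid", og)


def _ols_cos_sin(times, values, alpha, omega):
    """OLS of values on {1, cos phi, sin phi}; returns (m, d, g, rss, rank)."""
    phi = phase_transform(times, alpha, omega)
    X = np.column_stack([np.ones_like(phi), np.cos(phi), np.sin(phi)])
    coef, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ coef
    return coef[0], coef[1], coef[2], float(resid @ resid), rank


def _amp_phase(d: float, g: float) -> tuple[float, float]:
    """Recover (A, beta) from d = A cos(beta), g = -A sin(beta)."""
    A = math.hypot(d, g)
    beta = float(wrap_angle(math.atan2(-g, d))) if A > 0 else 0.0
    return A, beta


def linear_substep(times, values, alpha: float, omega: float):
    """Exact least squares over (M, A, beta) at fixed (alpha, omega).

    Returns ``(M, A, beta, rss)``.  Raises ``ValueError`` when the design is
    rank-deficient (a degenerate window where the warped phase carries no
    cosine/sine variation).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 samples")
    m, d, g, rss, rank = _ols_cos_sin(times, values, alpha, omega)
    if rank < 3:
        raise ValueError("degenerate window: constant warped phase")
    A, beta = _amp_phase(d, g)
    return float(m), A, beta, rss


class DesignGrid:
    """Precomputed OLS machinery for one time grid and one GridConfig.

    For each grid node ``(alpha_i, omega_j)`` stores the regressors
    ``cos(phi)``, ``sin(phi)`` and the inverse Gram matrix of
    ``[1, cos(phi), sin(phi)]`` so that the residual sum of squares at all
    nodes for a new response vector costs two (G, n) mat-vecs.

    Nodes are ordered by ascending omega then alpha so that ``argmin`` ties
    resolve to the sharpest wave deterministically.
    """

    def __init__(self, times, cfg: GridConfig):
        times = np.asarray(times, dtype=float)
        self.times = times
        self.cfg = cfg
        alphas = np.linspace(0.0, TWO_PI, cfg.alpha_grid_size, endpoint=False)
        omegas = np.asarray(cfg.omega_grid, dtype=float)
        # omega-major ordering: ties in rss pick the smallest omega first
        self.node_omega = np.repeat(omegas, alphas.size)
        self.node_alpha = np.tile(alphas, omegas.size)
        n = times.size
        G = self.node_alpha.size
        C = np.empty((G, n))
        S = np.empty((G, n))
        for j, om in enumerate(omegas):
            for i, al in enumerate(alphas):
                phi = phase_transform(times, al, om)
                k = j * alphas.size + i
                C[k] = np.cos(phi)
                S[k] = np.sin(phi)
        self.C, self.S = C, S
        XtX = np.empty((G, 3, 3))
        XtX[:, 0, 0] = n
        XtX[:, 0, 1] = XtX[:, 1, 0] = C.sum(axis=1)
        XtX[:, 0, 2] = XtX[:, 2, 0] = S.sum(axis=1)
        XtX[:, 1, 1] = np.einsum("ij,ij->i", C, C)
        XtX[:, 1, 2] = XtX[:, 2, 1] = np.einsum("ij,ij->i", C, S)
        XtX[:, 2, 2] = np.einsum("ij,ij->i", S, S)
        self.XtX_inv = np.linalg.inv(XtX)

    def best_node(self, values):
        """(alpha, omega, rss) of the best grid node for this response."""
        return self.best_nodes(values)[0]

    def best_nodes(self, values):
        """Best grid node overall plus, when that node is sinusoidal
        (omega = 1, where alpha is unidentifiable), the best node with
        omega < 1 as a second refinement start."""
        y = np.asarray(values, dtype=float)
        Xty = np.stack([np.full(self.node_alpha.size, y.sum()), self.C @ y, self.S @ y], axis=1)
        coef = np.einsum("gij,gj->gi", self.XtX_inv, Xty)
        rss = y @ y - np.einsum("gi,gi->g", coef, Xty)
        k = int(np.argmin(rss))
        out = [(float(self.node_alpha[k]), float(self.node_omega[k]), float(rss[k]))]
        sub = self.node_omega < 1.0
        if self.node_omega[k] >= 1.0 and np.any(sub):
            idx = np.flatnonzero(sub)
            k2 = idx[int(np.argmin(rss[idx]))]
            out.append((float(self.node_alpha[k2]), float(self.node_omega[k2]),
                        float(rss[k2])))
        return out


_GRID_CACHE: dict = {}


def get_design_grid(times, cfg: GridConfig) -> DesignGrid:
    """Memoised :class:`DesignGrid` for a given time grid and config."""
    times = np.asarray(times, dtype=float)
    key = (hash(times.tobytes()), times.size, cfg)
    grid = _GRID_CACHE.get(key)
    if grid is None or grid.times.shape != times.shape or not np.array_equal(grid.times, times):
        grid = DesignGrid(times, cfg)
        if len(_GRID_CACHE) > 16:
            _GRID_CACHE.clear()
        _GRID_CACHE[key] = grid
    return grid


def _profile_rss(times, values, alpha, omega):
    m, d, g, rss, _ = _ols_cos_sin(times, values, alpha, omega)
    return rss


def fit_single_fmm(times, values, cfg: GridConfig | None = None, *, grid: DesignGrid | None = None):
    """Fit intercept plus one FMM wave by profiled least squares.

    Grid search over ``(alpha, omega)`` (via :class:`DesignGrid`), then, if
    ``cfg.refine``, Nelder-Mead refinement of ``(alpha, omega)`` with the
    linear parameters re-profiled at each probe.  The refined solution is
    kept only when it does not increase the residual sum of squares, so the
    returned rss is never worse than the best grid node's.

    Returns ``(M, WaveParams, rss)``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size < 8:
        raise ValueError("need at least 8 samples")
    if cfg is None:
        cfg = grid.cfg if grid is not None else GridConfig()
    if grid is None:
        grid = get_design_grid(times, cfg)

    # centre and scale the response so the optimiser's stopping tolerances
    # are unit-free: the fit is then exactly shift- and scale-equivariant
    shift = float(values.mean())
    scale = float(values.std())
    if scale == 0.0:
        return shift, WaveParams(A=0.0, alpha=0.0, beta=0.0, omega=1.0), 0.0
    values = (values - shift) / scale

    starts = grid.best_nodes(values)
    alpha, omega, rss = starts[0]

    if cfg.refine:
        def objective(x):
            a, om = x
            omc = min(max(om, _OMEGA_FLOOR), 1.0)
            # quadratic penalty outside (floor, 1] instead of a flat clamp:
            # a flat plateau beyond omega = 1 swallows the simplex when it
            # overshoots a broad-wave minimum (the response is normalised,
            # so the penalty scale is unit-free)
            penalty = 10.0 * times.size * (om - omc) ** 2
            return _profile_rss(times, values, a, omc) + penalty

        d_alpha = TWO_PI / cfg.alpha_grid_size
        for a0, om0, rss0 in starts:
            # the omega vertex must move off the boundary: at omega = 1 the
            # location angle is unidentifiable (pure sinusoid), so a simplex
            # clipped to the boundary could never explore sharper shapes
            om_vertex = om0 * 1.5
            if om_vertex > 1.0:
                om_vertex = om0 * 0.7
            om_vertex = min(max(om_vertex, _OMEGA_FLOOR), 1.0)
            res = minimize(
                objective,
                x0=[a0, om0],
                method="Nelder-Mead",
                options={
                    "initial_simplex": [
                        [a0, om0],
                        [a0 + 0.5 * d_alpha, om0],
                        [a0, om_vertex],
                    ],
                    "xatol": 1e-6,
                    "fatol": 1e-12,
                    "maxiter": 300,
                },
            )
            if res.fun < rss:
                alpha = float(wrap_angle(res.x[0]))
                omega = float(min(max(res.x[1], _OMEGA_FLOOR), 1.0))
                rss = float(res.fun)

    m, d, g, rss_fin, rank = _ols_cos_sin(times, values, alpha, omega)
    A, beta = _amp_phase(d, g)
    return (
        shift + scale * float(m),
        WaveParams(A=scale * A, alpha=alpha, beta=beta, omega=omega),
        scale * scale * float(rss_fin),
    )


def refine_joint(times, values, waves, *, maxiter: int = 3000,
                 omega_floor: float = _OMEGA_FLOOR):
    """Joint derivative-free refinement of several waves' (alpha, omega).

    Backfitting optimises one component at a time and can stall where two
    overlapping sharp waves trade energy; this polishes all location and
    sharpness parameters together by Nelder-Mead, re-profiling the linear
    parameters (intercept, per-wave amplitude and shape angle) exactly by
    OLS at every probe.  Returns ``(M, waves, rss)``; never returns a worse
    rss than the starting configuration.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    K = len(waves)
    if K == 0:
        raise ValueError("need at least one wave")
    shift = float(values.mean())
    scale = float(values.std())
    if scale == 0.0:
        scale = 1.0
    values = (values - shift) / scale
    ones = np.ones_like(times)

    def design(x):
        cols = [ones]
        for k in range(K):
            a = x[2 * k]
            om = min(max(x[2 * k + 1], omega_floor), 1.0)
            phi = phase_transform(times, a, om)
            cols.append(np.cos(phi))
            cols.append(np.sin(phi))
        return np.column_stack(cols)

    def solve(x):
        X = design(x)
        coef, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
        resid = values - X @ coef
        return coef, float(resid @ resid)

    x0 = np.empty(2 * K)
    for k, w in enumerate(waves):
        x0[2 * k] = w.alpha
        x0[2 * k + 1] = w.omega
    _, rss0 = solve(x0)

    res = minimize(lambda x: solve(x)[1], x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-14})
    x = res.x if res.fun <= rss0 else x0
    coef, rss = solve(x)
    out = []
    for k in range(K):
        d, g = coef[1 + 2 * k], coef[2 + 2 * k]
        A, beta = _amp_phase(float(d), float(g))
        out.append(WaveParams(A=scale * A, alpha=float(wrap_angle(x[2 * k])), beta=beta,
                              omega=float(min(max(x[2 * k + 1], omega_floor), 1.0))))
    return shift + scale * float(coef[0]), out, scale * scale * rss
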