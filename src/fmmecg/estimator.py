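"""The Maximization-Identification (MI) estimation algorithm.

A beat is fit as an intercept plus ``K >= 5`` FMM components via backfitting
(the M step: cyclic refits of one component against the residual of the
others), after which wave letters P, Q, R, S, T are assigned to components
by morphology rules (the I step): R is the sharp, crest-shaped, high
explained-variance component near the supplied QRS phase; the remaining
letters are preassigned by circular location order around R and revoked when
they violate the expected morphology (P/T crests, Q/S troughs, Q sharper
than P), in which case lower-ranked components are searched.  M and I steps
alternate until the explained variance stabilises.

The letter-assignment thresholds below are tunable defaults chosen for
near-lead-II morphology; they are exposed in :class:`MIConfig` and are not
authoritative clinical constants.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import (
    TWO_PI,
    WAVE_LABELS,
    ModelParams,
    WaveParams,
    circular_distance,
    crest_trough_times,
    fmm_wave,
    is_circular_order,
    is_positive_wave,
    wrap_angle,
)
from .wavefit import DesignGrid, GridConfig, fit_single_fmm, get_design_grid, refine_joint

__all__ = [
    "MIConfig",
    "FMMComponent",
    "FMMEcgFit",
    "WaveIdentificationError",
    "backfit_pass",
    "explained_variance_profile",
    "marginal_pv",
    "order_components",
    "identify_R",
    "assign_waves",
    "fit_beat",
]

logger = logging.getLogger(__name__)

_ZERO_WAVE = WaveParams(A=0.0, alpha=0.0, beta=0.0, omega=1.0)

#: backfitting turns after each component introduction in the first M step
_GROW_TURNS = 3

#: Cyclic position of each letter in the activation sequence.
_LETTER_INDEX = {lab: i for i, lab in enumerate(WAVE_LABELS)}


class WaveIdentificationError(RuntimeError):
    """Raised when the I step cannot identify a required wave (e.g. R)."""


@dataclass(frozen=True)
class MIConfig:
    """Tunable knobs of the MI algorithm.

    K_max
        Number of components carried by the M step; waves of atypical beats
        may hide in the sixth or seventh component.
    max_iter, pv_tol
        Stop when the full-model R-squared gain falls below ``pv_tol``
        (0.01% as a fraction) or after ``max_iter`` MI iterations.
    first_pass_turns
        Backfitting turns in the first M step (started from zero components).
    r_beta_interval, r_omega_max, qrs_proximity
        R-wave filters: shape angle inside the interval (a crest, not a
        trough), sharpness below ``r_omega_max``, crest phase within
        ``qrs_proximity`` radians of the annotated QRS phase.
    noise_pv_max, noise_omega_max
        A component with explained-variance increment *and* sharpness both
        below these is flagged as noise and never lettered.
    """

    K_max: int = 7
    max_iter: int = 10
    pv_tol: float = 1e-4
    first_pass_turns: int = 5
    r_beta_interval: tuple[float, float] = (math.pi / 2.0, 5.0 * math.pi / 3.0)
    r_omega_max: float = 0.12
    qrs_proximity: float = 0.2 * math.pi
    noise_pv_max: float = 0.005
    noise_omega_max: float = 0.02
    joint_refine: bool = True
    refine_maxiter: int = 3000
    grid: GridConfig = field(default_factory=GridConfig)

    def __post_init__(self):
        if self.K_max < 5:
            raise ValueError("K_max must be >= 5")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FMMComponent:
    """One fitted oscillatory component and its bookkeeping.

    ``pv`` is the ordered explained-variance increment (telescopes to the
    full-model R-squared); ``pv_marginal`` is the leave-one-out contribution
    (full R-squared minus R-squared without this component), which is
    order-independent and is what the noise detection looks at.
    """

    w: WaveParams
    M_share: float = 0.0
    pv: float = 0.0
    pv_marginal: float | None = None
    label: str = "unassigned"  # P,Q,R,S,T | unassigned | noise


@dataclass(frozen=True)
class FMMEcgFit:
    """Result of fitting one beat.

    ``params`` holds the intercept and the lettered waves (all five only
    when ``status == "OK"``).  ``r2`` and ``sigma2`` refer to the full
    K-component fit, whose explained variance the per-component ``pv``
    values telescope to.
    """

    params: ModelParams
    sigma2: float
    r2: float
    pv_by_wave: dict
    status: str  # "OK" | "incomplete"
    n_iter: int
    components: list
    r2_history: tuple = ()

    def predict(self, t):
        """Full fitted curve (intercept plus every component)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.params.M, dtype=float)
        for c in self.components:
            out += fmm_wave(t, c.w)
        return out if out.ndim else float(out)


def _component_values(times, components):
    return [fmm_wave(times, c.w) if c.w.A != 0.0 else np.zeros_like(times) for c in components]


def backfit_pass(times, values, components: Sequence[FMMComponent], cfg: MIConfig | None = None,
                 *, grid: DesignGrid | None = None) -> list[FMMComponent]:
    """One full backfitting turn: refit each component on the others' residual.

    Coordinate descent over (intercept, component k) blocks, so the total
    model residual sum of squares cannot increase across the pass.
    """
    cfg = cfg or MIConfig()
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = get_design_grid(times, cfg.grid)
    comps = [replace(c) if isinstance(c, FMMComponent) else FMMComponent(c) for c in components]
    vals = _component_values(times, comps)
    total = np.sum(vals, axis=0)
    for k, c in enumerate(comps):
        resid = values - (total - vals[k])
        m, w, _ = fit_single_fmm(times, resid, grid=grid)
        c.w = w
        c.M_share = m
        new_vals = fmm_wave(times, w)
        total += new_vals - vals[k]
        vals[k] = new_vals
    return comps


def order_components(times, values, components: Sequence[FMMComponent]) -> list[FMMComponent]:
    """Sort components by decreasing individual explained-variance contribution.

    The contribution is measured leave-one-out within the fitted ensemble
    (full-model R-squared minus the R-squared without the component), which
    is well defined for narrow spike-like waves whose in-isolation variance
    is dominated by their own baseline offset.
    """
    comps = list(components)
    loo = marginal_pv(times, values, comps)
    order = sorted(range(len(comps)), key=lambda i: loo[i], reverse=True)
    return [comps[i] for i in order]


def explained_variance_profile(times, values, components: Sequence[FMMComponent]):
    """Cumulative R-squared and per-component increments (PV).

    ``r2_cumulative[k]`` is the coefficient of determination of the model
    using the first ``k + 1`` components (with the intercept re-profiled at
    each truncation); ``pv`` are its first differences, so they telescope to
    the full-model R-squared.  Components are expected pre-ordered by
    decreasing individual contribution (:func:`order_components`).
    """
    values = np.asarray(values, dtype=float)
    tss = float(np.sum((values - values.mean()) ** 2))
    if tss <= 0:
        raise ValueError("zero-variance signal")
    partial = np.zeros_like(values)
    r2_cum = []
    for c in components:
        partial = partial + fmm_wave(times, c.w)
        resid = values - partial
        rss = float(np.sum((resid - resid.mean()) ** 2))
        r2_cum.append(1.0 - rss / tss)
    pv = np.diff([0.0] + r2_cum).tolist()
    return pv, r2_cum


def marginal_pv(times, values, components) -> list[float]:
    """Leave-one-out explained-variance contribution of each component."""
    values = np.asarray(values, dtype=float)
    tss = float(np.sum((values - values.mean()) ** 2))
    if tss <= 0:
        raise ValueError("zero-variance signal")
    vals = _component_values(times, components)
    total = np.sum(vals, axis=0)

    def r2_of(fit_sum):
        resid = values - fit_sum
        return 1.0 - float(np.sum((resid - resid.mean()) ** 2)) / tss

    r2_full = r2_of(total)
    return [r2_full - r2_of(total - v) for v in vals]


def _noise_pv(c: FMMComponent) -> float:
    return c.pv if c.pv_marginal is None else c.pv_marginal


def _mark_noise(comps, cfg, keep: int | None = None):
    """Flag components that carry no signal.

    Two rules on the (marginal) explained variance: the morphological one
    (small contribution *and* spike-like sharpness) and an unconditional
    floor — a component contributing less than the convergence tolerance is
    overfit bookkeeping, whatever its shape, and must never get a letter.
    """
    for i, c in enumerate(comps):
        if i == keep:
            continue
        pv = _noise_pv(c)
        if pv < cfg.noise_pv_max and c.w.omega < cfg.noise_omega_max:
            c.label = "noise"
        elif pv < cfg.pv_tol:
            c.label = "noise"


def identify_R(components: Sequence[FMMComponent], qrs_phase: float, cfg: MIConfig,
               intercept: float = 0.0) -> int:
    """Pick the R-wave component.

    Candidates are the top five components (by PV) whose crest phase lies
    within ``cfg.qrs_proximity`` of the annotated QRS phase, whose shape
    angle lies in ``cfg.r_beta_interval`` (a crest, not a trough) and whose
    sharpness is below ``cfg.r_omega_max``.  Among candidates the one with
    the largest fitted-model value at its own crest wins.
    """
    lo, hi = cfg.r_beta_interval
    candidates = []
    for i, c in enumerate(components[: min(5, len(components))]):
        if c.w.A == 0.0 or c.label == "noise":
            continue
        t_u = crest_trough_times(c.w).t_U
        if circular_distance(t_u, qrs_phase) > cfg.qrs_proximity:
            continue
        if not (lo < c.w.beta < hi):
            continue
        if c.w.omega >= cfg.r_omega_max:
            continue
        mu = intercept + sum(fmm_wave(t_u, cc.w) for cc in components)
        candidates.append((mu, i))
    if not candidates:
        raise WaveIdentificationError(
            "no component qualifies as the R wave "
            f"(qrs_phase={qrs_phase:.3f}, filters: beta in ({lo:.3f},{hi:.3f}), "
            f"omega<{cfg.r_omega_max}, proximity<{cfg.qrs_proximity:.3f})"
        )
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return candidates[0][1]


def _letters_consistent(assignment: dict) -> bool:
    """Circular-order check over whichever letters are currently assigned."""
    present = [lab for lab in WAVE_LABELS if lab in assignment]
    if len(present) < 2:
        return True
    angles = np.asarray([assignment[lab] for lab in present])
    offs = wrap_angle(angles - angles[0])
    return bool(np.all(np.diff(offs) >= 0.0))


def _morphology_ok(letter: str, w: WaveParams, assignment: dict,
                   comps_by_letter: dict) -> bool:
    """Expected per-letter morphology: P/T crests, Q/S troughs, Q sharper than P."""
    positive = is_positive_wave(w)
    if letter in ("P", "T") and not positive:
        return False
    if letter in ("Q", "S") and positive:
        return False
    if letter == "Q" and "P" in comps_by_letter:
        if w.omega >= comps_by_letter["P"].w.omega:
            return False
    trial = dict(assignment)
    trial[letter] = w.alpha
    return _letters_consistent(trial)


def assign_waves(components: Sequence[FMMComponent], r_index: int, qrs_phase: float,
                 cfg: MIConfig) -> list[FMMComponent]:
    """Letter the components around an already-identified R wave.

    Free components among the top five are preassigned S, T, P, Q by
    increasing circular location after R (the activation order).  Letters
    whose component violates the expected morphology are revoked in the
    cascade order Q, P, S, T and re-searched among the components ranked
    beyond the top five; letters that stay unfilled leave the fit
    incomplete.  Components below the noise thresholds are flagged ``noise``
    and never lettered.
    """
    comps = [replace(c) for c in components]
    for c in comps:
        c.label = "unassigned"
    _mark_noise(comps, cfg, keep=r_index)
    comps[r_index].label = "R"
    alpha_r = comps[r_index].w.alpha

    free = [i for i, c in enumerate(comps)
            if i != r_index and c.label != "noise" and c.w.A > 0]
    free.sort(key=lambda i: wrap_angle(comps[i].w.alpha - alpha_r))
    roles = ("S", "T", "P", "Q")

    def _weight(c):
        return max(_noise_pv(c), 0.0) + 1e-12

    # preassignment: assign the roles S, T, P, Q (the circular activation
    # order after R) to components so that polarities are respected (P/T
    # crests, Q/S troughs), the circular order is preserved, and the total
    # explained variance of the lettered components is maximal.  Components
    # beyond the top five may take a letter here; that is where waves of
    # atypical fits hide.
    best_pairing, best_score = (), -math.inf
    for k in range(min(len(free), 4), -1, -1):
        for comp_sub in combinations(free, k):
            for role_sub in combinations(range(4), k):
                score = 0.0
                ok = True
                for i, ri in zip(comp_sub, role_sub):
                    letter = roles[ri]
                    if (letter in ("P", "T")) != is_positive_wave(comps[i].w):
                        ok = False
                        break
                    score += _weight(comps[i])
                if ok and score > best_score:
                    best_score = score
                    best_pairing = tuple(zip(comp_sub, role_sub))
    for i, ri in best_pairing:
        comps[i].label = roles[ri]

    def current_assignment(skip=None):
        return {c.label: c.w.alpha for c in comps
                if c.label in _LETTER_INDEX and c.label != skip}

    def comps_by_letter(skip=None):
        return {c.label: c for c in comps
                if c.label in _LETTER_INDEX and c.label != skip}

    # revocation cascade: for each letter keep the morphology-passing
    # candidate (current holder or any unlettered component, including the
    # tail ranks beyond the top five) that explains the most variance
    for letter in ("Q", "P", "S", "T"):
        holder = next((c for c in comps if c.label == letter), None)
        others = current_assignment(skip=letter)
        by_letter = comps_by_letter(skip=letter)
        candidates = [c for c in comps
                      if c is holder or (c.label == "unassigned" and c.w.A > 0)]
        valid = [c for c in candidates if _morphology_ok(letter, c.w, others, by_letter)]
        if not valid:
            if holder is not None:
                holder.label = "unassigned"
                logger.debug("revoked %s: morphology check failed", letter)
            continue
        best = max(valid, key=_weight)
        if best is not holder:
            if holder is not None:
                holder.label = "unassigned"
                logger.debug("revoked %s in favour of a better candidate", letter)
            best.label = letter
    return comps


def _score_components(times, values, comps):
    """Order components, refresh pv/marginal-pv bookkeeping, clear labels."""
    comps = order_components(times, values, comps)
    pv, r2_cum = explained_variance_profile(times, values, comps)
    loo = marginal_pv(times, values, comps)
    for c, p, m in zip(comps, pv, loo):
        c.pv = p
        c.pv_marginal = m
        c.label = "unassigned"
    return comps, r2_cum[-1]


def _letter_components(times, values, comps, qrs_phase, cfg):
    """One I step: find R, then assign the remaining letters."""
    intercept = float(np.mean(values - np.sum(_component_values(times, comps), axis=0)))
    r_idx = identify_R(comps, qrs_phase, cfg, intercept=intercept)
    return assign_waves(comps, r_idx, qrs_phase, cfg)


def fit_beat(beat, cfg: MIConfig | None = None) -> FMMEcgFit:
    """Run the full MI algorithm on one beat.

    ``beat`` is any object with ``times`` (phases in [0, 2*pi)), ``values``
    and ``qrs_phase`` attributes (:class:`fmmecg.segmentation.BeatSignal`).
    The first M step backfits up to ``cfg.first_pass_turns`` turns from zero
    components; each later iteration re-initialises with the currently
    lettered waves (zeros elsewhere) and makes one turn.  Iteration stops
    when the full-model R-squared gain drops below ``cfg.pv_tol`` or at
    ``cfg.max_iter``.
    """
    cfg = cfg or MIConfig()
    times = np.asarray(beat.times, dtype=float)
    values = np.asarray(beat.values, dtype=float)
    if times.size < 40:
        raise ValueError("beat must have at least 40 samples")
    tss = float(np.sum((values - values.mean()) ** 2))
    if tss <= 0:
        raise ValueError("degenerate beat: constant signal")
    qrs_phase = float(beat.qrs_phase)
    grid = get_design_grid(times, cfg.grid)

    comps = [FMMComponent(_ZERO_WAVE) for _ in range(cfg.K_max)]
    r2_history: list[float] = []
    prev_r2 = None
    best_complete = None
    identified = False
    n_iter = 0

    for it in range(1, cfg.max_iter + 1):
        n_iter = it
        if it == 1:
            # first M step: introduce components one at a time, with short
            # backfitting interludes — far more robust against two adjacent
            # sharp waves being merged into one component than starting all
            # K slots at zero
            comps = []
            for _ in range(cfg.K_max):
                comps = comps + [FMMComponent(_ZERO_WAVE)]
                for _ in range(_GROW_TURNS):
                    comps = backfit_pass(times, values, comps, cfg, grid=grid)
        else:
            lettered = [c for c in comps if c.label in _LETTER_INDEX]
            comps = [replace(c) for c in lettered]
            comps += [FMMComponent(_ZERO_WAVE) for _ in range(cfg.K_max - len(comps))]
        # backfit until the turn-to-turn gain stalls (the number of useful
        # turns depends on the initialisation)
        turn_r2 = 0.0
        for _ in range(cfg.first_pass_turns):
            comps = backfit_pass(times, values, comps, cfg, grid=grid)
            _, r2_cum = explained_variance_profile(times, values, comps)
            if r2_cum[-1] - turn_r2 < cfg.pv_tol:
                turn_r2 = r2_cum[-1]
                break
            turn_r2 = r2_cum[-1]

        comps, r2_full = _score_components(times, values, comps)
        try:
            comps = _letter_components(times, values, comps, qrs_phase, cfg)
        except WaveIdentificationError as err:
            logger.info("I step failed: %s", err)
            break
        identified = True

        lettered = [c for c in comps if c.label in _LETTER_INDEX]
        if cfg.joint_refine and lettered:
            # polish all lettered waves together against the raw signal:
            # backfitting stalls where overlapping sharp waves trade energy,
            # and the joint move can cross that valley.  The polished waves
            # then carry the whole fit, so the remaining slots restart at
            # zero (they regrow in the next M step if needed); letters may
            # migrate between components in the process, so identify again
            # afterwards, falling back to the pre-polish letters if that
            # fails
            snapshot = [replace(c) for c in comps]
            r2_snapshot = r2_full
            _, polished, _ = refine_joint(
                times, values, [c.w for c in lettered], maxiter=cfg.refine_maxiter
            )
            for c, w in zip(lettered, polished):
                c.w = w
            comps = [replace(c) for c in lettered]
            comps += [FMMComponent(_ZERO_WAVE) for _ in range(cfg.K_max - len(comps))]
            comps, r2_polished = _score_components(times, values, comps)
            try:
                comps = _letter_components(times, values, comps, qrs_phase, cfg)
                r2_full = r2_polished
            except WaveIdentificationError:
                logger.info("post-polish identification failed; keeping "
                            "pre-polish letters")
                comps = snapshot
                r2_full = r2_snapshot

        labels_now = {c.label for c in comps if c.label in _LETTER_INDEX}
        if len(labels_now) == 5:
            alphas = {c.label: c.w.alpha for c in comps if c.label in _LETTER_INDEX}
            if is_circular_order([alphas[lab] for lab in WAVE_LABELS]) and (
                best_complete is None or r2_full > best_complete[0]
            ):
                best_complete = (r2_full, [replace(c) for c in comps])

        # the trajectory the algorithm retains is the best solution so far;
        # an intermediate iterate may dip (productively) when a mislabelled
        # wave is dropped and regrown
        r2_history.append(max(r2_full, r2_history[-1]) if r2_history else r2_full)

        if prev_r2 is not None and abs(r2_full - prev_r2) < cfg.pv_tol:
            break
        prev_r2 = r2_full

    # return the best fully lettered solution seen; fall back to the final
    # iterate only when no iterate ever carried all five letters
    if best_complete is not None:
        r2_keep, comps = best_complete
        identified = True
        r2_history = r2_history or [r2_keep]

    total = np.sum(_component_values(times, comps), axis=0)
    M = float(np.mean(values - total))
    rss = float(np.sum((values - M - total) ** 2))
    sigma2 = rss / times.size
    r2 = 1.0 - rss / tss

    waves = {c.label: c.w for c in comps if c.label in _LETTER_INDEX}
    params = ModelParams(M=M, waves=waves)
    complete = identified and len(waves) == 5
    ok = complete and is_circular_order([waves[lab].alpha for lab in WAVE_LABELS])
    pv_by_wave = {lab: max(0.0, c.pv) for lab, c in
                  ((c.label, c) for c in comps if c.label in _LETTER_INDEX)}
    status = "OK" if ok else "incomplete"
    logger.info("beat fit: status=%s r2=%.5f iters=%d", status, r2, n_iter)
    return FMMEcgFit(
        params=params,
        sigma2=sigma2,
        r2=r2,
        pv_by_wave=pv_by_wave,
        status=status,
        n_iter=n_iter,
        components=comps,
        r2_history=tuple(r2_history),
    )
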