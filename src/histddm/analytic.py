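"""Closed-form drift-diffusion choice probabilities and how pooling
history-biased initial states manufactures apparent lapses.

For a diffusion dx = μ dt + σ dW started at x(0) = I between absorbing
bounds ±B, the probability of absorbing at +B is

    P(B+) = (1 − e^{−2μ(B+I)/σ²}) / (1 − e^{−4μB/σ²}),

which reduces to the logistic function of μB/σ² only when I = 0. Small
|I| shifts the psychometric curve horizontally; large |I| additionally
flattens its effective slope. Averaging choices over a distribution of
history-dependent I therefore yields a heavy-tailed pooled curve whose
4-parameter-logistic fit shows nonzero "lapse" asymptotes even though no
evidence-independent process is present: apparent lapses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .history import HistoryFilterParams, HistoryState, update_history

__all__ = [
    "SimpleDDMParams",
    "choice_prob_analytic",
    "simulate_choice_em",
    "psychometric_from_initial_state",
    "pooled_psychometric",
    "PooledResult",
]

#: below this |μB/σ²| the 0/0 form is replaced by its limit (B+I)/(2B)
_MU_TOL = 1e-8


@dataclass(frozen=True)
class SimpleDDMParams:
    """Constant-drift DDM with absorbing bounds at ±B."""

    drift: float
    bound: float = 1.0
    diffusion_var: float = 1.0
    initial_state: float = 0.0

    def __post_init__(self) -> None:
        if not self.bound > 0:
            raise ValueError("bound must be > 0")
        if not self.diffusion_var > 0:
            raise ValueError("diffusion_var must be > 0")


def choice_prob_analytic(params: SimpleDDMParams) -> float:
    """Probability of absorbing at the +B bound.

    Strictly increasing in both drift and initial state. |I| ≤ B is
    required; |I| = B is immediate absorption (probability 0 or 1).
    """
    mu, B, s2, I = params.drift, params.bound, params.diffusion_var, params.initial_state
    if abs(I) > B:
        raise ValueError(f"|initial_state|={abs(I)} exceeds bound {B}")
    if abs(mu) * B / s2 < _MU_TOL:
        return (B + I) / (2.0 * B)
    # expm1 keeps the ratio stable for small exponents; for large positive
    # drift both exponents underflow benignly toward P -> 1.
    num = -np.expm1(-2.0 * mu * (B + I) / s2)
    den = -np.expm1(-4.0 * mu * B / s2)
    return float(num / den)


def simulate_choice_em(
    params: SimpleDDMParams,
    n_paths: int,
    rng: np.random.Generator,
    dt: float = 1e-3,
    t_max: float = 50.0,
) -> tuple[float, float]:
    """Euler–Maruyama estimate of P(B+) with its Monte-Carlo SE.

    Forward-simulates ``n_paths`` diffusions until absorption (cap
    ``t_max``), with a Brownian-bridge test for within-step boundary
    crossings (end-point checks alone miss O(√dt) of the crossings);
    the rare unabsorbed path is resolved by the sign of its final
    position. Used as the sampling-based cross-check of
    :func:`choice_prob_analytic`.
    """
    mu, B, sig, I = params.drift, params.bound, np.sqrt(params.diffusion_var), params.initial_state
    var_dt = params.diffusion_var * dt
    x = np.full(n_paths, float(I))
    alive = np.ones(n_paths, dtype=bool)
    upper = np.zeros(n_paths, dtype=bool)
    n_steps = int(round(t_max / dt))
    sqdt = np.sqrt(dt)
    for _ in range(n_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x0 = x[idx]
        x1 = x0 + mu * dt + sig * sqdt * rng.standard_normal(idx.size)
        x[idx] = x1
        hit_up = x1 >= B
        hit_lo = x1 <= -B
        interior = ~(hit_up | hit_lo)
        if np.any(interior):
            u = rng.random(idx.size)
            bridge_up = u < np.exp(-2.0 * (B - x0) * (B - x1) / var_dt)
            v = rng.random(idx.size)
            bridge_lo = v < np.exp(-2.0 * (B + x0) * (B + x1) / var_dt)
            hit_up |= interior & bridge_up
            hit_lo |= interior & ~bridge_up & bridge_lo
        upper[idx[hit_up]] = True
        alive[idx[hit_up | hit_lo]] = False
    upper[alive] = x[alive] > 0
    p = upper.mean()
    se = np.sqrt(max(p * (1 - p), 1.0 / n_paths) / n_paths)
    return float(p), float(se)


def psychometric_from_initial_state(
    drifts: Sequence[float],
    params: SimpleDDMParams,
    I: float,
) -> np.ndarray:
    """Choice-probability curve over a drift grid at a fixed initial state."""
    return np.array(
        [choice_prob_analytic(replace(params, drift=float(mu), initial_state=I)) for mu in drifts]
    )


@dataclass(frozen=True)
class PooledResult:
    """Closed-loop pooled psychometric and its history-conditioned splits."""

    drift_levels: np.ndarray
    pooled_curve: np.ndarray          # empirical P(R) per drift level
    pooled_fit: "PsychometricParams"  # 4-parameter logistic fit
    conditioned_fits: dict            # {'Rw': fit, 'Lw': fit}
    conditioned_curves: dict          # {'Rw': P(R) per level, 'Lw': ...}
    initial_states: np.ndarray


def pooled_psychometric(
    history_params: HistoryFilterParams,
    ddm: SimpleDDMParams,
    n_trials: int = 20_000,
    seed: int | np.random.Generator = 0,
    drift_levels: Sequence[float] | None = None,
) -> PooledResult:
    """Simulate a closed-loop session where choices feed the history filter,
    pool choices per drift level, and fit the 4-parameter logistic.

    Each trial draws a drift uniformly from ``drift_levels`` (symmetric
    about 0), computes the analytic choice probability at the current
    initial state, samples the choice, scores it against the drift sign
    (zero-drift trials rewarded at random), and updates the filters.
    """
    from .psychometrics import PsychometricParams, fit_psychometric

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if drift_levels is None:
        drift_levels = np.linspace(-4.0, 4.0, 9) * ddm.diffusion_var / ddm.bound
    levels = np.asarray(drift_levels, dtype=float)

    state = HistoryState.zero()
    mus = rng.choice(levels, size=n_trials)
    I_seq = np.empty(n_trials)
    choices_R = np.zeros(n_trials, dtype=bool)
    pairs = np.empty(n_trials, dtype=object)
    for n in range(n_trials):
        I = np.clip(state.initial_state, -ddm.bound, ddm.bound)
        I_seq[n] = I
        p = choice_prob_analytic(replace(ddm, drift=mus[n], initial_state=I))
        chose_R = rng.random() < p
        choices_R[n] = chose_R
        if mus[n] == 0:
            win = rng.random() < 0.5
        else:
            win = chose_R == (mus[n] > 0)
        pairs[n] = ("R" if chose_R else "L") + ("w" if win else "l")
        state = update_history(state, pairs[n], history_params)
    prev = np.empty(n_trials, dtype=object)
    prev[0] = "start"
    prev[1:] = pairs[:-1]

    def _curve(mask: np.ndarray) -> np.ndarray:
        out = np.full(levels.size, np.nan)
        for i, mu in enumerate(levels):
            sel = mask & (mus == mu)
            if sel.any():
                out[i] = choices_R[sel].mean()
        return out

    all_mask = np.ones(n_trials, dtype=bool)
    pooled_curve = _curve(all_mask)
    pooled_fit = fit_psychometric(mus, choices_R, seed=rng)
    cond_fits, cond_curves = {}, {}
    for pair in ("Rw", "Lw"):
        mask = prev == pair
        cond_curves[pair] = _curve(mask)
        cond_fits[pair] = fit_psychometric(mus[mask], choices_R[mask], seed=rng)
    return PooledResult(levels, pooled_curve, pooled_fit, cond_fits, cond_curves, I_seq)
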