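"""Slow reference implementations used to validate the solvers.

These deliberately take a different route from the production code:
the Fokker–Planck engine is checked against brute-force particle
(Euler–Maruyama) simulation of the accumulator SDE, and the
constant-drift case against the classical eigenfunction series for the
first-passage density of a Wiener process between two absorbing
boundaries.
"""

from __future__ import annotations

import numpy as np

from .accumulator import AccumulatorParams, adapt_click_magnitudes
from .io import TrialRecord

__all__ = ["simulate_trial_particles", "wiener_first_passage_density"]


def simulate_trial_particles(
    trial: TrialRecord,
    params: AccumulatorParams,
    I: float,
    n_particles: int,
    rng: np.random.Generator,
    dt: float = 2e-4,
    horizon: float | None = None,
) -> dict:
    """Euler–Maruyama simulation of the click accumulator for one trial.

    Returns choices (x(T) vs bias with fair-coin ties), absorption flags
    and decision times for every particle. Clicks are applied as jumps
    of ``side * C * (1 + σ_s * N(0,1))`` at the step containing each
    click; bounds are sticky. The diffusion substep includes a
    Brownian-bridge test for within-step boundary crossings, matching
    the Fokker–Planck solver's bridge-corrected transitions.
    """
    T = trial.duration if horizon is None else horizon
    n_steps = max(1, int(np.ceil(T / dt - 1e-9)))
    magsL, magsR = adapt_click_magnitudes(
        trial.left_clicks, trial.right_clicks, params.phi, params.tau_phi
    )
    click_step: dict[int, list[tuple[float, float]]] = {}
    for times, mags, sign in ((trial.left_clicks, magsL, -1.0), (trial.right_clicks, magsR, 1.0)):
        for t, C in zip(times, mags):
            k = min(int(t / dt), n_steps - 1)
            click_step.setdefault(k, []).append((sign, C))

    x = np.full(n_particles, float(I))
    alive = np.ones(n_particles, dtype=bool)
    dec_time = np.full(n_particles, np.nan)
    hit_upper = np.zeros(n_particles, dtype=bool)
    sig_a = np.sqrt(params.sigma2_a)
    sig_s = np.sqrt(params.sigma2_s)
    B = params.bound
    if abs(I) >= B:
        hit_upper[:] = I >= B
        dec_time[:] = 0.0
        alive[:] = False
    sqdt = np.sqrt(dt)
    var_dt = params.sigma2_a * dt
    for k in range(n_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x0 = x[idx]
        x1 = x0 + (params.drift + params.lam * x0) * dt + sig_a * sqdt * rng.standard_normal(idx.size)
        # diffusion substep absorption: end point or within-step bridge
        up = x1 >= B
        lo = x1 <= -B
        if var_dt > 0:
            interior = ~(up | lo)
            bup = rng.random(idx.size) < np.exp(-2.0 * (B - x0) * (B - x1) / var_dt)
            blo = rng.random(idx.size) < np.exp(-2.0 * (B + x0) * (B + x1) / var_dt)
            up |= interior & bup
            lo |= interior & ~bup & blo
        x[idx] = x1
        # clicks act only on paths that survived the diffusion substep
        surv = ~(up | lo)
        for sign, C in click_step.get(k, ()):
            js = idx[surv]
            x[js] += sign * C * (1.0 + sig_s * rng.standard_normal(js.size))
        up |= surv & (x[idx] >= B)
        lo |= surv & (x[idx] <= -B) & ~up
        done = up | lo
        hit_upper[idx[up]] = True
        x[idx[up]] = B
        x[idx[lo]] = -B
        dec_time[idx[done]] = (k + 1) * dt
        alive[idx[done]] = False
    absorbed = ~alive
    choice_R = np.where(
        absorbed,
        hit_upper,
        (x > params.bias) | ((x == params.bias) & (rng.random(n_particles) < 0.5)),
    )
    return {
        "choice_R": choice_R,
        "absorbed": absorbed,
        "decision_time": dec_time,
        "x_final": x,
    }


def wiener_first_passage_density(
    t: np.ndarray,
    mu: float,
    sigma2: float,
    bound: float,
    I: float,
    which: str = "upper",
    tail: float = 1e-14,
) -> np.ndarray:
    """First-passage density of dx = μ dt + σ dW, x(0) = I, at the
    upper (+B) or lower (−B) absorbing boundary.

    Classical eigenfunction series for absorption at 0 of a diffusion on
    (0, a): g₀(t) = (πσ²/a²) e^{−μz/σ² − μ²t/(2σ²)}
    Σ_k k sin(kπz/a) e^{−k²π²σ²t/(2a²)}; the upper boundary follows by
    the reflection z → a − z, μ → −μ. Terms are truncated once their
    exponential factor at min(t) drops below ``tail``.
    """
    t = np.asarray(t, dtype=float)
    a = 2.0 * bound
    z = I + bound
    if which == "upper":
        z, mu = a - z, -mu
    elif which != "lower":
        raise ValueError("which must be 'upper' or 'lower'")
    t_min = max(float(t.min()), 1e-12)
    decay = np.pi**2 * sigma2 / (2.0 * a**2)
    k_max = int(np.ceil(np.sqrt(-np.log(tail) / (decay * t_min)))) + 1
    k = np.arange(1, k_max + 1)
    pref = (np.pi * sigma2 / a**2) * np.exp(-mu * z / sigma2 - mu**2 * t / (2.0 * sigma2))
    series = (k[None, :] * np.sin(k[None, :] * np.pi * z / a)
              * np.exp(-k[None, :] ** 2 * decay * t[:, None])).sum(axis=1)
    return pref * series
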