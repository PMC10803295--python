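"""Four-parameter logistic psychometric fits and history-modulation
statistics.

The psychometric function is

    P(choose R | x) = κ0 + κ1 / (1 + e^{−b (x − x0)})

with left asymptote κ0 (left lapse rate), scale κ1 (right lapse rate
1 − κ0 − κ1), threshold x0 (x at the inflection point) and sensitivity
b (slope there). Lapse rates are always read from these fits, never
from raw error rates at extreme stimulus strengths.

History modulation is summarized by fitting separate curves to choices
conditioned on the previous non-violation trial being a rightward or
leftward win:

    threshold modulation  = x0^Rw − x0^Lw
    net lapse modulation  = 2(κ0^Rw − κ0^Lw) + (κ1^Rw − κ1^Lw)

(the latter is the sum of the left- and right-asymptote differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .io import SessionTable

__all__ = [
    "PsychometricParams",
    "ModulationReport",
    "fit_psychometric",
    "condition_on_history",
    "stimulus_strengths",
    "modulation_metrics",
    "bootstrap_ci",
]

_P_FLOOR = 1e-9


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of the 4-parameter logistic; asymptotes κ0, κ0+κ1."""

    kappa0: float
    kappa1: float
    x0: float
    b: float
    loglik: float = np.nan
    boundary_fit: bool = False  # degenerate data drove a parameter to its bound

    @property
    def lapse_left(self) -> float:
        return self.kappa0

    @property
    def lapse_right(self) -> float:
        return 1.0 - (self.kappa0 + self.kappa1)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        z = np.clip(-self.b * (np.asarray(x, float) - self.x0), -700, 700)
        return self.kappa0 + self.kappa1 / (1.0 + np.exp(z))


def _nll(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    k0, k1, x0, b = theta
    p = k0 + k1 / (1.0 + np.exp(np.clip(-b * (x - x0), -700, 700)))
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    return float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).sum())


def fit_psychometric(
    stimulus: Sequence[float],
    choices_right: Sequence[bool],
    weights: Sequence[float] | None = None,
    n_starts: int = 5,
    seed: int | np.random.Generator = 0,
) -> PsychometricParams:
    """Constrained Binomial maximum likelihood fit of the 4-parameter
    logistic; κ0, κ1 ∈ [0, 1] with κ0 + κ1 ≤ 1.

    The likelihood surface is multimodal at small N, so the fit is
    multi-started from a data-driven initialization plus seeded random
    perturbations; the best optimum is kept. Degenerate data (all one
    choice) produce a boundary fit flagged as such.
    """
    x = np.asarray(stimulus, dtype=float)
    y = np.asarray(choices_right, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("stimulus and choices must be equal-length and non-empty")
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct stimulus strengths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1e-6)
    # data-driven start: asymptote guesses from the outer fifths of the axis
    left = y[x <= lo + 0.2 * span]
    right = y[x >= hi - 0.2 * span]
    k0_init = float(np.clip(left.mean() if left.size else 0.05, 0.01, 0.45))
    top = float(np.clip(right.mean() if right.size else 0.95, 0.55, 0.99))
    base = np.array([k0_init, top - k0_init, float(np.median(x)), 4.0 / span])

    bounds = [(0.0, 1.0), (0.0, 1.0), (lo - span, hi + span), (1e-6, 1e3)]
    cons = [{"type": "ineq", "fun": lambda th: 1.0 - th[0] - th[1]}]
    best = None
    for s in range(n_starts):
        theta0 = base.copy()
        if s > 0:
            theta0 = theta0 * np.exp(0.3 * rng.standard_normal(4))
            theta0[2] = base[2] + 0.3 * span * rng.standard_normal()
            theta0[:2] = np.clip(theta0[:2], 0.0, 0.9)
            if theta0[0] + theta0[1] > 1:
                theta0[1] = 1 - theta0[0]
        res = minimize(_nll, theta0, args=(x, y), method="SLSQP", bounds=bounds,
                       constraints=cons, options={"maxiter": 300, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    k0, k1, x0, b = best.x
    on_bound = bool(
        k0 < 1e-9 and k1 > 1 - 1e-6 or k1 < 1e-6 or np.unique(y).size < 2
    )
    return PsychometricParams(float(k0), float(k1), float(x0), float(b),
                              loglik=-float(best.fun), boundary_fit=on_bound)


def stimulus_strengths(table: SessionTable, axis: Literal["click_difference", "log_rate_ratio"] = "click_difference") -> np.ndarray:
    """Per-trial stimulus strength: signed click-count difference
    (fixed-duration convention) or the signed log click-rate ratio
    (reaction-time convention, realized counts over the sampled
    duration)."""
    if axis == "click_difference":
        return np.array([t.click_difference for t in table], dtype=float)
    out = np.empty(len(table))
    for i, t in enumerate(table):
        nr, nl = len(t.right_clicks) + 0.5, len(t.left_clicks) + 0.5  # additive smoothing
        out[i] = np.log(nr / nl)
    return out


Conditioner = Literal["prev_Rw", "prev_Lw", "prev_win", "prev_loss"]


def condition_on_history(table: SessionTable, conditioner: Conditioner) -> SessionTable:
    """Trials whose previous non-violation trial matches the conditioner.

    Violation trials are transparent: the relevant predecessor is the
    most recent trial with a recorded choice and outcome. The returned
    subset keeps original trial indices and excludes violation trials
    themselves.
    """
    want = conditioner.removeprefix("prev_")
    kept = []
    prev_pair: str | None = None
    for t in table:
        if prev_pair is not None and not t.violation:
            match = (
                prev_pair == want
                if want in ("Rw", "Lw")
                else prev_pair.endswith("w" if want == "win" else "l")
            )
            if match:
                kept.append(t)
        if not t.violation:
            prev_pair = t.history_pair
    return SessionTable(tuple(kept), table.task_mode)


@dataclass(frozen=True)
class ModulationReport:
    """History modulation of psychometric threshold and lapse rates."""

    threshold_mod: float
    lapse_mod: float
    threshold_ci: tuple[float, float] | None = None
    lapse_ci: tuple[float, float] | None = None


def modulation_metrics(
    params_Rw: PsychometricParams, params_Lw: PsychometricParams
) -> ModulationReport:
    """Threshold and net lapse-rate modulation between post-right-win and
    post-left-win psychometric fits."""
    threshold_mod = params_Rw.x0 - params_Lw.x0
    lapse_mod = 2.0 * (params_Rw.kappa0 - params_Lw.kappa0) + (params_Rw.kappa1 - params_Lw.kappa1)
    return ModulationReport(float(threshold_mod), float(lapse_mod))


def bootstrap_ci(
    fit_fn: Callable[[np.ndarray, np.ndarray], PsychometricParams],
    stimulus: Sequence[float],
    choices_right: Sequence[bool],
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Trial-resampled percentile confidence intervals for the four
    psychometric parameters. Deterministic given the seed."""
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentile CIs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(stimulus, float)
    y = np.asarray(choices_right, float)
    draws = np.empty((n_boot, 4))
    for b in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        # guard degenerate resamples lacking 4 distinct strengths
        tries = 0
        while np.unique(x[idx]).size < 4 and tries < 10:
            idx = rng.integers(0, x.size, size=x.size)
            tries += 1
        fit = fit_fn(x[idx], y[idx])
        draws[b] = (fit.kappa0, fit.kappa1, fit.x0, fit.b)
    a = (1.0 - level) / 2.0
    qs = np.quantile(draws, [a, 1.0 - a], axis=0)
    names = ("kappa0", "kappa1", "x0", "b")
    return {n: (float(qs[0, i]), float(qs[1, i])) for i, n in enumerate(names)}
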