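"""Maximum-likelihood fitting of the accumulator model variants and
per-trial BIC model comparison.

A :class:`ModelSpec` names the variant (history-dependent initial
states on/off, true-lapse variant, task mode) and declares which
parameters are free; everything else is pinned at a fixed value. The
choice-only likelihood runs through the batched Fokker–Planck engine;
the joint choice/reaction-time likelihood loops trials through the
reference solver. Violation trials never enter the likelihood but the
history state threads through them (frozen, matching the filter rules).

Models are compared on per-trial BIC, (k ln N − 2 ln L)/N, which puts
sessions of different lengths on a common scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .accumulator import AccumulatorParams, FPGrid
from .batch import PreparedSession, choice_probs_batched
from .history import PAIRS, HistoryFilterParams
from .io import SessionTable
from .lapse import LapseParams
from .ndt import NDTParams, joint_choice_rt_likelihood

__all__ = ["ModelSpec", "FitResult", "negative_log_likelihood", "fit_mle", "bic_compare"]

_P_FLOOR = 1e-10

HISTORY_NAMES = ("eta_Rw", "eta_Lw", "eta_loss", "beta_win", "beta_loss")
ACC_NAMES = ("lam", "sigma2_a", "sigma2_s", "bound", "phi", "tau_phi", "bias")
LAPSE_NAMES = ("kappa", "rho", "matching_slope")
NDT_NAMES = ("omega_L", "omega_R", "nu_L", "nu_R", "alpha", "gamma_o")

#: neutral defaults for pinned parameters and optimizer starting points
DEFAULTS: dict[str, float] = {
    "eta_Rw": 0.2, "eta_Lw": -0.2, "eta_loss": 0.1, "beta_win": 0.5, "beta_loss": 0.3,
    "lam": 0.0, "sigma2_a": 1.0, "sigma2_s": 0.1, "bound": 3.0, "phi": 0.5,
    "tau_phi": 0.1, "bias": 0.0,
    "kappa": 0.1, "rho": 0.5, "matching_slope": 1.0,
    "omega_L": 1.5, "omega_R": 1.5, "nu_L": 10.0, "nu_R": 10.0, "alpha": 0.0,
    "gamma_o": 0.0,
}

#: identifiability-motivated box bounds; all overridable per spec
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "eta_Rw": (-3.0, 3.0), "eta_Lw": (-3.0, 3.0), "eta_loss": (-3.0, 3.0),
    "beta_win": (0.0, 0.999), "beta_loss": (0.0, 0.999),
    "lam": (-5.0, 5.0), "sigma2_a": (0.0, 25.0), "sigma2_s": (0.0, 4.0),
    "bound": (0.5, 10.0), "phi": (0.01, 1.5), "tau_phi": (0.02, 1.0),
    "bias": (-3.0, 3.0),
    "kappa": (0.0, 0.5), "rho": (0.0, 1.0), "matching_slope": (0.0, 50.0),
    "omega_L": (0.1, 10.0), "omega_R": (0.1, 10.0), "nu_L": (0.5, 50.0),
    "nu_R": (0.5, 50.0), "alpha": (-0.01, 0.01), "gamma_o": (-10.0, 10.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """A fittable model variant.

    ``free`` lists the parameter names the optimizer may move; every
    other parameter is held at ``fixed`` (falling back to module
    defaults). When ``with_hist`` is false all history increments are
    pinned at zero and history names may not be freed.
    """

    with_hist: bool = True
    lapse_variant: Literal["motor", "inattention", "hybrid"] = "motor"
    task_mode: Literal["fixed_duration", "reaction_time"] = "fixed_duration"
    free: tuple[str, ...] = ("eta_Rw", "eta_Lw", "beta_win", "bound", "kappa")
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_bins: int = 61
    dt: float = 0.01

    def __post_init__(self) -> None:
        all_names = set(HISTORY_NAMES) | set(ACC_NAMES) | set(LAPSE_NAMES) | set(NDT_NAMES)
        unknown = [p for p in tuple(self.free) + tuple(self.fixed) if p not in all_names]
        if unknown:
            raise ValueError(f"unknown parameters {unknown}")
        if not self.with_hist and any(p in HISTORY_NAMES for p in self.free):
            raise ValueError("history parameters cannot be free when with_hist=False")
        if self.lapse_variant != "hybrid" and "matching_slope" in self.free:
            raise ValueError("matching_slope is only free in the hybrid variant")

    @property
    def k(self) -> int:
        return len(self.free)

    def full_params(self, theta: Sequence[float] | Mapping[str, float]) -> dict[str, float]:
        vals = dict(DEFAULTS)
        vals.update(self.fixed)
        if isinstance(theta, Mapping):
            vals.update(theta)
        else:
            theta = np.asarray(theta, dtype=float)
            if theta.size != len(self.free):
                raise ValueError(f"expected {len(self.free)} free parameters, got {theta.size}")
            vals.update(dict(zip(self.free, theta)))
        if not self.with_hist:
            vals.update({"eta_Rw": 0.0, "eta_Lw": 0.0, "eta_loss": 0.0})
        return vals

    def build(self, theta) -> tuple[HistoryFilterParams, AccumulatorParams, LapseParams, NDTParams]:
        v = self.full_params(theta)
        hist = HistoryFilterParams.paper_constrained(
            v["eta_Rw"], v["eta_Lw"], v["eta_loss"], v["beta_win"], v["beta_loss"]
        )
        acc = AccumulatorParams(
            lam=v["lam"], sigma2_a=v["sigma2_a"], sigma2_s=v["sigma2_s"], bound=v["bound"],
            phi=v["phi"], tau_phi=v["tau_phi"], bias=v["bias"],
        )
        lapse = LapseParams(
            kappa=v["kappa"], rho=v["rho"],
            matching_slope=v["matching_slope"] if self.lapse_variant == "hybrid" else None,
            variant=self.lapse_variant,
        )
        ndt = NDTParams(
            omega_L=v["omega_L"], omega_R=v["omega_R"], nu_L=v["nu_L"], nu_R=v["nu_R"],
            alpha=v["alpha"], gamma_o=v["gamma_o"],
        )
        return hist, acc, lapse, ndt

    def get_bounds(self) -> list[tuple[float, float]]:
        return [self.bounds.get(p, DEFAULT_BOUNDS[p]) for p in self.free]


def _pair_codes(table: SessionTable) -> np.ndarray:
    codes = {"Rw": 0, "Lw": 1, "Rl": 2, "Ll": 3, "none": -1}
    return np.array([codes[t.history_pair] for t in table], dtype=np.int64)


def _initial_states(pair_codes: np.ndarray, hist: HistoryFilterParams) -> np.ndarray:
    """Plain-scalar filter recursion (fast path, equivalent to
    :func:`histddm.history.initial_state_sequence`)."""
    eta = np.array([hist.eta[p] for p in PAIRS])
    beta = np.array([hist.beta[p] for p in PAIRS])
    f0 = f1 = f2 = f3 = 0.0
    out = np.empty(pair_codes.size)
    for n, c in enumerate(pair_codes):
        out[n] = f0 + f1 + f2 + f3
        if c < 0:
            continue  # violation: frozen
        f0 *= beta[0]; f1 *= beta[1]; f2 *= beta[2]; f3 *= beta[3]
        if c == 0: f0 += eta[0]
        elif c == 1: f1 += eta[1]
        elif c == 2: f2 += eta[2]
        else: f3 += eta[3]
    return out


def _lapse_probs(lapse: LapseParams, I: np.ndarray) -> np.ndarray:
    if lapse.variant == "motor":
        return np.full(I.shape, lapse.rho)
    d = I - lapse.rho
    if lapse.variant == "inattention":
        return np.where(d > 0, 1.0, np.where(d == 0, 0.5, 0.0))
    return 1.0 / (1.0 + np.exp(-np.clip(lapse.matching_slope * d, -700, 700)))


class LikelihoodContext:
    """Caches the prepared session so repeated objective evaluations
    only redo parameter-dependent work."""

    def __init__(self, table: SessionTable, spec: ModelSpec):
        self.table = table
        self.spec = spec
        self.pair_codes = _pair_codes(table)
        self.nonviol = self.pair_codes >= 0
        self.n = int(self.nonviol.sum())
        if spec.task_mode == "fixed_duration":
            self.prep = PreparedSession.from_table(table, spec.dt)
            self.choice_R = self.prep.choice_R

    def nll(self, theta) -> float:
        spec = self.spec
        try:
            hist, acc, lapse, ndt = spec.build(theta)
        except ValueError:
            return np.inf
        I = _initial_states(self.pair_codes, hist)
        if spec.task_mode == "fixed_duration":
            p_acc = choice_probs_batched(self.prep, acc, I, n_bins=spec.n_bins)
            p_R = (1.0 - lapse.kappa) * p_acc + lapse.kappa * _lapse_probs(lapse, I)
            p_obs = np.where(self.choice_R, p_R, 1.0 - p_R)[self.nonviol]
            p_obs = np.clip(p_obs, _P_FLOOR, 1.0)
            return float(-np.log(p_obs).sum())
        total = 0.0
        grid = FPGrid(bound=acc.bound, n_bins=spec.n_bins, dt=spec.dt)
        prev_error = False
        for i, t in enumerate(self.table):
            if t.violation:
                continue
            try:
                lik = joint_choice_rt_likelihood(
                    t, float(I[i]), acc, ndt, lapse, grid, prev_error=prev_error
                )
            except ValueError:
                return np.inf
            total -= np.log(max(lik, _P_FLOOR))
            prev_error = t.outcome == "loss"
        return float(total)


def negative_log_likelihood(
    table: SessionTable, spec: ModelSpec, params: Sequence[float] | Mapping[str, float]
) -> float:
    """Summed −ln likelihood of the observed choices (and, in
    reaction-time mode, RTs) over non-violation trials."""
    ctx = LikelihoodContext(table, spec)
    if isinstance(params, Mapping):
        full = spec.full_params({})
        params = [params.get(p, full[p]) for p in spec.free]
    val = ctx.nll(np.asarray(params, dtype=float))
    if not np.isfinite(val):
        # locate the offending trial for the diagnostic
        raise FloatingPointError("non-finite likelihood; check parameter domain")
    return val


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: ModelSpec
    best_params: dict[str, float]
    loglik: float
    n_trials: int
    k: int
    per_trial_bic: float
    converged: bool
    n_starts: int
    seed: int
    nll_evals: int = 0

    def to_json(self) -> str:
        v = self.best_params
        blocks = {
            "history": {p: v[p] for p in HISTORY_NAMES},
            "accumulator": {p: v[p] for p in ACC_NAMES},
            "lapse": {p: v[p] for p in LAPSE_NAMES},
            "ndt": {p: v[p] for p in NDT_NAMES},
            "free": list(self.spec.free),
            "loglik": self.loglik,
            "n_trials": self.n_trials,
            "k": self.k,
            "per_trial_bic": self.per_trial_bic,
            "meta": {
                "seed": self.seed,
                "n_starts": self.n_starts,
                "converged": self.converged,
                "with_hist": self.spec.with_hist,
                "lapse_variant": self.spec.lapse_variant,
                "task_mode": self.spec.task_mode,
                "grid": {"n_bins": self.spec.n_bins, "dt": self.spec.dt},
            },
        }
        return json.dumps(blocks, indent=2)


def per_trial_bic(loglik: float, k: int, n: int) -> float:
    return (k * np.log(n) - 2.0 * loglik) / n


def fit_mle(
    table: SessionTable,
    spec: ModelSpec,
    init: Mapping[str, float] | None = None,
    seed: int = 0,
    n_starts: int = 5,
    maxfev: int = 400,
) -> FitResult:
    """Constrained multi-start maximum likelihood.

    Start 0 uses ``init`` (or neutral defaults); the remaining starts
    perturb it within bounds, seeded. Nelder–Mead with box bounds;
    the best optimum is kept, and non-convergence is flagged on the
    result rather than raised. Deterministic given the seed.
    """
    ctx = LikelihoodContext(table, spec)
    rng = np.random.default_rng(seed)
    bounds = spec.get_bounds()
    base = np.array(
        [(init or {}).get(p, np.clip(DEFAULTS[p], *b)) for p, b in zip(spec.free, bounds)]
    )
    evals = 0

    def obj(theta):
        nonlocal evals
        evals += 1
        return ctx.nll(theta)

    if not spec.free:  # nothing to optimize: evaluate the pinned model
        loglik = -ctx.nll(np.empty(0))
        return FitResult(
            spec=spec, best_params=spec.full_params({}), loglik=float(loglik),
            n_trials=ctx.n, k=0,
            per_trial_bic=float(per_trial_bic(loglik, 0, ctx.n)),
            converged=True, n_starts=0, seed=seed, nll_evals=1,
        )

    best = None
    for s in range(n_starts):
        theta0 = base.copy()
        if s > 0:
            for j, (lo, hi) in enumerate(bounds):
                width = hi - lo
                theta0[j] = np.clip(theta0[j] + 0.15 * width * rng.standard_normal(), lo, hi)
        res = minimize(
            obj, theta0, method="Nelder-Mead", bounds=bounds,
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-4},
        )
        if best is None or res.fun < best.fun:
            best = res
    loglik = -float(best.fun)
    params = spec.full_params(best.x)
    return FitResult(
        spec=spec,
        best_params=params,
        loglik=loglik,
        n_trials=ctx.n,
        k=spec.k,
        per_trial_bic=float(per_trial_bic(loglik, spec.k, ctx.n)),
        converged=bool(best.success),
        n_starts=n_starts,
        seed=seed,
        nll_evals=evals,
    )


@dataclass(frozen=True)
class BICComparison:
    per_trial_bic_a: float
    per_trial_bic_b: float
    delta: float          # a − b; negative prefers a
    preferred: str        # 'a' or 'b'


def bic_compare(fit_a: FitResult, fit_b: FitResult) -> BICComparison:
    """Per-trial BIC comparison of two fits to the same table."""
    if fit_a.n_trials != fit_b.n_trials:
        raise ValueError("fits compare different trial counts")
    delta = fit_a.per_trial_bic - fit_b.per_trial_bic
    return BICComparison(
        fit_a.per_trial_bic, fit_b.per_trial_bic, float(delta), "a" if delta <= 0 else "b"
    )
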