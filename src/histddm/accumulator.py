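"""Pulsatile-evidence accumulator: adaptation, Fokker–Planck evolution,
choice likelihood, and first-passage densities.

Within a trial the accumulated evidence x(t) obeys

    dx = 0                                         if |x| >= B (sticky bound)
    dx = λ x dt + (ε_R C_R ξ_R − ε_L C_L ξ_L) dt + σ_a dW   otherwise

where ε are the click trains, C the per-click magnitudes after sensory
adaptation (strength ϕ, recovery time constant τ_ϕ), ξ ~ N(1, σ_s²) the
per-click sensory noise, and x(0) = I(n), the history-dependent initial
state. A rightward choice is made when x(T) > bias.

The choice likelihood requires the full distribution P(x(t)), evolved
here on a discrete spatial grid: each transition step moves every bin's
mass through a Gaussian whose mean follows the deterministic drift (plus
any click input in the step) and whose variance collects the diffusion
and per-click sensory variance; destination mass is assigned by
differences of the Gaussian CDF at bin edges, with mass beyond ±B
captured in two sticky absorbing bins. Absorbed mass per time step is
the first-passage (bound-hitting-time) density needed by the joint
choice/reaction-time likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .io import TrialRecord

__all__ = [
    "AccumulatorParams",
    "FPGrid",
    "FirstPassageDensity",
    "FPResult",
    "adapt_click_magnitudes",
    "fokker_planck_evolve",
    "choice_likelihood",
    "first_passage_density",
]

#: floor on the per-transition Gaussian SD; at (and numerically below)
#: this scale the smoothed-interpolation weights reduce exactly to
#: mean-preserving two-node interpolation
_DETERMINISTIC_SD = 1e-12


@dataclass(frozen=True)
class AccumulatorParams:
    """Within-trial accumulator parameters.

    lam
        Leak (<0) / instability (>0) rate of the memory drift λx, per s.
    sigma2_a
        Diffusion variance of the accumulator, per s.
    sigma2_s
        Variance of the multiplicative per-click sensory noise ξ
        (mean 1); a click of adapted magnitude C contributes an input of
        mean ±C and variance C² σ_s².
    bound
        Absorbing decision bound B > 0; x freezes once |x| ≥ B.
    phi, tau_phi
        Sensory adaptation strength (ϕ<1 depression, ϕ>1 facilitation)
        and recovery time constant (s).
    bias
        Decision criterion on x(T); rightward choice iff x(T) > bias.
    drift
        Constant drift term (per s). Zero in the click model proper —
        clicks are the only systematic input — but nonzero values turn
        the engine into a plain constant-drift DDM, the reduced regime
        used to validate it against closed-form results.
    """

    lam: float = 0.0
    sigma2_a: float = 1.0
    sigma2_s: float = 0.0
    bound: float = 4.0
    phi: float = 1.0
    tau_phi: float = 0.1
    bias: float = 0.0
    drift: float = 0.0

    def __post_init__(self) -> None:
        if not self.bound > 0:
            raise ValueError("bound must be > 0")
        if not self.tau_phi > 0:
            raise ValueError("tau_phi must be > 0")
        if self.sigma2_a < 0 or self.sigma2_s < 0:
            raise ValueError("variances must be >= 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")


@dataclass(frozen=True)
class FPGrid:
    """Spatial/temporal discretization for the Fokker–Planck solver.

    ``n_bins`` interior bins (odd, so one bin is centered on 0) span
    [−B, B]; two extra sticky bins hold the absorbed mass at each bound.
    State vectors have length ``n_bins + 2`` with index 0 = absorbed at
    −B and index −1 = absorbed at +B.
    """

    bound: float
    n_bins: int = 201
    dt: float = 0.002

    def __post_init__(self) -> None:
        if self.n_bins < 51 or self.n_bins % 2 == 0:
            raise ValueError("n_bins must be odd and >= 51")
        if not (self.dt > 0 and self.bound > 0):
            raise ValueError("dt and bound must be > 0")

    @property
    def dx(self) -> float:
        return 2.0 * self.bound / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(-self.bound, self.bound, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + 0.5 * self.dx

    def n_steps(self, duration: float) -> int:
        return max(1, int(np.ceil(duration / self.dt - 1e-9)))


@dataclass(frozen=True)
class FirstPassageDensity:
    """Absorbed probability mass per time bin at each bound."""

    t: np.ndarray            # time-bin centers
    mass_upper: np.ndarray   # P(decide R in bin), sums with lower+survivor to 1
    mass_lower: np.ndarray
    survivor: float          # interior mass remaining at the horizon

    @property
    def total(self) -> float:
        return float(self.mass_upper.sum() + self.mass_lower.sum() + self.survivor)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else float(2 * self.t[0])


@dataclass(frozen=True)
class FPResult:
    """Final state of a Fokker–Planck evolution."""

    grid: FPGrid
    P_final: np.ndarray                 # length n_bins + 2
    passage: FirstPassageDensity
    trajectory: np.ndarray | None = None  # (n_steps + 1, n_bins + 2) if stored
    conservation_error: float = 0.0


def adapt_click_magnitudes(
    left_clicks: Sequence[float],
    right_clicks: Sequence[float],
    phi: float,
    tau_phi: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-click magnitudes after sensory adaptation.

    The adaptation state C relaxes toward 1 between clicks,
    C(t) = 1 + (C⁺ − 1) e^{−Δt/τ_ϕ}, starting fully recovered
    (C(0) = 1). Each click reports the state just before its own jump
    and then multiplies the state by ϕ. Simultaneous left/right clicks
    are processed in time order with left before right at exact ties.
    """
    left = np.asarray(left_clicks, dtype=float)
    right = np.asarray(right_clicks, dtype=float)
    if (left.size and left.min() < 0) or (right.size and right.min() < 0):
        raise ValueError("click times must be >= 0")
    times = np.concatenate([left, right])
    sides = np.concatenate([np.zeros(left.size, int), np.ones(right.size, int)])
    order = np.lexsort((sides, times))
    mags = np.empty(times.size)
    C = 1.0
    t_prev = 0.0
    for j in order:
        C = 1.0 + (C - 1.0) * np.exp(-(times[j] - t_prev) / tau_phi)
        mags[j] = C
        C *= phi
        t_prev = times[j]
    return mags[: left.size], mags[left.size :]


def _deposit(mean: float, grid: FPGrid, out: np.ndarray, mass: float = 1.0) -> None:
    """Mean-preserving two-node deposit of a point mass, with the
    absorbing bounds acting as virtual nodes at ±B."""
    B, dx = grid.bound, grid.dx
    if mean >= B:
        out[-1] += mass
        return
    if mean <= -B:
        out[0] += mass
        return
    nodes = np.concatenate([[-B], grid.centers, [B]])
    j = int(np.searchsorted(nodes, mean)) - 1
    j = min(max(j, 0), nodes.size - 2)
    w_hi = (mean - nodes[j]) / (nodes[j + 1] - nodes[j])
    # node index -> state index: virtual -B node is absorbing bin 0,
    # virtual +B node is absorbing bin -1, interior node k is bin k+1
    for node, w in ((j, 1.0 - w_hi), (j + 1, w_hi)):
        if node == 0:
            out[0] += mass * w
        elif node == nodes.size - 1:
            out[-1] += mass * w
        else:
            out[node] += mass * w  # interior node `node` maps to state index node


def _transition_matrix(grid: FPGrid, means: np.ndarray, sd: float) -> np.ndarray:
    """Full (n+2)×(n+2) transition matrix taking each interior bin's mass
    through N(mean_i, sd²); absorbing bins are sticky.

    Mass is distributed by Gaussian-smoothed linear interpolation over
    the grid nodes: node j receives ∫ N(x; mean, s²) hat_j(x) dx, the
    second difference of E(a) = (a−m)Φ(z) + s φ(z). This conserves mass
    exactly, preserves the mean, and reduces to plain two-node
    interpolation as s → 0, so purely deterministic dynamics are not
    numerically frozen. Hat distribution is a convolution with a
    triangular kernel of variance dx²/6, so that amount is subtracted
    from the requested variance; the compensation is exact whenever
    sd² ≥ dx²/6 and keeps repeated applications from inflating the
    diffusion.
    """
    n = grid.n_bins
    A = np.zeros((n + 2, n + 2))
    A[0, 0] = 1.0
    A[-1, -1] = 1.0
    s = np.sqrt(max(sd**2 - grid.dx**2 / 6.0, _DETERMINISTIC_SD**2))
    # uniform node set: interior centers plus one virtual absorbing node
    # a full spacing beyond each end (same convention as the batched
    # displacement kernels, so the two engines agree to round-off)
    dx = grid.dx
    nodes = np.concatenate([[grid.centers[0] - dx], grid.centers, [grid.centers[-1] + dx]])
    z = (nodes[None, :] - means[:, None]) / s           # (n, n+2)
    E = (nodes[None, :] - means[:, None]) * ndtr(z) + s * _phi(z)
    slopes = np.diff(E, axis=1) / dx                    # (n, n+1)
    W = np.empty((n, n + 2))
    W[:, 0] = slopes[:, 0]
    W[:, 1:-1] = np.diff(slopes, axis=1)
    W[:, -1] = 1.0 - slopes[:, -1]
    A[:, 1:-1] = W.T
    return A


def _phi(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.square(np.clip(z, -38.0, 38.0))) / np.sqrt(2.0 * np.pi)


def base_transition_matrix(grid: FPGrid, params: AccumulatorParams) -> np.ndarray:
    """One-step transition for drift λx and diffusion σ_a² (no clicks).

    The linear drift is integrated exactly over the step
    (mean x e^{λΔt}, variance σ_a² (e^{2λΔt} − 1)/(2λ)). A Brownian-
    bridge correction then reassigns to the bounds the mass of paths
    that cross within the step but end in the interior — without it,
    end-point absorption under-counts first passages by O(√Δt).
    """
    lam, dt = params.lam, grid.dt
    growth = np.exp(lam * dt)
    var_dt = params.sigma2_a * (np.expm1(2 * lam * dt) / (2 * lam) if abs(lam) > 1e-12 else dt)
    drift_dt = params.drift * (np.expm1(lam * dt) / lam if abs(lam) > 1e-12 else dt)
    means = grid.centers * growth + drift_dt
    A = _transition_matrix(grid, means, float(np.sqrt(max(var_dt, 0.0))))
    if var_dt > 0:
        B = grid.bound
        x0 = grid.centers[None, :]          # source (columns)
        x1 = grid.centers[:, None]          # destination (rows)
        cross_up = np.exp(-2.0 * (B - x0) * (B - x1) / var_dt)
        cross_lo = np.exp(-2.0 * (B + x0) * (B + x1) / var_dt)
        W = A[1:-1, 1:-1]
        up_extra = (W * cross_up).sum(axis=0)
        lo_extra = (W * cross_lo * (1.0 - cross_up)).sum(axis=0)
        A[1:-1, 1:-1] = W * (1.0 - cross_up) * (1.0 - cross_lo)
        A[-1, 1:-1] += up_extra
        A[0, 1:-1] += lo_extra
    return A


def click_transition_matrix(grid: FPGrid, shift: float, sd: float) -> np.ndarray:
    """Transition applying one click's Gaussian input N(±C, C²σ_s²)."""
    return _transition_matrix(grid, grid.centers + shift, sd)


def _clicks_by_step(trial: TrialRecord, params: AccumulatorParams, grid: FPGrid, n_steps: int):
    magsL, magsR = adapt_click_magnitudes(
        trial.left_clicks, trial.right_clicks, params.phi, params.tau_phi
    )
    events: dict[int, list[tuple[float, float, bool]]] = {}
    sig_s = np.sqrt(params.sigma2_s)
    merged = [(t, -1.0, C) for t, C in zip(trial.left_clicks, magsL)]
    merged += [(t, 1.0, C) for t, C in zip(trial.right_clicks, magsR)]
    # clicks within one transition step are applied in time order (left
    # before right at exact ties, matching the adaptation pass); a click
    # in the first half of its step is applied before the step's
    # drift/diffusion substep, centering the time-quantization error
    merged.sort(key=lambda e: (e[0], e[1]))
    for t, sign, C in merged:
        k = min(int(t / grid.dt), n_steps - 1)
        before = (t - k * grid.dt) < 0.5 * grid.dt
        events.setdefault(k, []).append((sign * C, C * sig_s, before))
    return events


def fokker_planck_evolve(
    trial: TrialRecord,
    params: AccumulatorParams,
    I: float,
    grid: FPGrid | None = None,
    horizon: float | None = None,
    store_trajectory: bool = False,
) -> FPResult:
    """Evolve P(x(t)) for one trial from a point mass at the initial
    state I, recording the absorbed mass per step at each bound.

    ``horizon`` defaults to the stimulus duration; a longer horizon keeps
    evolving the distribution without further clicks (used for
    reaction-time likelihoods). |I| ≥ B puts all mass in the matching
    absorbing bin at t = 0.
    """
    if grid is None:
        grid = FPGrid(bound=params.bound)
    elif grid.bound != params.bound:
        raise ValueError("grid bound must match params.bound")
    T = trial.duration if horizon is None else horizon
    n_steps = grid.n_steps(T)
    P = np.zeros(grid.n_bins + 2)
    _deposit(I, grid, P)
    mass_upper = np.zeros(n_steps)
    mass_lower = np.zeros(n_steps)
    traj = [P.copy()] if store_trajectory else None

    A = base_transition_matrix(grid, params)
    events = _clicks_by_step(trial, params, grid, n_steps)
    cons_err = 0.0
    # mass absorbed by the initial deposit (|I| >= B) counts as a
    # decision at time zero, i.e. in the first time bin
    lo0, up0 = 0.0, 0.0
    for k in range(n_steps):
        step_events = events.get(k, ())
        for shift, sd, before in step_events:
            if before:
                P = click_transition_matrix(grid, shift, sd) @ P
        P = A @ P
        for shift, sd, before in step_events:
            if not before:
                P = click_transition_matrix(grid, shift, sd) @ P
        mass_lower[k] = P[0] - lo0
        mass_upper[k] = P[-1] - up0
        lo0, up0 = P[0], P[-1]
        cons_err = max(cons_err, abs(P.sum() - 1.0))
        if store_trajectory:
            traj.append(P.copy())
    t = (np.arange(n_steps) + 0.5) * grid.dt
    passage = FirstPassageDensity(t, mass_upper, mass_lower, survivor=float(P[1:-1].sum()))
    return FPResult(
        grid,
        P,
        passage,
        trajectory=np.asarray(traj) if store_trajectory else None,
        conservation_error=cons_err,
    )


def prob_right_from_state(P: np.ndarray, grid: FPGrid, bias: float) -> float:
    """P(choose R): mass strictly above the bias criterion, counting the
    ±B absorbed bins as point masses at ±B, splitting the interior bin
    containing the bias linearly, and scoring mass exactly at the bias
    as a fair coin."""
    edges = grid.edges
    interior = P[1:-1]
    frac_above = np.clip((edges[1:] - bias) / grid.dx, 0.0, 1.0)
    p = float(interior @ frac_above)
    for mass, x in ((P[0], -grid.bound), (P[-1], grid.bound)):
        if x > bias:
            p += mass
        elif x == bias:
            p += 0.5 * mass
    return p


def choice_likelihood(
    trial: TrialRecord,
    params: AccumulatorParams,
    I: float,
    grid: FPGrid | None = None,
) -> float:
    """P(choose R) at the end of a fixed-duration trial."""
    res = fokker_planck_evolve(trial, params, I, grid)
    return prob_right_from_state(res.P_final, res.grid, params.bias)


def first_passage_density(
    trial: TrialRecord,
    params: AccumulatorParams,
    I: float,
    grid: FPGrid | None = None,
    horizon: float | None = None,
) -> FirstPassageDensity:
    """Bound-hitting-time density for a reaction-time trial.

    The stimulus is assumed to continue while the accumulator is
    unabsorbed; clicks beyond the horizon never enter (sticky bounds
    already guarantee that clicks after a given hitting time cannot
    influence the mass absorbed at that time).
    """
    res = fokker_planck_evolve(trial, params, I, grid, horizon=horizon)
    return res.passage
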