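"""Vectorized Fokker–Planck choice likelihoods over whole sessions.

Maximum-likelihood fitting needs P(choose R) for thousands of trials at
every objective evaluation. This module evolves the distributions of
all trials simultaneously: the no-click drift/diffusion step is one
matrix product over a (trials × bins) state array, and click inputs —
which are additive and independent of x — are applied as displacement
kernels (Gaussian CDF differences over relative bin offsets) to just
the trials with a click in that step, with boundary overflow routed to
the sticky absorbing bins.

The per-trial solver in :mod:`histddm.accumulator` is the reference
path; this one must agree with it (see the consistency tests) and only
exists for speed. One deliberate approximation: within a transition
step, drift/diffusion is applied before the step's click input for all
trials (the per-trial solver orders them identically), and the per-click
sensory noise uses ndtr directly with no deterministic special case, so
σ_s = 0 fits should use the reference path.
"""

from __future__ import annotations

from dataclasses import dataclass

from math import erf as math_erf

import numpy as np
from numba import njit

from .accumulator import AccumulatorParams, FPGrid, base_transition_matrix
from .io import SessionTable

__all__ = ["PreparedSession", "choice_probs_batched", "adapted_magnitudes_padded"]


def adapted_magnitudes_padded(
    click_t: np.ndarray, click_mask: np.ndarray, phi: float, tau_phi: float
) -> np.ndarray:
    """Adapted magnitudes for padded (n_trials, K) merged click arrays,
    vectorized across trials by iterating over the short click index."""
    n, K = click_t.shape
    mags = np.zeros((n, K))
    C = np.ones(n)
    t_prev = np.zeros(n)
    for k in range(K):
        live = click_mask[:, k]
        dtk = click_t[:, k] - t_prev
        C_here = 1.0 + (C - 1.0) * np.exp(-np.maximum(dtk, 0.0) / tau_phi)
        mags[:, k] = np.where(live, C_here, 0.0)
        C = np.where(live, C_here * phi, C)
        t_prev = np.where(live, click_t[:, k], t_prev)
    return mags

_TAIL_SIGMAS = 8.0  # kernel support half-width in click-noise SDs


@dataclass
class PreparedSession:
    """Session unpacked into flat arrays for repeated likelihood evaluation.

    Built once per (table, dt); adapted click magnitudes are cached per
    (phi, tau_phi) so they are only recomputed when adaptation
    parameters actually move during a fit.
    """

    dt: float
    n_trials: int
    n_steps: np.ndarray        # per-trial step counts
    choice_R: np.ndarray       # bool, False for 'L' (undefined on violations)
    violation: np.ndarray      # bool
    # padded (n_trials, K) click arrays
    click_t: np.ndarray
    click_side: np.ndarray     # +1 right, −1 left, 0 padding
    click_mask: np.ndarray
    # flat event arrays sorted by (substep, round, trial); a substep is
    # 2*step + phase, phase 0 applying before the drift/diffusion substep
    # (clicks in the first half of the step) and phase 1 after
    ev_sub: np.ndarray
    ev_trial: np.ndarray
    ev_col: np.ndarray         # column into the padded click arrays
    ev_round: np.ndarray       # occurrence index of this trial within its substep

    def __post_init__(self) -> None:
        self._adapt_cache: dict[tuple[float, float], np.ndarray] = {}

    @classmethod
    def from_table(cls, table: SessionTable, dt: float) -> "PreparedSession":
        n_trials = len(table)
        K = max((len(t.left_clicks) + len(t.right_clicks) for t in table), default=0)
        K = max(K, 1)
        click_t = np.zeros((n_trials, K))
        click_side = np.zeros((n_trials, K), dtype=np.int8)
        click_mask = np.zeros((n_trials, K), dtype=bool)
        n_steps = np.empty(n_trials, dtype=np.int64)
        choice_R = np.zeros(n_trials, dtype=bool)
        violation = np.zeros(n_trials, dtype=bool)
        for i, t in enumerate(table):
            n_steps[i] = max(1, int(np.ceil(t.duration / dt - 1e-9)))
            choice_R[i] = t.choice == "R"
            violation[i] = t.violation
            times = np.concatenate([t.left_clicks, t.right_clicks])
            sides = np.concatenate(
                [-np.ones(len(t.left_clicks), dtype=np.int8), np.ones(len(t.right_clicks), dtype=np.int8)]
            )
            order = np.lexsort((sides, times))  # left before right at ties
            m = times.size
            click_t[i, :m] = times[order]
            click_side[i, :m] = sides[order]
            click_mask[i, :m] = True

        tr, col = np.nonzero(click_mask)
        t_ev = click_t[tr, col]
        step = np.minimum((t_ev / dt).astype(np.int64), n_steps[tr] - 1)
        before = (t_ev - step * dt) < 0.5 * dt
        sub = 2 * step + (~before).astype(np.int64)
        order = np.lexsort((col, tr, sub))
        tr, col, sub = tr[order], col[order], sub[order]
        # occurrence of each trial within a substep: events for the same
        # trial in the same substep must be applied sequentially
        rnd = np.zeros(tr.size, dtype=np.int64)
        for i in range(1, tr.size):  # short: one pass over clicks
            if tr[i] == tr[i - 1] and sub[i] == sub[i - 1]:
                rnd[i] = rnd[i - 1] + 1
        order2 = np.lexsort((tr, rnd, sub))
        return cls(
            dt=dt,
            n_trials=n_trials,
            n_steps=n_steps,
            choice_R=choice_R,
            violation=violation,
            click_t=click_t,
            click_side=click_side,
            click_mask=click_mask,
            ev_sub=sub[order2],
            ev_trial=tr[order2],
            ev_col=col[order2],
            ev_round=rnd[order2],
        )

    def adapted_magnitudes(self, phi: float, tau_phi: float) -> np.ndarray:
        """Padded (n_trials, K) adapted magnitudes, vectorized across
        trials by iterating over the (short) click index."""
        key = (float(phi), float(tau_phi))
        cached = self._adapt_cache.get(key)
        if cached is not None:
            return cached
        mags = adapted_magnitudes_padded(self.click_t, self.click_mask, phi, tau_phi)
        self._adapt_cache[key] = mags
        if len(self._adapt_cache) > 32:
            self._adapt_cache.pop(next(iter(self._adapt_cache)))
        return mags


def _deposit_batched(I: np.ndarray, grid: FPGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-preserving deposit of per-trial point masses at I, with the
    bounds as virtual nodes. Returns (interior (n_trials, n), lower, upper)."""
    n = grid.n_bins
    B, dx = grid.bound, grid.dx
    nodes = np.concatenate([[-B], grid.centers, [B]])
    interior = np.zeros((I.size, n))
    lo = np.zeros(I.size)
    up = np.zeros(I.size)
    Ic = np.clip(I, -B, B)
    j = np.clip(np.searchsorted(nodes, Ic) - 1, 0, nodes.size - 2)
    w_hi = (Ic - nodes[j]) / (nodes[j + 1] - nodes[j])
    rows = np.arange(I.size)
    for node_idx, w in ((j, 1.0 - w_hi), (j + 1, w_hi)):
        at_lo = node_idx == 0
        at_up = node_idx == nodes.size - 1
        mid = ~(at_lo | at_up)
        np.add.at(lo, rows[at_lo], w[at_lo])
        np.add.at(up, rows[at_up], w[at_up])
        np.add.at(interior, (rows[mid], node_idx[mid] - 1), w[mid])
    lo[I <= -B] = 1.0
    up[I >= B] = 1.0
    return interior, lo, up


@njit(cache=True)
def _apply_events_nb(P, lo, up, rows, means, sds, dx, tail):
    """Apply each event's N(mean, sd²) displacement kernel to its trial's
    interior mass, in place and in order (so several clicks of one trial
    in the same substep compose sequentially).

    Weights are the Gaussian-smoothed linear-interpolation (hat) weights
    over relative offsets k·dx — the second difference of
    E(a) = (a−m)Φ(z) + sφ(z) — matching the per-trial transition
    matrices exactly: mass-conserving, mean-preserving, stable as s → 0,
    with the hat kernel's own variance dx²/6 subtracted from the
    requested variance. Residual tails fold into the end offsets;
    destinations beyond the grid accumulate in the absorbing totals.
    """
    n = P.shape[1]
    sq2 = np.sqrt(2.0)
    sq2pi = np.sqrt(2.0 * np.pi)
    var_comp = dx * dx / 6.0
    scratch = np.empty(n)
    for e in range(rows.size):
        r = rows[e]
        m = means[e]
        s2 = sds[e] * sds[e] - var_comp
        s = np.sqrt(s2) if s2 > 1e-24 else 1e-12
        k_lo = int(np.floor((m - tail * s) / dx)) - 1
        k_hi = int(np.ceil((m + tail * s) / dx)) + 1
        L = k_hi - k_lo + 1  # number of offset nodes
        for i in range(n):
            scratch[i] = P[r, i]
            P[r, i] = 0.0
        # slopes of E between consecutive offset nodes
        a = k_lo * dx
        z = (a - m) / s
        zc = min(max(z, -38.0), 38.0)
        E_prev = (a - m) * 0.5 * (1.0 + math_erf(z / sq2)) + s * np.exp(-0.5 * zc * zc) / sq2pi
        slope_prev = 0.0  # E' below the kernel support is ~0
        for ci in range(L):
            if ci < L - 1:
                a = (k_lo + ci + 1) * dx
                z = (a - m) / s
                zc = min(max(z, -38.0), 38.0)
                E_next = (a - m) * 0.5 * (1.0 + math_erf(z / sq2)) + s * np.exp(-0.5 * zc * zc) / sq2pi
                slope = (E_next - E_prev) / dx
                E_prev = E_next
                we = slope - slope_prev
                slope_prev = slope
            else:
                we = 1.0 - slope_prev
            if we <= 1e-300:
                continue
            k = k_lo + ci
            if k >= 0:
                for i in range(0, n - k):
                    P[r, i + k] += we * scratch[i]
                for i in range(max(n - k, 0), n):
                    up[r] += we * scratch[i]
            else:
                for i in range(-k, n):
                    P[r, i + k] += we * scratch[i]
                for i in range(0, min(-k, n)):
                    lo[r] += we * scratch[i]


def choice_probs_batched(
    prep: PreparedSession,
    params: AccumulatorParams,
    I: np.ndarray,
    n_bins: int = 61,
) -> np.ndarray:
    """P(choose R) for every trial of a prepared session.

    ``I`` is the per-trial initial state (length n_trials). Returns the
    accumulator-only probabilities; lapse mixing happens downstream.
    """
    if I.shape != (prep.n_trials,):
        raise ValueError("I must have one entry per trial")
    grid = FPGrid(bound=params.bound, n_bins=n_bins, dt=prep.dt)
    A = base_transition_matrix(grid, params)
    A_int = A[1:-1, 1:-1]
    a_lo = A[0, 1:-1]
    a_up = A[-1, 1:-1]

    P, lo, up = _deposit_batched(np.asarray(I, float), grid)
    mags = prep.adapted_magnitudes(params.phi, params.tau_phi)
    sig_s = float(np.sqrt(params.sigma2_s))

    max_steps = int(prep.n_steps.max()) if prep.n_trials else 0
    sub_ptr = np.searchsorted(prep.ev_sub, np.arange(2 * max_steps + 1))
    uniform = bool(np.all(prep.n_steps == max_steps))
    ev_C = mags[prep.ev_trial, prep.ev_col]
    ev_means = prep.click_side[prep.ev_trial, prep.ev_col] * ev_C
    ev_sds = ev_C * sig_s

    def _apply_events(s0: int, s1: int) -> None:
        if s0 < s1:
            _apply_events_nb(
                P, lo, up, prep.ev_trial[s0:s1], ev_means[s0:s1], ev_sds[s0:s1],
                grid.dx, _TAIL_SIGMAS,
            )

    for k in range(max_steps):
        _apply_events(sub_ptr[2 * k], sub_ptr[2 * k + 1])
        if uniform:
            lo += P @ a_lo
            up += P @ a_up
            P = P @ A_int.T
        else:
            act = np.flatnonzero(prep.n_steps > k)
            Pa = P[act]
            lo[act] += Pa @ a_lo
            up[act] += Pa @ a_up
            P[act] = Pa @ A_int.T
        _apply_events(sub_ptr[2 * k + 1], sub_ptr[2 * k + 2])

    frac_above = np.clip((grid.edges[1:] - params.bias) / grid.dx, 0.0, 1.0)
    p = P @ frac_above
    if grid.bound > params.bias:
        p += up
    elif grid.bound == params.bias:
        p += 0.5 * up
    if -grid.bound > params.bias:
        p += lo
    elif -grid.bound == params.bias:
        p += 0.5 * lo
    return p
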