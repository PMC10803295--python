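"""Non-decision times and the joint choice/reaction-time likelihood.

Observed reaction times decompose into the accumulator's bound-hitting
(decision) time plus a non-decision time (NDT) modeling sensory and
motor latencies. NDTs are draws from a Wald (inverse Gaussian)
distribution — itself the first-passage time of a single-bound
diffusion with bound ω_k and drift ν_k per choice side k ∈ {L, R} —
whose effective drift slows with trial number (satiation, rate α) and
after errors (post-error slowing, increment γ_o, typically negative):

    τ_NDT ~ IG( ω_k / (ν_k − α n + γ_o·1⁻_{n−1}),  ω_k² )

with IG parameterized by (mean, shape). The joint likelihood of an
observed (choice, RT) pair marginalizes the first-passage density over
hitting times τ ≤ RT, convolved with the NDT density at RT − τ; on true
lapse trials the RT arises from the NDT alone.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats

from .accumulator import AccumulatorParams, FPGrid, first_passage_density
from .io import TrialRecord
from .lapse import LapseParams, true_lapse_prob

__all__ = ["NDTParams", "effective_drift", "ndt_density", "sample_ndt",
           "joint_choice_rt_likelihood"]


@dataclass(frozen=True)
class NDTParams:
    """Wald non-decision-time parameters (per-side bounds/drifts plus
    trial-number and post-error drift modulation)."""

    omega_L: float = 1.5
    omega_R: float = 1.5
    nu_L: float = 10.0
    nu_R: float = 10.0
    alpha: float = 0.0
    gamma_o: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_L <= 0 or self.omega_R <= 0:
            raise ValueError("Wald bounds omega must be > 0")


def effective_drift(params: NDTParams, side: str, trial_number: int, prev_error: bool) -> float:
    nu = params.nu_R if side == "R" else params.nu_L
    drift = nu - params.alpha * trial_number + (params.gamma_o if prev_error else 0.0)
    if drift <= 0:
        raise ValueError(
            f"effective NDT drift {drift:.4g} <= 0 (side={side}, n={trial_number})"
        )
    return drift


def _ig(params: NDTParams, side: str, trial_number: int, prev_error: bool):
    omega = params.omega_R if side == "R" else params.omega_L
    drift = effective_drift(params, side, trial_number, prev_error)
    mean = omega / drift
    shape = omega**2
    # scipy's invgauss(mu, scale): mean = mu*scale, shape = scale
    return stats.invgauss(mu=mean / shape, scale=shape)


def ndt_density(
    t: float | np.ndarray,
    side: str,
    trial_number: int,
    prev_error: bool,
    params: NDTParams,
) -> float | np.ndarray:
    """Wald density of the non-decision time at t > 0 (0 for t ≤ 0)."""
    dist = _ig(params, side, trial_number, prev_error)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    pos = t_arr > 0
    out[pos] = dist.pdf(t_arr[pos])
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def sample_ndt(
    side: str,
    trial_number: int,
    prev_error: bool,
    params: NDTParams,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    dist = _ig(params, side, trial_number, prev_error)
    draw = dist.rvs(size=size, random_state=rng)
    return float(draw) if size is None else draw


def joint_choice_rt_likelihood(
    trial: TrialRecord,
    I: float,
    theta_acc: AccumulatorParams,
    theta_ndt: NDTParams,
    theta_lapse: LapseParams,
    grid: FPGrid | None = None,
    prev_error: bool = False,
) -> float:
    """Likelihood density of the observed (choice, RT) pair.

    Accumulation branch: Σ over hitting-time bins τ ≤ RT of the
    first-passage mass for the observed choice times the NDT density at
    RT − τ (discrete convolution on the Fokker–Planck time grid). Lapse
    branch: lapse choice probability times the NDT density at the full
    RT. Total = (1 − κ)·acc + κ·lapse.
    """
    if trial.violation or trial.rt is None:
        raise ValueError("joint likelihood requires a non-violation trial with an RT")
    if trial.rt <= 0:
        raise ValueError("rt must be > 0")
    rt = trial.rt
    side = trial.choice
    passage = first_passage_density(trial, theta_acc, I, grid, horizon=rt)
    mass = passage.mass_upper if side == "R" else passage.mass_lower
    lags = rt - passage.t
    dens = ndt_density(lags, side, trial.trial_index, prev_error, theta_ndt)
    acc_branch = float(mass @ dens)
    lapse_p = true_lapse_prob(theta_lapse, I)
    p_choice_lapse = lapse_p if side == "R" else 1.0 - lapse_p
    lapse_branch = p_choice_lapse * float(
        ndt_density(rt, side, trial.trial_index, prev_error, theta_ndt)
    )
    kappa = theta_lapse.kappa
    return (1.0 - kappa) * acc_branch + kappa * lapse_branch
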