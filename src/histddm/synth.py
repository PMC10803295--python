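"""Fully synthetic sessions with the statistical structure the analysis
assumes: Poisson click trains, a closed-loop generative agent whose
initial state follows its own realized choice-outcome history, true
lapses, sticky-bound accumulation, and (in reaction-time mode) Wald
non-decision times.

The generator is the stand-in for real rat sessions: fitting code sees
only the session table; the latent ground truth (initial states, lapse
flags, decision times) is returned separately — and written to a
sidecar file, never into the session CSV — for test harnesses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from numba import njit

from .accumulator import AccumulatorParams
from .batch import adapted_magnitudes_padded
from .history import PAIRS, HistoryFilterParams
from .io import SessionTable, TrialRecord
from .lapse import LapseParams
from .ndt import NDTParams, sample_ndt

__all__ = [
    "TaskConfig",
    "GenerativeAgent",
    "generate_click_trains",
    "simulate_agent_session",
    "make_cohort",
    "write_truth_sidecar",
]

#: default difficulty levels: generative (right, left) rates in Hz summing
#: to 40, mirrored about equality — the task family's convention
DEFAULT_RATE_PAIRS = ((39.0, 1.0), (31.0, 9.0), (26.0, 14.0), (22.0, 18.0))


@dataclass(frozen=True)
class TaskConfig:
    """Task-side generative settings.

    ``rate_ratios`` lists r_R/r_L levels (symmetric about 1); the two
    Poisson rates always sum to ``total_click_rate``. ``duration`` is a
    fixed stimulus length or a (lo, hi) uniform range for the
    fixed-duration task; in reaction-time mode clicks are generated over
    ``rt_window`` seconds and truncated at the response.
    """

    n_trials: int = 1000
    task_mode: Literal["fixed_duration", "reaction_time"] = "fixed_duration"
    total_click_rate: float = 40.0
    rate_ratios: tuple[float, ...] = tuple(
        r / l for r, l in DEFAULT_RATE_PAIRS
    ) + tuple(l / r for r, l in DEFAULT_RATE_PAIRS)
    duration: float | tuple[float, float] = (0.2, 1.0)
    reward_rule: Literal["greater_count", "greater_rate"] | None = None
    rt_window: float = 8.0
    violation_prob: float = 0.0
    sim_dt: float = 1e-3
    session_id: str = "synth0"

    def __post_init__(self) -> None:
        if self.total_click_rate <= 0:
            raise ValueError("total_click_rate must be > 0")
        ratios = sorted(self.rate_ratios)
        inv = sorted(1.0 / r for r in self.rate_ratios)
        if not np.allclose(ratios, inv, rtol=1e-9):
            raise ValueError("rate_ratios must be symmetric about 1")

    @property
    def effective_reward_rule(self) -> str:
        if self.reward_rule is not None:
            return self.reward_rule
        return "greater_count" if self.task_mode == "fixed_duration" else "greater_rate"


@dataclass(frozen=True)
class GenerativeAgent:
    """Full generative model: history filters, accumulator, true lapses,
    and (reaction-time mode) non-decision times."""

    history: HistoryFilterParams = field(
        default_factory=lambda: HistoryFilterParams.paper_constrained(
            eta_Rw=0.8, eta_Lw=-0.8, eta_loss=0.35, beta_win=0.55, beta_loss=0.35
        )
    )
    acc: AccumulatorParams = field(default_factory=lambda: AccumulatorParams(
        lam=0.0, sigma2_a=7.0, sigma2_s=0.2, bound=2.5, phi=0.35, tau_phi=0.1, bias=0.0
    ))
    lapse: LapseParams = field(default_factory=lambda: LapseParams(kappa=0.08, rho=0.5))
    ndt: NDTParams = field(default_factory=lambda: NDTParams(
        omega_L=1.5, omega_R=1.5, nu_L=10.0, nu_R=10.0, alpha=0.0, gamma_o=-1.0
    ))


def generate_click_trains(
    config: TaskConfig, rng: np.random.Generator
) -> list[dict]:
    """Per-trial Poisson click trains plus the rewarded side.

    Difficulty level and rewarded side are sampled independently: a
    ratio level is drawn, oriented so its loud side matches a coin flip,
    then homogeneous Poisson trains are sampled for each side. The
    correct side follows the reward rule: realized count comparison
    (ties broken at random) or the generative rate comparison.
    """
    trials = []
    ratios = np.asarray(config.rate_ratios, dtype=float)
    for _ in range(config.n_trials):
        ratio = float(rng.choice(ratios))
        r_R = config.total_click_rate * ratio / (1.0 + ratio)
        r_L = config.total_click_rate - r_R
        if config.task_mode == "fixed_duration":
            dur = (
                float(config.duration)
                if np.isscalar(config.duration)
                else float(rng.uniform(*config.duration))
            )
        else:
            dur = config.rt_window
        left = np.sort(rng.uniform(0.0, dur, rng.poisson(r_L * dur)))
        right = np.sort(rng.uniform(0.0, dur, rng.poisson(r_R * dur)))
        if config.effective_reward_rule == "greater_count":
            if right.size != left.size:
                correct = "R" if right.size > left.size else "L"
            else:
                correct = "R" if rng.random() < 0.5 else "L"
        else:
            correct = "R" if r_R > r_L else ("L" if r_L > r_R else ("R" if rng.random() < 0.5 else "L"))
        trials.append(
            {"left": left, "right": right, "duration": dur, "correct": correct, "ratio": ratio}
        )
    return trials


_VARIANT_CODE = {"motor": 0, "inattention": 1, "hybrid": 2}


@njit(cache=True)
def _simulate_kernel(
    durations,
    click_ptr,
    click_t,
    click_val,          # signed adapted magnitude per click
    correct_R,          # int8
    dt,
    lam,
    sig_a,
    sig_s,
    B,
    bias,
    eta4,
    beta4,
    kappa,
    variant,
    rho,
    mslope,
    rt_mode,
    t_max,
    viol_prob,
    seed,
):
    np.random.seed(seed)
    n = durations.size
    I_seq = np.empty(n)
    choice_R = np.empty(n, dtype=np.int8)   # 1 R, 0 L, -1 violation
    win = np.zeros(n, dtype=np.int8)
    lapsed = np.zeros(n, dtype=np.bool_)
    absorbed = np.zeros(n, dtype=np.bool_)
    tau = np.full(n, np.nan)
    filters = np.zeros(4)
    sqdt = np.sqrt(dt)
    for i in range(n):
        I = filters[0] + filters[1] + filters[2] + filters[3]
        I_seq[i] = I
        if viol_prob > 0.0 and np.random.random() < viol_prob:
            choice_R[i] = -1
            continue  # filters frozen on violations
        chose_R = 0
        if np.random.random() < kappa:
            lapsed[i] = True
            tau[i] = 0.0
            if variant == 0:
                p = rho
            elif variant == 1:
                d = I - rho
                p = 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
            else:
                p = 1.0 / (1.0 + np.exp(-mslope * (I - rho)))
            chose_R = 1 if np.random.random() < p else 0
        else:
            x = I
            if x >= B:
                absorbed[i] = True
                tau[i] = 0.0
                chose_R = 1
            elif x <= -B:
                absorbed[i] = True
                tau[i] = 0.0
                chose_R = 0
            else:
                horizon = t_max if rt_mode else durations[i]
                n_steps = int(np.ceil(horizon / dt - 1e-9))
                c0, c1 = click_ptr[i], click_ptr[i + 1]
                cp = c0
                done = False
                var_dt = sig_a * sig_a * dt
                for k in range(n_steps):
                    x_prev = x
                    x += lam * x * dt + sig_a * sqdt * np.random.normal()
                    t_hi = (k + 1) * dt
                    hit = 0
                    if x >= B:
                        hit = 1
                    elif x <= -B:
                        hit = -1
                    elif var_dt > 0.0:
                        # Brownian-bridge within-step crossing test
                        if np.random.random() < np.exp(-2.0 * (B - x_prev) * (B - x) / var_dt):
                            hit = 1
                        elif np.random.random() < np.exp(-2.0 * (B + x_prev) * (B + x) / var_dt):
                            hit = -1
                    if hit == 0:
                        while cp < c1 and click_t[cp] < t_hi:
                            v = click_val[cp]
                            x += v + abs(v) * sig_s * np.random.normal()
                            cp += 1
                        if x >= B:
                            hit = 1
                        elif x <= -B:
                            hit = -1
                    if hit != 0:
                        absorbed[i] = True
                        tau[i] = t_hi
                        chose_R = 1 if hit == 1 else 0
                        x = B if hit == 1 else -B
                        done = True
                        break
                if not done:
                    tau[i] = horizon if rt_mode else np.nan
                    if x > bias:
                        chose_R = 1
                    elif x < bias:
                        chose_R = 0
                    else:
                        chose_R = 1 if np.random.random() < 0.5 else 0
        choice_R[i] = chose_R
        w = 1 if chose_R == correct_R[i] else 0
        win[i] = w
        pair = (0 if chose_R == 1 else 1) if w == 1 else (2 if chose_R == 1 else 3)
        for h in range(4):
            filters[h] *= beta4[h]
        filters[pair] += eta4[pair]
    return I_seq, choice_R, win, lapsed, absorbed, tau


def simulate_agent_session(
    config: TaskConfig,
    agent: GenerativeAgent,
    rng: np.random.Generator,
) -> tuple[SessionTable, dict]:
    """Closed-loop simulation of an agent performing a whole session.

    Per trial: the initial state is computed from the realized past
    choice-outcome pairs; with probability κ the trial is a true lapse
    (variant rule, reaction time from the non-decision process alone),
    otherwise the accumulator SDE is forward-simulated from I(n). In
    reaction-time mode the reported RT is the bound-hitting time plus a
    Wald non-decision sample, and the stored click train is truncated at
    the response. Returns the session table and a hidden ground-truth
    dict (initial states, lapse flags, decision times).
    """
    stims = generate_click_trains(config, rng)
    n = len(stims)
    K = max(max(s["left"].size + s["right"].size for s in stims), 1)
    click_t = np.zeros((n, K))
    click_side = np.zeros((n, K), dtype=np.int8)
    click_mask = np.zeros((n, K), dtype=bool)
    for i, s in enumerate(stims):
        times = np.concatenate([s["left"], s["right"]])
        sides = np.concatenate(
            [-np.ones(s["left"].size, np.int8), np.ones(s["right"].size, np.int8)]
        )
        order = np.lexsort((sides, times))
        m = times.size
        click_t[i, :m] = times[order]
        click_side[i, :m] = sides[order]
        click_mask[i, :m] = True
    mags = adapted_magnitudes_padded(click_t, click_mask, agent.acc.phi, agent.acc.tau_phi)
    flat = click_mask.ravel()
    click_ptr = np.concatenate([[0], np.cumsum(click_mask.sum(axis=1))]).astype(np.int64)
    flat_t = click_t.ravel()[flat]
    flat_val = (click_side * mags).ravel()[flat]
    durations = np.array([s["duration"] for s in stims])
    correct_R = np.array([1 if s["correct"] == "R" else 0 for s in stims], dtype=np.int8)

    h = agent.history
    eta4 = np.array([h.eta[p] for p in PAIRS])
    beta4 = np.array([h.beta[p] for p in PAIRS])
    lp = agent.lapse
    rt_mode = config.task_mode == "reaction_time"
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    I_seq, choice_R, win, lapsed, absorbed, tau = _simulate_kernel(
        durations,
        click_ptr,
        flat_t,
        flat_val,
        correct_R,
        config.sim_dt,
        agent.acc.lam,
        float(np.sqrt(agent.acc.sigma2_a)),
        float(np.sqrt(agent.acc.sigma2_s)),
        agent.acc.bound,
        agent.acc.bias,
        eta4,
        beta4,
        lp.kappa,
        _VARIANT_CODE[lp.variant],
        lp.rho,
        float(lp.matching_slope or 0.0),
        rt_mode,
        config.rt_window,
        config.violation_prob,
        kernel_seed,
    )

    rts = np.full(n, np.nan)
    if rt_mode:
        prev_err = False
        for i in range(n):
            if choice_R[i] < 0:
                continue
            side = "R" if choice_R[i] == 1 else "L"
            ndt = sample_ndt(side, i + 1, prev_err, agent.ndt, rng)
            rts[i] = tau[i] + ndt
            prev_err = win[i] == 0
    trials = []
    for i, s in enumerate(stims):
        viol = choice_R[i] < 0
        if rt_mode and not viol:
            dur = float(max(rts[i], config.sim_dt))
            left = tuple(x for x in s["left"] if x <= dur)
            right = tuple(x for x in s["right"] if x <= dur)
        else:
            dur = float(durations[i])
            left, right = tuple(s["left"]), tuple(s["right"])
        trials.append(
            TrialRecord(
                trial_index=i + 1,
                left_clicks=left,
                right_clicks=right,
                duration=dur,
                choice="none" if viol else ("R" if choice_R[i] == 1 else "L"),
                outcome="none" if viol else ("win" if win[i] == 1 else "loss"),
                rt=float(rts[i]) if (rt_mode and not viol) else None,
                violation=bool(viol),
                session_id=config.session_id,
            )
        )
    table = SessionTable(tuple(trials), config.task_mode)
    truth = {
        "initial_state": I_seq,
        "lapsed": lapsed,
        "absorbed": absorbed,
        "decision_time": tau,
        "rt": rts,
        "correct_R": correct_R,
        "ratio": np.array([s["ratio"] for s in stims]),
    }
    return table, truth


def make_cohort(
    n_rats: int,
    parameter_ranges: Mapping[str, tuple[float, float]],
    config: TaskConfig,
    seed: int,
) -> list[tuple[SessionTable, GenerativeAgent, dict]]:
    """Draw ``n_rats`` agents with independent uniform parameters within
    the given ranges (keys: eta_Rw, eta_Lw, eta_loss, beta_win,
    beta_loss, lam, sigma2_a, sigma2_s, bound, phi, tau_phi, bias,
    kappa, rho) and simulate one session each. Reproducible by seed."""
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_rats):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in parameter_ranges.items()}
        base = GenerativeAgent()
        hist_kw = {
            k: draw.pop(k)
            for k in ("eta_Rw", "eta_Lw", "eta_loss", "beta_win", "beta_loss")
            if k in draw
        }
        hdef = base.history
        hist = HistoryFilterParams.paper_constrained(
            eta_Rw=hist_kw.get("eta_Rw", hdef.eta["Rw"]),
            eta_Lw=hist_kw.get("eta_Lw", hdef.eta["Lw"]),
            eta_loss=hist_kw.get("eta_loss", hdef.eta["Ll"]),
            beta_win=hist_kw.get("beta_win", hdef.beta["Rw"]),
            beta_loss=hist_kw.get("beta_loss", hdef.beta["Rl"]),
        )
        lapse_kw = {k: draw.pop(k) for k in ("kappa", "rho") if k in draw}
        acc = replace(base.acc, **{k: v for k, v in draw.items()})
        lapse = replace(base.lapse, **lapse_kw)
        agent = replace(base, history=hist, acc=acc, lapse=lapse)
        cfg = replace(config, session_id=f"{config.session_id}_rat{r}")
        table, truth = simulate_agent_session(cfg, agent, rng)
        out.append((table, agent, truth))
    return out


def write_truth_sidecar(truth: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Serialize the hidden ground truth as JSON next to a session CSV."""
    payload = {
        k: np.asarray(v).tolist() for k, v in truth.items()
    }
    Path(path).write_text(json.dumps(payload))
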