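"""Trial-history filters that set the accumulator's initial state.

Each choice-outcome pair h ∈ {Rw, Lw, Rl, Ll} (right-win, left-win,
right-loss, left-loss) is tracked by its own exponential filter i^h.
After trial n−1 with observed pair o, every filter decays by its β^h and
the filter matching o is incremented by η^h:

    i^h(n) = β^h i^h(n−1) + η^h 1[o_{n−1} = h]

The initial accumulator state on trial n is the sum of the four filters,
I(n) = Σ_h i^h(n). Positive I favors the rightward bound +B.

Violation trials (no choice, no outcome) freeze the filters by default —
no increment and no decay — since those trials carry no history signal;
a flag switches to decay-only propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np

from .io import SessionTable

__all__ = ["PAIRS", "HistoryFilterParams", "HistoryState", "update_history",
           "initial_state_sequence", "dbm_constrain"]

PAIRS = ("Rw", "Lw", "Rl", "Ll")

ConstraintMode = Literal["unconstrained", "paper_constrained", "dbm"]


@dataclass(frozen=True)
class HistoryFilterParams:
    """Increment (eta) and decay (beta) per choice-outcome pair.

    ``constraint_mode`` records the tying scheme:

    - ``unconstrained``: 8 free parameters.
    - ``paper_constrained``: losses share eta and beta; wins share beta
      (5 free: eta_Rw, eta_Lw, eta_loss, beta_win, beta_loss). After a
      right loss the increment is −eta_loss and after a left loss
      +eta_loss (lose-switch sign convention).
    - ``dbm``: single beta and single |eta|, signed by chosen side
      (2 free) — the exponential-filter reduction of a dynamic belief
      model tracking a prior with unsignaled switches.
    """

    eta: Mapping[str, float]
    beta: Mapping[str, float]
    constraint_mode: ConstraintMode = "unconstrained"

    def __post_init__(self) -> None:
        for h in PAIRS:
            if h not in self.eta or h not in self.beta:
                raise ValueError(f"missing pair {h}")
            if not (0.0 <= self.beta[h] < 1.0):
                raise ValueError(f"beta[{h}]={self.beta[h]} must lie in [0, 1)")
        if self.constraint_mode == "paper_constrained":
            ok = (
                self.beta["Rl"] == self.beta["Ll"]
                and self.eta["Rl"] == -self.eta["Ll"]
                and self.beta["Rw"] == self.beta["Lw"]
            )
            if not ok:
                raise ValueError("paper_constrained requires tied loss params and tied win betas")
        if self.constraint_mode == "dbm":
            betas = {self.beta[h] for h in PAIRS}
            mags = {abs(self.eta[h]) for h in PAIRS}
            signs_ok = (
                self.eta["Rw"] >= 0 and self.eta["Lw"] <= 0
                and self.eta["Rl"] >= 0 and self.eta["Ll"] <= 0
            )
            if len(betas) > 1 or len(mags) > 1 or not signs_ok:
                raise ValueError("dbm requires one beta, one |eta|, sign set by chosen side")

    @classmethod
    def zeros(cls) -> "HistoryFilterParams":
        return cls({h: 0.0 for h in PAIRS}, {h: 0.0 for h in PAIRS})

    @classmethod
    def paper_constrained(
        cls,
        eta_Rw: float,
        eta_Lw: float,
        eta_loss: float,
        beta_win: float,
        beta_loss: float,
    ) -> "HistoryFilterParams":
        """Identifiability-constrained form used for non-reaction-time data.

        ``eta_loss`` is the magnitude of the lose-switch update: a right
        loss shifts the initial state by −eta_loss, a left loss by
        +eta_loss.
        """
        eta = {"Rw": eta_Rw, "Lw": eta_Lw, "Rl": -eta_loss, "Ll": eta_loss}
        beta = {"Rw": beta_win, "Lw": beta_win, "Rl": beta_loss, "Ll": beta_loss}
        return cls(eta, beta, "paper_constrained")

    @property
    def n_free(self) -> int:
        return {"unconstrained": 8, "paper_constrained": 5, "dbm": 2}[self.constraint_mode]

    def stationary_bound(self) -> float:
        """Upper bound on |I(n)|: Σ_h |η^h| / (1 − β^h)."""
        return sum(abs(self.eta[h]) / (1.0 - self.beta[h]) for h in PAIRS)


@dataclass(frozen=True)
class HistoryState:
    """The four filter values and their sum, the initial state I(n)."""

    filters: Mapping[str, float]

    @classmethod
    def zero(cls) -> "HistoryState":
        return cls({h: 0.0 for h in PAIRS})

    @property
    def initial_state(self) -> float:
        return sum(self.filters[h] for h in PAIRS)


def update_history(
    state: HistoryState,
    observed_pair: str,
    params: HistoryFilterParams,
    *,
    decay_on_violation: bool = False,
) -> HistoryState:
    """One step of the filter recursion given the previous trial's pair.

    ``observed_pair='none'`` (violation) leaves the state frozen unless
    ``decay_on_violation`` is set, in which case filters decay without
    increment.
    """
    if observed_pair == "none":
        if not decay_on_violation:
            return state
        return HistoryState({h: params.beta[h] * state.filters[h] for h in PAIRS})
    if observed_pair not in PAIRS:
        raise ValueError(f"unknown choice-outcome pair {observed_pair!r}")
    return HistoryState(
        {
            h: params.beta[h] * state.filters[h]
            + (params.eta[h] if h == observed_pair else 0.0)
            for h in PAIRS
        }
    )


def initial_state_sequence(
    table: SessionTable | Iterable[str],
    params: HistoryFilterParams,
    start_state: HistoryState | None = None,
    *,
    decay_on_violation: bool = False,
) -> np.ndarray:
    """I(n) for every trial of a session, in table order.

    Accepts either a :class:`SessionTable` or a bare sequence of pair
    labels. I(1) equals the start state's initial state (all-zero by
    default: no information before the first trial).
    """
    if isinstance(table, SessionTable):
        pairs = [t.history_pair for t in table]
    else:
        pairs = list(table)
    state = start_state if start_state is not None else HistoryState.zero()
    out = np.empty(len(pairs))
    for n, pair in enumerate(pairs):
        out[n] = state.initial_state
        state = update_history(state, pair, params, decay_on_violation=decay_on_violation)
    return out


def dbm_constrain(params: HistoryFilterParams) -> HistoryFilterParams:
    """Project onto the dynamic-belief-model reduction: one decay rate,
    one update magnitude, sign set by the chosen side (R positive).

    Averages the existing decay rates and |increments|; idempotent on
    already-constrained parameters.
    """
    beta = float(np.mean([params.beta[h] for h in PAIRS]))
    mag = float(np.mean([abs(params.eta[h]) for h in PAIRS]))
    sign = {"Rw": 1.0, "Lw": -1.0, "Rl": 1.0, "Ll": -1.0}
    return HistoryFilterParams(
        {h: sign[h] * mag for h in PAIRS},
        {h: beta for h in PAIRS},
        "dbm",
    )
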