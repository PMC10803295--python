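"""True-lapse processes and their mixture with the accumulator.

On a fraction κ of trials the choice bypasses evidence accumulation:

- ``motor``: a biased coin, P(R) = ρ, independent of everything.
- ``inattention``: deterministically choose the side favored by the
  initial state relative to a criterion ρ (0.5 at exact ties) — an
  evidence-independent but history-dependent lapse.
- ``hybrid``: logistic in m(I − ρ); interpolates between the two as the
  matching slope m grows.

The observed choice probability is the κ-mixture of the lapse rule and
the accumulator's choice probability, so asymptotic performance is
compressed into [κ·min_lapse, 1 − κ(1 − max_lapse)]: the true-lapse
floor and ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["LapseParams", "true_lapse_prob", "mixture_choice_prob"]

Variant = Literal["motor", "inattention", "hybrid"]


@dataclass(frozen=True)
class LapseParams:
    """Mixture fraction κ, lapse bias ρ, and (hybrid only) slope m.

    For the motor variant ρ is a probability in [0, 1]; for the
    inattention/hybrid variants ρ is a criterion on the initial-state
    axis, in accumulator units.
    """

    kappa: float = 0.0
    rho: float = 0.5
    matching_slope: float | None = None
    variant: Variant = "motor"

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        if self.variant == "motor":
            if not (0.0 <= self.rho <= 1.0):
                raise ValueError("motor-variant rho is a probability in [0, 1]")
            if self.matching_slope is not None:
                raise ValueError("matching_slope is only meaningful for the hybrid variant")
        elif self.variant == "inattention":
            if self.matching_slope is not None:
                raise ValueError("matching_slope is only meaningful for the hybrid variant")
        elif self.variant == "hybrid":
            if self.matching_slope is None or self.matching_slope < 0:
                raise ValueError("hybrid variant requires matching_slope m >= 0")
        else:
            raise ValueError(f"unknown lapse variant {self.variant!r}")


def true_lapse_prob(params: LapseParams, I: float = 0.0) -> float:
    """Probability of a rightward choice on a lapse trial."""
    if params.variant == "motor":
        return params.rho
    d = I - params.rho
    if params.variant == "inattention":
        return 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
    # hybrid: sigmoid with matching slope m
    return float(1.0 / (1.0 + np.exp(-np.clip(params.matching_slope * d, -700, 700))))


def mixture_choice_prob(p_acc: float, params: LapseParams, I: float = 0.0) -> float:
    """Total P(choose R) from accumulation and true lapses:
    (1 − κ) p_acc + κ · lapse rule."""
    if not (0.0 <= p_acc <= 1.0 + 1e-12):
        raise ValueError(f"p_acc={p_acc} is not a probability")
    return (1.0 - params.kappa) * min(p_acc, 1.0) + params.kappa * true_lapse_prob(params, I)
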