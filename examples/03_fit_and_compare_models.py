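"""Fit the accumulator with and without history-dependent initial
states and compare them by per-trial BIC.

Simulates a 2500-trial session from a history-updating agent, fits
both model variants by maximum likelihood (Fokker–Planck choice
likelihoods, accumulator noise parameters pinned at their generative
values to keep this example quick), and shows that BIC prefers the
history model and recovers its parameters.
"""

import numpy as np

from histddm import (
    GenerativeAgent,
    ModelSpec,
    TaskConfig,
    bic_compare,
    fit_mle,
    simulate_agent_session,
)

table, _ = simulate_agent_session(
    TaskConfig(n_trials=2500, duration=0.5), GenerativeAgent(), np.random.default_rng(3)
)

common = dict(lam=0.0, sigma2_a=7.0, sigma2_s=0.2, bound=2.5,
              phi=0.35, tau_phi=0.1, bias=0.0, rho=0.5)
hist_spec = ModelSpec(
    free=("eta_Rw", "eta_Lw", "beta_win", "kappa"),
    fixed=dict(eta_loss=0.35, beta_loss=0.35, **common),
    n_bins=51, dt=0.01,
)
null_spec = ModelSpec(with_hist=False, free=("kappa",), fixed=common,
                      n_bins=51, dt=0.01)

fit_h = fit_mle(table, hist_spec, seed=0, n_starts=1, maxfev=140)
fit_0 = fit_mle(table, null_spec, seed=0, n_starts=1, maxfev=30)

print("history model fit (generative values: eta_Rw 0.8, eta_Lw -0.8, "
      "beta_win 0.55, kappa 0.08):")
for p in hist_spec.free:
    print(f"  {p:>9} = {fit_h.best_params[p]:+.3f}")
cmp = bic_compare(fit_h, fit_0)
print(f"per-trial BIC: with history {cmp.per_trial_bic_a:.4f} vs "
      f"without {cmp.per_trial_bic_b:.4f}")
print(f"delta {cmp.delta:+.4f} -> the history model is "
      + ("preferred" if cmp.preferred == "a" else "rejected"))
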