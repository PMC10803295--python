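"""Simulate a synthetic rat session and quantify history modulation.

Generates a Poisson-clicks session from the full generative agent
(history filters + click accumulator + motor lapses), writes/reads it
through the CSV round trip, applies the session quality filters, and
fits history-conditioned psychometric curves. The threshold and
lapse-rate modulations move together — the signature of initial-state
updating.
"""

import tempfile
from pathlib import Path

import numpy as np

from histddm import (
    GenerativeAgent,
    TaskConfig,
    apply_session_filters,
    condition_on_history,
    fit_psychometric,
    modulation_metrics,
    read_session_table,
    simulate_agent_session,
    stimulus_strengths,
    write_session_table,
)

cfg = TaskConfig(n_trials=6000, duration=0.5)
table, truth = simulate_agent_session(cfg, GenerativeAgent(), np.random.default_rng(1))

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "session.csv"
    write_session_table(table, path)
    table = read_session_table(path)

table = apply_session_filters(table)
print(f"session retained: {len(table)} trials, "
      f"accuracy {np.mean([t.outcome == 'win' for t in table]):.3f}")

fits = {}
for key in ("prev_Rw", "prev_Lw"):
    sub = condition_on_history(table, key).non_violation()
    x = stimulus_strengths(sub)  # signed click difference
    y = np.array([t.choice == "R" for t in sub])
    fits[key] = fit_psychometric(x, y, seed=0)
    print(f"{key}: threshold {fits[key].x0:+.2f} clicks, "
          f"lapse L {fits[key].lapse_left:.3f}, lapse R {fits[key].lapse_right:.3f}")

mod = modulation_metrics(fits["prev_Rw"], fits["prev_Lw"])
print(f"threshold modulation {mod.threshold_mod:+.2f} clicks "
      "(negative: post-right-win curves shift toward rightward choices)")
print(f"net lapse-rate modulation {mod.lapse_mod:+.3f} "
      "(positive: asymptotes shift the same way)")
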