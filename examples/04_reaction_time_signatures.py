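"""Reaction-time signatures of initial-state updating.

Simulates a reaction-time session (stimulus plays until the bound is
hit; RT = decision time + Wald non-decision time) and prints the three
RT signatures that distinguish history-dependent initial states from
drift-rate variability: faster errors than wins, faster responses to
history-consistent stimuli, and repetition bias concentrated at fast
RTs.
"""

import numpy as np

from histddm import GenerativeAgent, TaskConfig, simulate_agent_session

cfg = TaskConfig(n_trials=8000, task_mode="reaction_time")
table, truth = simulate_agent_session(cfg, GenerativeAgent(), np.random.default_rng(7))

rts = np.array([t.rt for t in table])
wins = np.array([t.outcome == "win" for t in table])
print(f"accuracy {wins.mean():.3f}, mean RT {rts.mean():.3f} s")
print(f"1) mean RT on wins {rts[wins].mean():.3f} s vs errors "
      f"{rts[~wins].mean():.3f} s  (errors faster)")

correct_R = truth["correct_R"].astype(bool)
prev_Rw = np.zeros(len(table), dtype=bool)
pp = None
for i, t in enumerate(table):
    if pp is not None:
        prev_Rw[i] = pp == "Rw"
    pp = t.history_pair
print(f"2) after a right win: RT {rts[prev_Rw & correct_R].mean():.3f} s on "
      f"rightward stimuli vs {rts[prev_Rw & ~correct_R].mean():.3f} s on "
      "leftward  (consistent stimuli faster)")

prev = None
reps, rr = [], []
for t in table:
    if prev is not None:
        reps.append(t.choice == prev)
        rr.append(t.rt)
    prev = t.choice
reps, rr = np.array(reps), np.array(rr)
qs = np.quantile(rr, [0.2, 0.4, 0.6, 0.8])
by_bin = [reps[np.digitize(rr, qs) == b].mean() for b in range(5)]
print("3) repetition probability by RT quintile (fast -> slow): "
      + ", ".join(f"{v:.3f}" for v in by_bin))
print("   history dependence lives in the fast responses, where the")
print("   initial state still dominates the accumulated evidence.")
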