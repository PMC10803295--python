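"""4-parameter logistic fitting, history conditioning, modulation
metrics, and bootstrap confidence intervals."""

import numpy as np
import pytest

from histddm.io import SessionTable
from histddm.psychometrics import (
    PsychometricParams,
    bootstrap_ci,
    condition_on_history,
    fit_psychometric,
    modulation_metrics,
    stimulus_strengths,
)

from conftest import make_trial


def sample_curve(rng, n, params, x_levels=None):
    x_levels = np.linspace(-8, 8, 9) if x_levels is None else x_levels
    x = rng.choice(x_levels, n)
    p = params.predict(x)
    y = rng.random(n) < p
    return x, y


class TestFit:
    def test_recovers_known_parameters_from_dense_data(self, rng):
        true = PsychometricParams(0.05, 0.90, 1.0, 0.8)
        x, y = sample_curve(rng, 60_000, true)
        fit = fit_psychometric(x, y, seed=0)
        assert fit.kappa0 == pytest.approx(true.kappa0, abs=0.01)
        assert fit.kappa1 == pytest.approx(true.kappa1, abs=0.02)
        assert fit.x0 == pytest.approx(true.x0, abs=0.15)
        assert fit.b == pytest.approx(true.b, rel=0.15)

    def test_symmetric_data_centers_threshold(self, rng):
        true = PsychometricParams(0.02, 0.96, 0.0, 1.0)
        x, y = sample_curve(rng, 30_000, true)
        fit = fit_psychometric(x, y, seed=0)
        assert abs(fit.x0) < 0.1

    def test_degenerate_all_one_choice_flagged(self, rng):
        x = rng.choice(np.linspace(-4, 4, 8), 500)
        fit = fit_psychometric(x, np.ones(500, dtype=bool), seed=0)
        assert fit.boundary_fit

    def test_needs_four_distinct_strengths(self):
        with pytest.raises(ValueError):
            fit_psychometric([0, 1, 0, 1], [0, 1, 0, 1])


class TestConditioning:
    @staticmethod
    def _alternating_session(n=20):
        trials = []
        for i in range(n):
            c = "R" if i % 2 == 0 else "L"
            trials.append(make_trial(i + 1, choice=c, outcome="win"))
        return SessionTable(tuple(trials))

    def test_partition_disjoint_and_exhaustive(self):
        table = self._alternating_session()
        rw = condition_on_history(table, "prev_Rw")
        lw = condition_on_history(table, "prev_Lw")
        idx_rw = {t.trial_index for t in rw}
        idx_lw = {t.trial_index for t in lw}
        assert idx_rw.isdisjoint(idx_lw)
        assert idx_rw | idx_lw == set(range(2, len(table) + 1))

    def test_win_loss_conditioners_union(self):
        trials = [
            make_trial(1, choice="R", outcome="win"),
            make_trial(2, choice="L", outcome="loss"),
            make_trial(3, choice="R", outcome="loss"),
            make_trial(4, choice="L", outcome="win"),
        ]
        table = SessionTable(tuple(trials))
        win = condition_on_history(table, "prev_win")
        loss = condition_on_history(table, "prev_loss")
        assert [t.trial_index for t in win] == [2]
        assert [t.trial_index for t in loss] == [3, 4]

    def test_violations_are_transparent(self):
        trials = [
            make_trial(1, choice="R", outcome="win"),
            make_trial(2, violation=True),
            make_trial(3, choice="L", outcome="win"),
        ]
        table = SessionTable(tuple(trials))
        rw = condition_on_history(table, "prev_Rw")
        assert [t.trial_index for t in rw] == [3]

    def test_all_violations_after_first_gives_empty_subsets(self):
        trials = [make_trial(1, choice="R", outcome="win")] + [
            make_trial(i, violation=True) for i in range(2, 8)
        ]
        table = SessionTable(tuple(trials))
        assert len(condition_on_history(table, "prev_Rw")) == 0

    def test_win_stay_agent_repeats_after_wins(self, rng):
        trials = []
        prev_choice = "R"
        for i in range(4000):
            choice = prev_choice if rng.random() < 0.7 else ("L" if prev_choice == "R" else "R")
            outcome = "win" if rng.random() < 0.8 else "loss"
            trials.append(make_trial(i + 1, choice=choice, outcome=outcome))
            prev_choice = choice if outcome == "win" else ("L" if choice == "R" else "R")
        table = SessionTable(tuple(trials))
        win_cond = condition_on_history(table, "prev_win")
        # P(repeat previous choice | previous win) > 0.5
        reps = []
        prev = None
        for t in table:
            if prev is not None and prev.outcome == "win":
                reps.append(t.choice == prev.choice)
            prev = t
        assert np.mean(reps) > 0.5


class TestModulation:
    def test_identical_fits_give_zero(self):
        f = PsychometricParams(0.05, 0.9, 0.3, 1.0)
        rep = modulation_metrics(f, f)
        assert rep.threshold_mod == 0.0 and rep.lapse_mod == 0.0

    def test_stated_arithmetic(self):
        a = PsychometricParams(0.10, 0.88, 0.5, 1.0)
        b = PsychometricParams(0.02, 0.90, -0.5, 1.0)
        rep = modulation_metrics(a, b)
        assert rep.threshold_mod == pytest.approx(1.0)
        assert rep.lapse_mod == pytest.approx(2 * 0.08 + (-0.02))


class TestBootstrap:
    def test_same_seed_identical_and_coverage_shape(self, rng):
        true = PsychometricParams(0.05, 0.9, 0.5, 0.9)
        x, y = sample_curve(rng, 3000, true)
        fit_fn = lambda xs, ys: fit_psychometric(xs, ys, n_starts=1, seed=0)
        ci1 = bootstrap_ci(fit_fn, x, y, n_boot=200, seed=42)
        ci2 = bootstrap_ci(fit_fn, x, y, n_boot=200, seed=42)
        assert ci1 == ci2
        for lo, hi in ci1.values():
            assert lo <= hi

    def test_ci_width_shrinks_with_sample_size(self, rng):
        true = PsychometricParams(0.05, 0.9, 0.5, 0.9)
        fit_fn = lambda xs, ys: fit_psychometric(xs, ys, n_starts=1, seed=0)
        widths = []
        for n in (800, 8000):
            x, y = sample_curve(rng, n, true)
            ci = bootstrap_ci(fit_fn, x, y, n_boot=200, seed=1)
            widths.append(ci["x0"][1] - ci["x0"][0])
        assert widths[1] < widths[0] * 0.6  # ~ 1/sqrt(10) expected


class TestStimulusAxis:
    def test_click_difference_axis(self):
        t = make_trial(1, left=(0.1, 0.2), right=(0.05,))
        table = SessionTable((t,))
        np.testing.assert_allclose(stimulus_strengths(table), [-1.0])

    def test_log_rate_ratio_sign(self):
        t = make_trial(1, left=(0.1,), right=(0.05, 0.2, 0.3))
        table = SessionTable((t,))
        assert stimulus_strengths(table, "log_rate_ratio")[0] > 0
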