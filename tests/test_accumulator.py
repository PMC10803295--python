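"""Fokker–Planck engine: adaptation, mass conservation, boundary cases,
deterministic limits, and agreement between the batched and per-trial
solvers."""

import numpy as np
import pytest

from histddm.accumulator import (
    AccumulatorParams,
    FPGrid,
    adapt_click_magnitudes,
    choice_likelihood,
    first_passage_density,
    fokker_planck_evolve,
)
from histddm.batch import PreparedSession, choice_probs_batched
from histddm.io import SessionTable

from conftest import make_trial, random_click_trial


class TestAdaptation:
    def test_no_adaptation_gives_unit_magnitudes(self):
        L, R = adapt_click_magnitudes([0.1, 0.2], [0.15, 0.3], phi=1.0, tau_phi=0.1)
        np.testing.assert_allclose(np.concatenate([L, R]), 1.0)

    def test_first_click_always_unit(self):
        L, R = adapt_click_magnitudes([], [0.37], phi=0.2, tau_phi=0.05)
        assert R[0] == pytest.approx(1.0)

    def test_closed_form_two_click_depression(self):
        L, _ = adapt_click_magnitudes([0.0, 0.1], [], phi=0.5, tau_phi=0.2)
        np.testing.assert_allclose(L, [1.0, 1.0 - 0.5 * np.exp(-0.5)], atol=1e-12)

    def test_matches_fine_ode_integration(self):
        """Cross-check against explicit Euler integration of the
        adaptation ODE with the click impulses."""
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0, 0.5, 24))
        sides = rng.random(24) < 0.5
        phi, tau = 0.3, 0.08
        L, R = adapt_click_magnitudes(times[~sides], times[sides], phi, tau)
        got = np.empty(24)
        got[~sides] = L
        got[sides] = R
        dt = 1e-6
        C, t_prev, out = 1.0, 0.0, []
        for t in times:
            n = int(round((t - t_prev) / dt))
            C = 1.0 + (C - 1.0) * np.exp(-n * dt / tau)
            out.append(C)
            C *= phi
            t_prev = t_prev + n * dt
        np.testing.assert_allclose(got, out, atol=1e-4)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            adapt_click_magnitudes([-0.1], [], 0.5, 0.1)


class TestFokkerPlanck:
    def test_frozen_particle_stays_put(self):
        t = make_trial(1)
        p = AccumulatorParams(lam=0, sigma2_a=0, sigma2_s=0, bound=4, phi=1.0)
        res = fokker_planck_evolve(t, p, I=0.3)
        centers = res.grid.centers
        mean = centers @ res.P_final[1:-1]
        assert mean == pytest.approx(0.3, abs=1e-9)
        assert choice_likelihood(t, p, 0.3) == pytest.approx(1.0)

    def test_start_at_bound_absorbs_instantly(self):
        t = make_trial(1)
        p = AccumulatorParams(bound=2.0)
        res = fokker_planck_evolve(t, p, I=2.0)
        assert res.passage.mass_upper[0] == pytest.approx(1.0)
        assert res.P_final[-1] == pytest.approx(1.0)

    def test_mass_conserved_every_step(self, click_fixture):
        trials, Is = click_fixture
        p = AccumulatorParams(lam=0.3, sigma2_a=2.0, sigma2_s=0.3, bound=2.5,
                              phi=0.4, tau_phi=0.1)
        for t, I in zip(trials[:3], Is[:3]):
            res = fokker_planck_evolve(t, p, I)
            assert res.conservation_error <= 1e-10
            assert res.passage.total == pytest.approx(1.0, abs=1e-10)

    def test_symmetry_gives_half(self):
        t = make_trial(1, left=(0.1, 0.3), right=(0.2, 0.4))
        # symmetric click pattern statistics: use mirrored trial instead
        tm = make_trial(1, left=(0.2, 0.4), right=(0.1, 0.3))
        p = AccumulatorParams(lam=0.0, sigma2_a=1.0, sigma2_s=0.2, bound=3.0,
                              phi=0.6, tau_phi=0.1)
        pa = choice_likelihood(t, p, 0.0)
        pb = choice_likelihood(tm, p, 0.0)
        assert pa + pb == pytest.approx(1.0, abs=1e-3)

    def test_no_clicks_zero_noise_diffusion_only_symmetric(self):
        t = make_trial(1)
        p = AccumulatorParams(lam=0.0, sigma2_a=1.0, bound=2.0)
        assert choice_likelihood(t, p, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_bias_beyond_support_forces_choice(self):
        t = make_trial(1, right=(0.1, 0.2, 0.3))
        p = AccumulatorParams(sigma2_a=1.0, bound=2.0, bias=2.5)
        assert choice_likelihood(t, p, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_initial_state(self, click_fixture):
        trials, _ = click_fixture
        p = AccumulatorParams(lam=0.0, sigma2_a=2.0, sigma2_s=0.2, bound=2.5,
                              phi=0.4, tau_phi=0.1)
        for t in trials[:2]:
            ps = [choice_likelihood(t, p, I) for I in np.linspace(-2.0, 2.0, 7)]
            assert np.all(np.diff(ps) > 0)

    def test_deterministic_counting_limit(self):
        """phi=1, sigma_s=0, sigma_a=0, lam=0: choice is the sign of the
        signed click sum plus I (grid commensurate with unit clicks)."""
        # dx = 2B/n = 0.1 so unit clicks land exactly on bin centers
        grid = FPGrid(bound=10.05, n_bins=201, dt=0.01)
        p = AccumulatorParams(lam=0, sigma2_a=0, sigma2_s=0, bound=10.05, phi=1.0)
        cases = [
            ((0.1, 0.2), (0.15,), -0.5),   # sum = -1, I = -0.5 -> L
            ((0.1,), (0.15, 0.2), 0.5),    # sum = +1, I = +0.5 -> R
            ((0.1, 0.2), (0.15, 0.3), 0.3),  # sum = 0, I = 0.3 -> R
        ]
        for L, R, I in cases:
            t = make_trial(1, left=L, right=R)
            want = 1.0 if (len(R) - len(L) + I) > 0 else 0.0
            assert choice_likelihood(t, p, I, grid) == pytest.approx(want, abs=1e-9)

    def test_complementarity_of_choice_probability(self, click_fixture):
        trials, Is = click_fixture
        p = AccumulatorParams(lam=-0.2, sigma2_a=2.0, sigma2_s=0.2, bound=2.5,
                              phi=0.4, tau_phi=0.1, bias=0.1)
        for t, I in zip(trials[:3], Is[:3]):
            res = fokker_planck_evolve(t, p, I)
            p_R = choice_likelihood(t, p, I)
            frac_below = np.clip((p.bias - res.grid.edges[:-1]) / res.grid.dx, 0, 1)
            p_L = res.P_final[0] + res.P_final[1:-1] @ frac_below
            assert p_R + p_L == pytest.approx(1.0, abs=1e-10)


class TestFirstPassage:
    def test_pure_drift_concentrates_at_crossing_time(self):
        p = AccumulatorParams(lam=0, sigma2_a=1e-4, bound=1.0, drift=2.0)
        t = make_trial(1, duration=2.0)
        fp = first_passage_density(t, p, I=0.0)
        t_hat = (fp.t * fp.mass_upper).sum() / fp.mass_upper.sum()
        assert t_hat == pytest.approx(0.5, abs=0.02)  # (B - I)/drift
        assert fp.mass_upper.sum() > 0.999

    def test_survivor_plus_absorbed_is_one(self):
        p = AccumulatorParams(lam=0, sigma2_a=0.5, bound=2.0)
        fp = first_passage_density(make_trial(1, duration=1.0), p, I=0.5)
        assert fp.total == pytest.approx(1.0, abs=1e-10)


class TestBatchedEngine:
    def test_matches_per_trial_solver_exactly(self, click_fixture):
        trials, Is = click_fixture
        p = AccumulatorParams(lam=-0.3, sigma2_a=2.0, sigma2_s=0.3, bound=2.5,
                              phi=0.4, tau_phi=0.1, bias=0.05)
        prep = PreparedSession.from_table(SessionTable(tuple(trials)), dt=0.01)
        pb = choice_probs_batched(prep, p, np.asarray(Is), n_bins=51)
        grid = FPGrid(bound=2.5, n_bins=51, dt=0.01)
        pp = [choice_likelihood(t, p, I, grid) for t, I in zip(trials, Is)]
        np.testing.assert_allclose(pb, pp, atol=1e-12)

    def test_variable_durations_freeze_finished_trials(self, rng):
        trials = [
            random_click_trial(1, rng, duration=0.3),
            random_click_trial(2, rng, duration=0.8),
        ]
        p = AccumulatorParams(lam=0.0, sigma2_a=2.0, sigma2_s=0.2, bound=2.5,
                              phi=0.4, tau_phi=0.1)
        prep = PreparedSession.from_table(SessionTable(tuple(trials)), dt=0.01)
        pb = choice_probs_batched(prep, p, np.zeros(2), n_bins=51)
        grid = FPGrid(bound=2.5, n_bins=51, dt=0.01)
        pp = [choice_likelihood(t, p, 0.0, grid) for t in trials]
        np.testing.assert_allclose(pb, pp, atol=1e-12)
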