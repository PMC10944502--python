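"""PD controller, super bolus, IOB safety loop, and closed-loop wiring."""

import numpy as np
import pytest

from tests.conftest import StubModel, constant_stub

from glucogan.controller import (
    ControllerConfig,
    ControllerState,
    compute_iob,
    exponential_iob,
    pd_action,
    reference_conditioning,
    run_closed_loop,
    super_bolus,
)
from glucogan.generation import LatentConfig
from glucogan.records import SAMPLES_PER_DAY


class TestIOB:
    def test_empty_history_is_zero(self):
        assert compute_iob([], dia=300.0) == 0.0

    def test_half_life_of_linear_decay(self):
        # a 2 U bolus aged dia/2 contributes 1 U
        assert compute_iob([2.0], dia=300.0, step_min=150.0) == pytest.approx(1.0)

    def test_bounded_by_recent_doses(self):
        rng = np.random.default_rng(0)
        history = rng.uniform(0, 2, 100).tolist()
        iob = compute_iob(history, dia=300.0)
        recent = sum(history[-60:])  # doses younger than dia at 5-min steps
        assert 0.0 <= iob <= recent

    def test_negative_doses_rejected(self):
        with pytest.raises(ValueError):
            compute_iob([-1.0], dia=300.0)

    def test_exponential_variant_decays(self):
        assert exponential_iob([2.0], dia=300.0, step_min=60.0) == pytest.approx(
            2.0 * np.exp(-1.0)
        )


class TestReferenceConditioning:
    def test_inactive_below_bound(self):
        assert reference_conditioning(120.0, 3.0, 6.0, 20.0) == 120.0

    def test_proportional_above_bound(self):
        assert reference_conditioning(120.0, 7.0, 6.0, 20.0) == 140.0

    def test_monotone_in_iob(self):
        refs = [reference_conditioning(120.0, iob, 6.0, 20.0)
                for iob in np.linspace(0, 12, 25)]
        assert all(a <= b for a, b in zip(refs, refs[1:]))


class TestSuperBolus:
    def test_meal_plus_basal_case(self):
        cfg = ControllerConfig(icr=10.0)
        assert super_bolus(60.0, cfg, cfg.g_ref, basal_next60=1.0) == 7.0

    def test_correction_case(self):
        cfg = ControllerConfig(icr=10.0, cf=50.0)
        assert super_bolus(60.0, cfg, cfg.g_ref + 50.0, basal_next60=0.0) == 7.0

    def test_no_meal_reduces_to_basal(self):
        cfg = ControllerConfig()
        assert super_bolus(0.0, cfg, cfg.g_ref, basal_next60=0.9) == 0.9

    def test_no_negative_correction_below_target(self):
        cfg = ControllerConfig(icr=10.0)
        assert super_bolus(0.0, cfg, cfg.g_ref - 80.0, basal_next60=0.0) == 0.0

    def test_negative_meal_rejected(self):
        with pytest.raises(ValueError):
            super_bolus(-1.0, ControllerConfig(), 120.0, 0.0)


class TestPDAction:
    def test_equilibrium_delivers_basal(self):
        cfg = ControllerConfig()
        state = ControllerState(prev_cgm=cfg.g_ref, gref_adjusted=cfg.g_ref)
        assert pd_action(state, cfg.g_ref, cfg, u_basal=1.0 / 12) == 1.0 / 12

    def test_hand_arithmetic_positive_error(self):
        cfg = ControllerConfig(k_p=0.001)
        state = ControllerState(prev_cgm=220.0, gref_adjusted=120.0)
        # k_p * 5 min * 100 mg/dL + 0.05 U basal = 0.55 U
        assert pd_action(state, 220.0, cfg, u_basal=0.05) == pytest.approx(0.55)

    def test_never_negative_on_falling_glucose(self):
        cfg = ControllerConfig()
        state = ControllerState(prev_cgm=200.0, gref_adjusted=120.0)
        assert pd_action(state, 125.0, cfg, u_basal=0.0) == 0.0

    def test_first_step_uses_zero_derivative(self):
        cfg = ControllerConfig(k_p=0.001)
        state = ControllerState(prev_cgm=None, gref_adjusted=120.0)
        assert pd_action(state, 170.0, cfg, u_basal=0.0) == pytest.approx(0.25)


class TestClosedLoop:
    def test_persistent_hyperglycemia_drives_insulin_above_basal(self):
        """A stub stuck at 150 mg/dL with target 120 must receive more than
        basal at every step (safety loop off so gating never intervenes)."""
        cfg = ControllerConfig(g_ref=120.0, safety_loop=False)
        model = constant_stub(150.0)
        _, log = run_closed_loop(
            model, np.zeros(SAMPLES_PER_DAY),
            np.array([""] * SAMPLES_PER_DAY, dtype=object),
            cfg, days=1, lat=LatentConfig(d_z=4), init_bg=150.0,
            return_log=True,
        )
        basal_step = 1.0 / 12
        assert np.all(log.dose_U.to_numpy() > basal_step)

    def test_equilibrium_stub_receives_exactly_basal(self):
        cfg = ControllerConfig(g_ref=120.0)
        model = constant_stub(120.0)
        _, log = run_closed_loop(
            model, np.zeros(SAMPLES_PER_DAY),
            np.array([""] * SAMPLES_PER_DAY, dtype=object),
            cfg, days=1, lat=LatentConfig(d_z=4), init_bg=120.0,
            return_log=True,
        )
        np.testing.assert_allclose(log.dose_U.to_numpy(), 1.0 / 12)

    def test_iob_bound_holds_over_random_stub_runs(self):
        """Over 50 random closed-loop runs, IOB never exceeds the bound by
        more than one step's dose."""
        rng = np.random.default_rng(0)
        cfg = ControllerConfig(g_ref=120.0, iob_max=4.0)
        violations = 0
        for run in range(50):
            level = rng.uniform(90.0, 320.0)
            jitter = rng.uniform(0.0, 30.0)
            seed = int(rng.integers(2**31))

            def window_fn(pi, ra, Z, level=level, jitter=jitter, seed=seed):
                wrng = np.random.default_rng(seed)
                return level + wrng.normal(0, jitter, (len(pi), 18))

            meals = np.zeros(SAMPLES_PER_DAY)
            labels = np.array([""] * SAMPLES_PER_DAY, dtype=object)
            for slot in rng.choice(SAMPLES_PER_DAY, 3, replace=False):
                meals[slot] = rng.uniform(20, 90)
                labels[slot] = "lunch"
            _, log = run_closed_loop(
                StubModel(window_fn), meals, labels, cfg, days=1,
                lat=LatentConfig(d_z=4, seed=run), return_log=True,
            )
            max_step_dose = log.dose_U.max()
            if (log.iob > cfg.iob_max + max_step_dose + 1e-9).any():
                violations += 1
        assert violations == 0

    def test_safety_loop_removes_iob_excursions(self):
        """Enabling the safety loop eliminates IOB excursions above the
        bound (up to one-step overshoot) present without it."""
        meals = np.zeros(SAMPLES_PER_DAY)
        labels = np.array([""] * SAMPLES_PER_DAY, dtype=object)
        model = constant_stub(300.0)  # relentless hyperglycemia
        cfg_off = ControllerConfig(g_ref=120.0, iob_max=3.0, safety_loop=False)
        cfg_on = ControllerConfig(g_ref=120.0, iob_max=3.0, safety_loop=True)
        _, log_off = run_closed_loop(model, meals, labels, cfg_off, 1,
                                     LatentConfig(d_z=4), return_log=True)
        _, log_on = run_closed_loop(model, meals, labels, cfg_on, 1,
                                    LatentConfig(d_z=4), return_log=True)
        one_step = log_on.dose_U.max()
        assert (log_off.iob > cfg_off.iob_max + one_step).any()
        assert not (log_on.iob > cfg_on.iob_max + one_step).any()

    def test_delivered_insulin_never_negative(self):
        model = constant_stub(80.0)  # below target the whole time
        rec = run_closed_loop(
            model, np.zeros(SAMPLES_PER_DAY),
            np.array([""] * SAMPLES_PER_DAY, dtype=object),
            ControllerConfig(), days=1, lat=LatentConfig(d_z=4),
        )
        assert np.all(rec.boluses >= 0)
        assert np.all(rec.basal >= 0)

    def test_super_bolus_suspends_basal(self):
        cfg = ControllerConfig(g_ref=120.0)
        meals = np.zeros(SAMPLES_PER_DAY)
        labels = np.array([""] * SAMPLES_PER_DAY, dtype=object)
        meals[100] = 60.0
        labels[100] = "lunch"
        _, log = run_closed_loop(
            constant_stub(120.0), meals, labels, cfg, 1,
            LatentConfig(d_z=4), init_bg=120.0, return_log=True,
        )
        assert log.basal_suspended.iloc[101:113].all()
        assert log.super_bolus.iloc[100] > 0

    def test_closed_loop_improves_time_in_range_on_responsive_stub(self):
        """Directional check: against an insulin-responsive stub, the
        closed loop spends at least as much time in 70-180 mg/dL as an
        open-loop constant-basal run with the same meals."""
        from glucogan.validation import glycemic_outcomes

        from glucogan.preprocessing import SignalNormalizer

        norms = {
            "pi": SignalNormalizer.from_range(0.0, 40.0),
            "ra": SignalNormalizer.from_range(0.0, 4.0),
            "bg": SignalNormalizer.from_range(0.0, 400.0),
        }

        def window_fn(pi, ra, Z):
            pi_raw = norms["pi"].inverse_transform(pi)
            ra_raw = norms["ra"].inverse_transform(ra)
            bg = 190.0 - 6.0 * (pi_raw - 14.0) + 40.0 * ra_raw
            return np.tile(
                norms["bg"].transform(np.clip(bg, 40.0, 400.0))[:, None],
                (1, 18),
            )

        model = StubModel(window_fn, normalizers=norms)
        meals = np.zeros(2 * SAMPLES_PER_DAY)
        labels = np.array([""] * len(meals), dtype=object)
        for slot in (90, 160, 240, 378, 448, 528):
            meals[slot] = 60.0
            labels[slot] = "lunch"

        closed = run_closed_loop(
            model, meals, labels, ControllerConfig(g_ref=120.0), days=2,
            lat=LatentConfig(d_z=4),
        )
        # open loop: basal only through the same model
        from glucogan.generation import generate_trace
        from glucogan.preprocessing import carbs_to_ra, insulin_to_plasma

        pi_open = insulin_to_plasma(np.full(len(meals), 1.0), np.zeros(len(meals)))
        open_bg = generate_trace(
            model,
            pi_open,
            carbs_to_ra(meals, labels),
            LatentConfig(d_z=4),
        )
        tir_closed = glycemic_outcomes(closed.bg).pct_70_180
        tir_open = glycemic_outcomes(np.clip(open_bg, 20, 600)).pct_70_180
        assert tir_closed >= tir_open
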