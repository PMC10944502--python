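"""Closed-loop insulin therapy: PD feedback with super bolus and an
insulin-on-board (IOB) safety loop, wired to a generative glucose model.

The inner loop is a proportional-derivative controller on the CGM error::

    u_c = max(0, k_p * dt * [(CGM - GrefS) + tau_d * dCGM/dt] + u_basal + u_b)

with the error defined as CGM minus the (adjusted) reference so that glucose
above target drives insulin delivery up, the derivative estimated by a
backward difference over the 5-minute step, and delivery clamped at zero
(insulin cannot be removed).  ``u_b`` is the super bolus at meal
announcements: carb-counted dose plus the upcoming 60 minutes of basal
(which is then suspended from delivery) plus a correction term clamped at
zero below target.

The outer safety loop bounds IOB: the glucose reference is raised in
proportion to the IOB excess (reference conditioning) and insulin delivery
is ceased entirely while IOB exceeds its bound, so IOB can overshoot the
bound by at most one step's dose.

In closed loop the controller's delivered insulin passes through the insulin
PK chain to produce PI, which (with the meal-derived RA) conditions the
generative model; only windows generated from inputs at or before ``t``
contribute to the CGM value at ``t+1`` (causal prefix of the recurrence
averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .generation import LatentConfig, draw_latents
from .preprocessing import PKParams, carbs_to_ra
from .records import BG_CLAMP, SAMPLES_PER_DAY, SAMPLING_PERIOD_MIN, PatientRecord


@dataclass(frozen=True)
class ControllerConfig:
    """PD gains, therapy parameters and safety-loop constants."""

    k_p: float = 0.001        # U/min per mg/dL
    tau_d: float = 30.0       # min
    g_ref: float = 120.0      # mg/dL
    icr: float = 10.0         # g/U  (the "insulin to CHO ratio")
    cf: float = 40.0          # mg/dL per U
    iob_max: float = 6.0      # U
    dia: float = 300.0        # min, insulin action duration for IOB decay
    k_sm: float = 20.0        # mg/dL per U of IOB excess (reference conditioning)
    safety_loop: bool = True
    step_min: float = SAMPLING_PERIOD_MIN

    def __post_init__(self):
        if min(self.k_p, self.tau_d, self.icr, self.cf, self.iob_max, self.dia) <= 0:
            raise ValueError("controller gains and bounds must be positive")
        if not 90 <= self.g_ref <= 160:
            raise ValueError("g_ref must lie in [90, 160] mg/dL")


@dataclass
class ControllerState:
    """Evolving controller memory between steps."""

    prev_cgm: float | None = None
    dose_history: list[float] = field(default_factory=list)  # U per step
    gref_adjusted: float = 0.0
    basal_suspended_steps: int = 0


def compute_iob(history, dia: float, step_min: float = SAMPLING_PERIOD_MIN) -> float:
    """Insulin on board with linear decay over ``dia`` minutes.

    ``history`` holds U delivered per past step, most recent last; a dose of
    age ``a`` contributes ``dose * max(0, 1 - a/dia)``.
    """
    if dia <= 0:
        raise ValueError("dia must be positive")
    history = np.asarray(history, float)
    if history.size == 0:
        return 0.0
    if np.any(history < 0):
        raise ValueError("dose history must be non-negative")
    ages = step_min * np.arange(len(history), 0, -1)
    return float(np.sum(history * np.clip(1.0 - ages / dia, 0.0, None)))


def exponential_iob(history, dia: float, step_min: float = SAMPLING_PERIOD_MIN) -> float:
    """Alternative IOB with exponential decay (time constant dia/5)."""
    if dia <= 0:
        raise ValueError("dia must be positive")
    history = np.asarray(history, float)
    if history.size == 0:
        return 0.0
    if np.any(history < 0):
        raise ValueError("dose history must be non-negative")
    ages = step_min * np.arange(len(history), 0, -1)
    return float(np.sum(history * np.exp(-5.0 * ages / dia)))


def reference_conditioning(g_ref: float, iob: float, iob_max: float,
                           k_sm: float) -> float:
    """Raise the glucose reference in proportion to the IOB excess."""
    return g_ref + k_sm * max(0.0, iob - iob_max)


def super_bolus(meal_g: float, cfg: ControllerConfig, cgm: float,
                basal_next60: float, gref_adjusted: float | None = None) -> float:
    """Meal super bolus: carb dose + upcoming 60-min basal + correction.

    The contributed basal must be suspended from delivery by the caller
    (``run_closed_loop`` suspends the following 60 min of basal).
    """
    if meal_g < 0:
        raise ValueError("meal grams must be non-negative")
    gref = cfg.g_ref if gref_adjusted is None else gref_adjusted
    return meal_g / cfg.icr + basal_next60 + max(0.0, cgm - gref) / cfg.cf


def pd_action(state: ControllerState, cgm: float, cfg: ControllerConfig,
              u_basal: float, u_b: float = 0.0) -> float:
    """PD insulin dose for one step (U), clamped at zero.

    ``u_basal`` is the basal insulin for this step in U; the first call uses
    a zero derivative.
    """
    gref_s = state.gref_adjusted if state.gref_adjusted else cfg.g_ref
    error = cgm - gref_s
    if state.prev_cgm is None:
        derivative = 0.0
    else:
        derivative = (cgm - state.prev_cgm) / cfg.step_min
    u_c = cfg.k_p * cfg.step_min * (error + cfg.tau_d * derivative) + u_basal + u_b
    return max(0.0, u_c)


def run_closed_loop(model, meals: np.ndarray, meal_labels: np.ndarray,
                    cfg: ControllerConfig, days: int, lat: LatentConfig,
                    basal_rate: float = 1.0, init_bg: float = 140.0,
                    pk: PKParams = PKParams(), weight: float = 70.0,
                    return_log: bool = False):
    """Simulate closed-loop therapy against a generative glucose model.

    Parameters
    ----------
    model : object with ``normalizers``, ``shift`` and ``generate_windows``
        A trained :class:`~glucogan.gan.GanModel` or a stub.
    meals, meal_labels : 5-min-grid series of meal grams and classes
        (carbohydrate inputs are taken from the real cohort).
    basal_rate : patient's basal profile, U/h (flat).
    init_bg : CGM value used before the first generated sample exists.

    Returns
    -------
    PatientRecord of the closed-loop run (generated BG, delivered insulin),
    plus a per-step controller log DataFrame when ``return_log``.
    """
    n = days * SAMPLES_PER_DAY
    meals = np.asarray(meals, float)[:n]
    meal_labels = np.asarray(meal_labels, dtype=object)[:n]
    if len(meals) < n:
        raise ValueError("meal series shorter than the requested horizon")
    shift = model.shift
    dt = cfg.step_min
    steps_per_hour = int(round(60.0 / dt))

    ra = carbs_to_ra(meals, meal_labels)
    ra_n = model.normalizers["ra"].transform(ra)
    Z = draw_latents(n, lat)

    # PK chain state for incremental PI computation
    tm, vi, ke = pk.t_max_I, pk.V_I * weight, pk.k_e
    u_basal_ss = basal_rate * 1000.0 / 60.0
    pk_state = np.array([u_basal_ss * tm, u_basal_ss * tm, u_basal_ss / (ke * vi)])

    def pk_step(state_vec, dose_u, rate_uh):
        u = rate_uh * 1000.0 / 60.0
        s = state_vec.copy()
        s[0] += dose_u * 1000.0

        def deriv(v):
            s1, s2, i = v
            return np.array([u - s1 / tm, (s1 - s2) / tm, s2 / (tm * vi) - ke * i])

        for _ in range(int(dt)):
            k1 = deriv(s)
            k2 = deriv(s + 0.5 * k1)
            k3 = deriv(s + 0.5 * k2)
            k4 = deriv(s + k3)
            s = s + (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        return s

    state = ControllerState(gref_adjusted=cfg.g_ref)
    sums = np.zeros(n + shift)
    counts = np.zeros(n + shift)
    bg = np.empty(n)
    delivered = np.zeros(n)
    basal_series = np.zeros(n)
    log_rows = []
    bg_norm = model.normalizers["bg"]
    pi_norm = model.normalizers["pi"]
    basal_per_step = basal_rate * dt / 60.0  # U per step

    for t in range(n):
        bg[t] = (
            float(bg_norm.inverse_transform(sums[t - 1] / counts[t - 1]))
            if t >= 1 and counts[t - 1] > 0
            else init_bg
        )
        bg[t] = float(np.clip(bg[t], *BG_CLAMP))

        iob = compute_iob(state.dose_history, cfg.dia, dt)
        if cfg.safety_loop:
            state.gref_adjusted = reference_conditioning(
                cfg.g_ref, iob, cfg.iob_max, cfg.k_sm
            )
        else:
            state.gref_adjusted = cfg.g_ref

        suspended = state.basal_suspended_steps > 0
        u_basal_step = 0.0 if suspended else basal_per_step
        if suspended:
            state.basal_suspended_steps -= 1

        u_b = 0.0
        if meals[t] > 0:
            basal_next60 = basal_rate * 1.0  # flat profile: 1 h of basal, U
            u_b = super_bolus(meals[t], cfg, bg[t], basal_next60,
                              state.gref_adjusted)
            state.basal_suspended_steps = steps_per_hour
            u_basal_step = 0.0

        dose = pd_action(state, bg[t], cfg, u_basal_step, u_b)
        if cfg.safety_loop and iob > cfg.iob_max:
            dose = 0.0  # cease insulin infusion while IOB exceeds its bound
        state.prev_cgm = bg[t]
        state.dose_history.append(dose)
        basal_contrib = min(dose, u_basal_step)
        delivered[t] = dose - basal_contrib  # bolus component, U
        basal_series[t] = basal_contrib * 60.0 / dt  # back to U/h

        # insulin -> plasma over this step; PI at t conditions the window
        pi_t = pk_state[2]
        pk_state = pk_step(pk_state, dose, 0.0)
        window = model.generate_windows(
            np.atleast_1d(pi_norm.transform(pi_t)),
            ra_n[t : t + 1],
            Z[t : t + 1],
        )[0]
        sums[t : t + shift] += window
        counts[t : t + shift] += 1.0

        if return_log:
            log_rows.append(
                {
                    "step": t, "cgm": bg[t], "iob": iob,
                    "gref_adjusted": state.gref_adjusted, "super_bolus": u_b,
                    "dose_U": dose, "basal_suspended": suspended,
                }
            )

    record = PatientRecord(
        patient_id="closed-loop",
        bg=np.clip(bg, *BG_CLAMP),
        basal=basal_series,
        boluses=delivered,
        meals=meals,
        meal_labels=meal_labels,
    )
    if return_log:
        return record, pd.DataFrame(log_rows)
    return record
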