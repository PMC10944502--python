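"""Synthetic T1D cohort generator.

Emulates multi-week basal-bolus therapy records — the statistical structure a
conditional glucose GAN is trained on — using a Bergman-minimal-style
glucose ODE driven by the same insulin PK chain and meal-absorption kernels
the preprocessing stage uses::

    X' = -p2 * X + p2 * SI * (I - Ib)          remote insulin action, 1/min
    G' = -(SG + X) * G + SG * Gb + RA_g / V_g  plasma glucose, mg/dL/min

where ``I`` is plasma insulin (mU/L) from the two-compartment subcutaneous
chain, ``Ib`` its steady state under the patient's prescribed basal rate,
``RA_g`` the meal rate of appearance converted to mg/min and ``V_g`` the
glucose distribution volume (dL).  A behavioral layer adds jittered meal
times, per-class meal sizes, carb-counted boluses with multiplicative dose
errors, and additive CGM noise.  BG is clamped to the CGM device range
[20, 600] mg/dL.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .preprocessing import DEFAULT_MEAL_LIBRARY, G_PER_MMOL, PKParams, ra_kernel
from .records import BG_CLAMP, SAMPLES_PER_DAY, SAMPLING_PERIOD_MIN, PatientRecord

#: glucose distribution volume, dL per kg body weight
VG_DL_PER_KG = 1.6

#: correction boluses target this glucose, mg/dL
CORRECTION_TARGET = 120.0

#: (mean minute-of-day, grams mean, grams sd) per meal class
MEAL_SCHEDULE = {
    "breakfast": (8 * 60, 50.0, 10.0),
    "lunch": (13 * 60, 70.0, 15.0),
    "dinner": (20 * 60, 80.0, 15.0),
    "snack": (17 * 60, 25.0, 8.0),
}
SNACK_PROBABILITY = 0.5
MEAL_JITTER_MIN = 30.0

#: sd of the day-to-day log-normal insulin-sensitivity fluctuation; real T1D
#: glycaemia varies far more day to day than a fixed-parameter ODE does
SI_DAY_SD = 0.3

#: circadian (within-day sinusoidal) modulation depths of insulin
#: sensitivity and of the endogenous glucose set point (dawn-phenomenon-like)
CIRCADIAN_SI = 0.3
CIRCADIAN_GB = 0.12

#: sd of the log-normal carbohydrate-counting error patients make when
#: dosing for a meal (the announced grams are correct; the bolus is not)
CARB_COUNT_SD = 0.25

#: probability a snack goes unbolused
SNACK_SKIP_BOLUS_PROB = 0.5


@dataclass(frozen=True)
class PatientParams:
    """Physiological and behavioral parameters of one virtual patient."""

    insulin_sensitivity: float  # SI, 1/min per mU/L of excess plasma insulin
    glucose_effectiveness: float  # SG, 1/min
    p2: float  # remote-action decay, 1/min
    basal_glucose: float  # Gb, mg/dL
    basal_insulin_rate: float  # U/h
    icr: float  # insulin-to-carb ratio, g/U
    cf: float  # correction factor, mg/dL per U
    body_weight: float  # kg
    cgm_noise_sd: float  # mg/dL
    dose_error_sd: float  # fractional (multiplicative log-normal)

    def __post_init__(self):
        positive = (
            self.insulin_sensitivity, self.glucose_effectiveness, self.p2,
            self.basal_glucose, self.basal_insulin_rate, self.icr, self.cf,
            self.body_weight,
        )
        if min(positive) <= 0:
            raise ValueError("rates and sensitivities must be strictly positive")
        if not 70 <= self.basal_glucose <= 180:
            raise ValueError("basal_glucose must lie in [70, 180] mg/dL")
        if not 4 <= self.icr <= 30:
            raise ValueError("icr must lie in [4, 30] g/U")
        if not 10 <= self.cf <= 100:
            raise ValueError("cf must lie in [10, 100] mg/dL per U")
        if self.cgm_noise_sd < 0 or self.dose_error_sd < 0:
            raise ValueError("noise parameters must be non-negative")


def sample_patient_params(seed: int) -> PatientParams:
    """Draw one patient's parameters from documented population ranges.

    Log-normal draws for strictly-positive scale parameters, uniform draws for
    bounded ones; deterministic for a fixed seed.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    return PatientParams(
        insulin_sensitivity=float(rng.lognormal(np.log(6e-4), 0.25)),
        glucose_effectiveness=float(rng.uniform(0.008, 0.015)),
        p2=float(rng.uniform(0.015, 0.03)),
        basal_glucose=float(rng.uniform(120.0, 165.0)),
        basal_insulin_rate=float(rng.lognormal(np.log(1.0), 0.2)),
        icr=float(rng.uniform(8.0, 15.0)),
        cf=float(rng.uniform(30.0, 60.0)),
        body_weight=float(np.clip(rng.normal(71.3, 12.0), 45.0, 120.0)),
        cgm_noise_sd=float(rng.uniform(2.0, 8.0)),
        dose_error_sd=float(rng.uniform(0.05, 0.2)),
    )


def _meal_plan(days: int, rng: np.random.Generator):
    """Draw (minute, grams, label) meal events for ``days`` days."""
    events = []
    for day in range(days):
        for label, (minute, g_mean, g_sd) in MEAL_SCHEDULE.items():
            if label == "snack" and rng.random() > SNACK_PROBABILITY:
                continue
            t = day * 1440 + minute + rng.uniform(-MEAL_JITTER_MIN, MEAL_JITTER_MIN)
            grams = max(10.0, rng.normal(g_mean, g_sd))
            events.append((float(t), grams, label))
    events.sort()
    return events


def simulate_patient(
    params: PatientParams,
    days: int,
    seed: int,
    basal_scale: float = 1.0,
    bolus_scale: float = 1.0,
    noise: bool = True,
) -> PatientRecord:
    """Simulate one patient's open-loop basal-bolus record on the 5-min grid.

    ``basal_scale`` / ``bolus_scale`` rescale *delivered* insulin relative to
    the prescription (the plasma-insulin reference ``Ib`` stays at the
    prescribed basal), which is how over-/under-dosing experiments are run.
    With ``noise=False`` both CGM noise and dose errors are switched off and
    the simulation is fully deterministic given ``params``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    n = days * SAMPLES_PER_DAY
    n_min = days * 1440
    pk = PKParams()
    tm, vi, ke = pk.t_max_I, pk.V_I * params.body_weight, pk.k_e
    v_g = VG_DL_PER_KG * params.body_weight  # dL

    meal_events = _meal_plan(days, rng)
    # rate of appearance on the 1-min internal grid, mg/min
    t_min_grid = np.arange(n_min, dtype=float)
    ra_mg = np.zeros(n_min)
    for t_meal, grams, label in meal_events:
        kernel = DEFAULT_MEAL_LIBRARY[label]
        ra_mg += ra_kernel(t_min_grid - t_meal, grams, kernel) * G_PER_MMOL * 1000.0

    u_basal = params.basal_insulin_rate * basal_scale * 1000.0 / 60.0  # mU/min
    i_b = (params.basal_insulin_rate * 1000.0 / 60.0) / (ke * vi)  # mU/L
    si, sg, p2, gb = (
        params.insulin_sensitivity, params.glucose_effectiveness,
        params.p2, params.basal_glucose,
    )

    # state: S1, S2 (mU), I (mU/L), X (1/min), G (mg/dL); PK chain starts at
    # the basal steady state (the patient has been on basal indefinitely)
    state = np.array([u_basal * tm, u_basal * tm, i_b, 0.0, gb])

    # day-to-day and circadian insulin-sensitivity fluctuation plus a
    # dawn-phenomenon-like set-point modulation (part of the noise model)
    if noise:
        si_daily = si * np.exp(rng.normal(0.0, SI_DAY_SD, size=days))
        circ_phase = float(rng.uniform(0.0, 2 * np.pi))
        circ_si, circ_gb = CIRCADIAN_SI, CIRCADIAN_GB
    else:
        si_daily = np.full(days, si)
        circ_phase, circ_si, circ_gb = 0.0, 0.0, 0.0

    def deriv(s, u, ra, si_t, gb_t):
        s1, s2, i, x, g = s
        return np.array([
            u - s1 / tm,
            (s1 - s2) / tm,
            s2 / (tm * vi) - ke * i,
            -p2 * x + p2 * si_t * (i - i_b),
            -(sg + x) * g + sg * gb_t + ra / v_g,
        ])

    # boluses: carb-counted + correction at meal times, snapped to the 5-min
    # grid, with multiplicative dose error
    meal_bolus_min = {}
    for t_meal, grams, label in meal_events:
        snapped = int(round(t_meal / SAMPLING_PERIOD_MIN)) * SAMPLING_PERIOD_MIN
        snapped = min(snapped, n_min - 1)
        meal_bolus_min[snapped] = (grams, label)

    bg = np.empty(n)
    basal_series = np.full(n, params.basal_insulin_rate * basal_scale)
    bolus_series = np.zeros(n)
    meal_series = np.zeros(n)
    label_series = np.array([""] * n, dtype=object)

    for minute in range(n_min):
        if minute % SAMPLING_PERIOD_MIN == 0:
            k = minute // SAMPLING_PERIOD_MIN
            bg[k] = state[4]
            if minute in meal_bolus_min:
                grams, label = meal_bolus_min[minute]
                meal_series[k] = grams
                label_series[k] = label
                counted = grams
                if noise:
                    counted *= float(np.exp(rng.normal(0.0, CARB_COUNT_SD)))
                    if label == "snack" and rng.random() < SNACK_SKIP_BOLUS_PROB:
                        counted = 0.0
                dose = counted / params.icr + max(0.0, state[4] - CORRECTION_TARGET) / params.cf
                dose *= bolus_scale
                if noise and params.dose_error_sd > 0:
                    dose *= float(np.exp(rng.normal(0.0, params.dose_error_sd)))
                bolus_series[k] = dose
                state[0] += dose * 1000.0  # impulse into S1, mU
        ra = ra_mg[minute]
        tod = (minute % 1440) / 1440.0 * 2 * np.pi
        si_t = si_daily[minute // 1440] * (1 + circ_si * np.sin(tod + circ_phase))
        gb_t = gb * (1 + circ_gb * np.sin(tod + circ_phase + 1.0))
        k1 = deriv(state, u_basal, ra, si_t, gb_t)
        k2 = deriv(state + 0.5 * k1, u_basal, ra, si_t, gb_t)
        k3 = deriv(state + 0.5 * k2, u_basal, ra, si_t, gb_t)
        k4 = deriv(state + k3, u_basal, ra, si_t, gb_t)
        state = state + (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        state[4] = np.clip(state[4], *BG_CLAMP)

    if noise and params.cgm_noise_sd > 0:
        bg = bg + rng.normal(0.0, params.cgm_noise_sd, size=n)
    bg = np.clip(bg, *BG_CLAMP)

    return PatientRecord(
        patient_id=f"sim-{seed}",
        bg=bg,
        basal=basal_series,
        boluses=bolus_series,
        meals=meal_series,
        meal_labels=label_series,
    )


def make_cohort(n_patients: int, days: int, seed: int) -> list[PatientRecord]:
    """Generate an independent cohort of virtual patients.

    Per-patient seeds are derived from the master seed with
    ``numpy.random.SeedSequence.spawn``, so patients share no random stream and
    the cohort is reproducible for a fixed master seed.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2 (leave-one-out needs >= 2)")
    if days < 1:
        raise ValueError("days must be >= 1")
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(2 * n_patients)
    ]
    records = []
    for i in range(n_patients):
        params = sample_patient_params(child_seeds[2 * i])
        rec = simulate_patient(params, days, child_seeds[2 * i + 1])
        rec.patient_id = f"P{i + 1:02d}"
        records.append(rec)
    return records


def cohort_manifest(records: list[PatientRecord], seed: int) -> str:
    """JSON manifest of a cohort: ids, derived seeds, parameter values.

    The per-patient seeds and parameters are re-derived from the master seed
    (the same deterministic derivation ``make_cohort`` uses).
    """
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(2 * len(records))
    ]
    patients = []
    for i, r in enumerate(records):
        patients.append(
            {
                "patient_id": r.patient_id,
                "n_samples": len(r),
                "params_seed": child_seeds[2 * i],
                "sim_seed": child_seeds[2 * i + 1],
                "params": asdict(sample_patient_params(child_seeds[2 * i])),
            }
        )
    return json.dumps(
        {
            "master_seed": seed,
            "sampling_period_min": SAMPLING_PERIOD_MIN,
            "patients": patients,
        },
        indent=2,
    )
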