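"""Conditional-input construction: insulin pharmacokinetics, meal absorption,
min-max normalization, and causal shifted training pairs.

Delivered insulin (basal U/h + boluses U) is converted to a plasma-insulin
approximation PI (mU/L) through a linear two-compartment subcutaneous
absorption chain feeding a single plasma pool::

    S1' = u - S1 / t_max_I
    S2' = S1 / t_max_I - S2 / t_max_I
    I'  = S2 / (t_max_I * V_I * BW) - k_e * I

with ``u`` in mU/min, ``S1, S2`` in mU, ``I`` in mU/L.  Meal carbohydrates
(grams) become a rate of appearance RA (mmol/min) through a two-compartment
gamma-shaped kernel ``f * D_mmol * t * exp(-t/t_max_G) / t_max_G**2`` whose
time-to-peak ``t_max_G`` depends on the meal class (a parametric surrogate for
published mixed-meal absorption libraries).

Training pairs are built by the causal shift: one (PI, RA) sample at grid
index ``t`` is mapped to the ``shift`` strictly-future BG samples
``bg[t+1 .. t+shift]`` (90 min = 18 samples at the 5-minute grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler

from .records import SAMPLING_PERIOD_MIN, PatientRecord

#: grams of glucose per mmol
G_PER_MMOL = 0.180

#: default causal shift: 90 min at 5-min sampling
DEFAULT_SHIFT = 18


@dataclass(frozen=True)
class PKParams:
    """Hovorka-style subcutaneous insulin pharmacokinetic constants."""

    t_max_I: float = 55.0  # min, absorption time constant
    V_I: float = 0.12      # L/kg, distribution volume
    k_e: float = 0.138     # 1/min, plasma elimination

    def __post_init__(self):
        if min(self.t_max_I, self.V_I, self.k_e) <= 0:
            raise ValueError("PK parameters must be strictly positive")


@dataclass(frozen=True)
class MealKernel:
    """Absorption kernel for one meal class.

    ``t_max_G`` is the time-to-peak (min) of the rate of appearance and ``f``
    the carbohydrate bioavailability fraction.
    """

    meal_class: str
    t_max_G: float
    f: float = 0.9

    def __post_init__(self):
        if self.t_max_G <= 0:
            raise ValueError("t_max_G must be positive")
        if not 0 < self.f <= 1:
            raise ValueError("bioavailability f must be in (0, 1]")


#: per-class time-to-peak defaults, min (parametric stand-in for a mixed-meal
#: library: larger, fattier meals absorb slower)
DEFAULT_MEAL_LIBRARY = {
    "breakfast": MealKernel("breakfast", 40.0),
    "lunch": MealKernel("lunch", 55.0),
    "dinner": MealKernel("dinner", 70.0),
    "snack": MealKernel("snack", 30.0),
}


def insulin_to_plasma(
    basal: np.ndarray,
    boluses: np.ndarray,
    pk: PKParams = PKParams(),
    weight: float = 70.0,
    dt: float = SAMPLING_PERIOD_MIN,
    substep: float = 1.0,
    return_states: bool = False,
) -> np.ndarray:
    """Convert delivered insulin into a plasma-insulin approximation (mU/L).

    Parameters
    ----------
    basal : array, U/h on the ``dt``-minute grid (held constant over each step).
    boluses : array, U; each bolus enters compartment S1 as an impulse at the
        start of its grid step.
    weight : body weight, kg.
    substep : internal RK4 step, min.
    return_states : if True also return (S1, S2, cumulative plasma appearance)
        sampled on the grid, for mass-balance checks.

    Returns
    -------
    PI : array of plasma insulin (mU/L), same length as the inputs, where
        ``PI[i]`` is the concentration at the *start* of grid step ``i``
        (before that step's bolus has had any effect).
    """
    basal = np.asarray(basal, float)
    boluses = np.asarray(boluses, float)
    if basal.shape != boluses.shape:
        raise ValueError("basal and bolus series must have equal length")
    n = len(basal)
    n_sub = int(round(dt / substep))
    tm, vi, ke = pk.t_max_I, pk.V_I * weight, pk.k_e

    def deriv(state, u):
        s1, s2, i, a = state
        app = s2 / tm
        return np.array([u - s1 / tm, s1 / tm - app, app / vi - ke * i, app])

    state = np.zeros(4)  # S1 (mU), S2 (mU), I (mU/L), cumulative appearance (mU)
    pi = np.empty(n)
    s1_out = np.empty(n)
    s2_out = np.empty(n)
    app_out = np.empty(n)
    for i in range(n):
        pi[i], s1_out[i], s2_out[i], app_out[i] = (
            state[2], state[0], state[1], state[3],
        )
        u = basal[i] * 1000.0 / 60.0  # U/h -> mU/min
        state[0] += boluses[i] * 1000.0  # bolus impulse, U -> mU
        for _ in range(n_sub):
            k1 = deriv(state, u)
            k2 = deriv(state + 0.5 * substep * k1, u)
            k3 = deriv(state + 0.5 * substep * k2, u)
            k4 = deriv(state + substep * k3, u)
            state = state + (substep / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if return_states:
        return pi, s1_out, s2_out, app_out
    return pi


def ra_kernel(t_min: np.ndarray, grams: float, kernel: MealKernel) -> np.ndarray:
    """Rate of appearance (mmol/min) of one meal at times ``t_min`` after it."""
    t = np.asarray(t_min, float)
    d_mmol = grams / G_PER_MMOL
    out = kernel.f * d_mmol * t * np.exp(-t / kernel.t_max_G) / kernel.t_max_G**2
    return np.where(t >= 0, out, 0.0)


def carbs_to_ra(
    meals: np.ndarray,
    labels: np.ndarray,
    library: dict[str, MealKernel] | None = None,
    dt: float = SAMPLING_PERIOD_MIN,
) -> np.ndarray:
    """Convert a sparse meal series (g) into a rate-of-appearance series.

    Contributions of overlapping meals are summed (the kernels are linear).

    Returns
    -------
    RA : array, mmol/min, same length as ``meals``.
    """
    meals = np.asarray(meals, float)
    labels = np.asarray(labels, dtype=object)
    if library is None:
        library = DEFAULT_MEAL_LIBRARY
    n = len(meals)
    t_grid = np.arange(n) * dt
    ra = np.zeros(n)
    for i in np.nonzero(meals > 0)[0]:
        label = str(labels[i])
        if label not in library:
            raise KeyError(f"unknown meal label {label!r} at index {int(i)}")
        ra += ra_kernel(t_grid - t_grid[i], meals[i], library[label])
    return ra


class DegenerateSignalError(ValueError):
    """Raised when a signal is constant and min-max scaling is undefined."""


class SignalNormalizer(TransformerMixin, BaseEstimator):
    """Min-max normalizer for one signal (thin wrapper over MinMaxScaler).

    Maps the training range onto [0, 1]; values outside the training range map
    outside [0, 1] (no clipping), and ``inverse_transform`` is exact.
    """

    def fit(self, X, y=None):
        x = np.asarray(X, float).reshape(-1, 1)
        if x.size < 2 or np.ptp(x) == 0:
            raise DegenerateSignalError(
                "signal is constant (or has <2 values); min-max scale undefined"
            )
        self._scaler = MinMaxScaler(clip=False).fit(x)
        self.data_min_ = float(self._scaler.data_min_[0])
        self.data_max_ = float(self._scaler.data_max_[0])
        return self

    def transform(self, X):
        x = np.asarray(X, float)
        return self._scaler.transform(x.reshape(-1, 1)).reshape(x.shape)

    def inverse_transform(self, X):
        x = np.asarray(X, float)
        return self._scaler.inverse_transform(x.reshape(-1, 1)).reshape(x.shape)

    @classmethod
    def from_range(cls, lo: float, hi: float) -> "SignalNormalizer":
        """Build a fitted normalizer from an explicit [lo, hi] range."""
        return cls().fit(np.array([lo, hi]))


def fit_normalizer(series: np.ndarray) -> SignalNormalizer:
    """Fit a min-max normalizer on one training signal."""
    return SignalNormalizer().fit(series)


@dataclass
class PairedSample:
    """One causal training pair: a (PI, RA) input and its future BG window."""

    pi: float
    ra: float
    bg_window: np.ndarray
    t_index: int

    def __post_init__(self):
        self.bg_window = np.asarray(self.bg_window, float)


def build_shifted_pairs(
    pi: np.ndarray,
    ra: np.ndarray,
    bg: np.ndarray,
    shift: int = DEFAULT_SHIFT,
) -> list[PairedSample]:
    """Map each (PI, RA) sample at index ``t`` to the BG window ``bg[t+1..t+shift]``.

    Returns ``N - shift`` pairs for series of length ``N`` (t = 0 .. N-shift-1);
    raises if no full strictly-future window exists.
    """
    pi, ra, bg = (np.asarray(a, float) for a in (pi, ra, bg))
    if not (len(pi) == len(ra) == len(bg)):
        raise ValueError("pi, ra, bg must have equal length")
    if shift < 1:
        raise ValueError("shift must be >= 1")
    n = len(bg)
    if n <= shift:
        raise ValueError(f"need more than shift={shift} samples, got {n}")
    return [
        PairedSample(pi=pi[t], ra=ra[t], bg_window=bg[t + 1 : t + 1 + shift], t_index=t)
        for t in range(n - shift)
    ]


def pairs_to_arrays(pairs: list[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs into sklearn-shaped arrays X=(n, 2) [pi, ra], y=(n, shift)."""
    X = np.array([[p.pi, p.ra] for p in pairs], float)
    y = np.stack([p.bg_window for p in pairs]).astype(float)
    return X, y


def record_to_conditions(
    record: PatientRecord,
    pk: PKParams = PKParams(),
    weight: float = 70.0,
    library: dict[str, MealKernel] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Derive the raw (PI, RA) condition series for one patient record."""
    pi = insulin_to_plasma(record.basal, record.boluses, pk, weight)
    ra = carbs_to_ra(record.meals, record.meal_labels, library)
    return pi, ra
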