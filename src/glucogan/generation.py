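"""Synthesis of full-length BG traces by recurrence averaging.

Each input (PI, RA) sample at grid index ``t`` yields a generated window
covering indices ``t+1 .. t+shift``; successive windows are shifted by one
sample, and the value reported at grid index ``tau`` is the arithmetic mean
of every window entry covering ``tau`` (up to ``shift`` contributors in the
interior, fewer near the start).  Averaging happens in normalized space and
the result is inverted through the BG normalizer — a linear map, so the
order of averaging and de-normalization is immaterial.

The trace is defined on grid indices ``1 .. N`` for inputs of length ``N``
(index ``tau`` has ``min(tau, shift)`` contributors), so an N-sample input
series yields an N-sample trace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocessing import record_to_conditions
from .records import BG_CLAMP, SAMPLES_PER_DAY, PatientRecord


@dataclass(frozen=True)
class LatentConfig:
    """Latent-space policy for a generation run.

    One standard-normal draw of dimension ``d_z`` per input window, scaled by
    ``magnitude``; larger magnitudes push the generator further from its
    conditional mode and raise the coefficient of variation of the output.
    The same configuration is used for every patient of a run.
    """

    d_z: int = 32
    magnitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("latent magnitude must be >= 0")


def scale_latent(z: np.ndarray, m: float) -> np.ndarray:
    """Elementwise latent magnitude scaling (vector arithmetic in Z)."""
    if m < 0:
        raise ValueError("latent magnitude must be >= 0")
    return m * np.asarray(z, float)


def draw_latents(n: int, lat: LatentConfig) -> np.ndarray:
    """The run's latent draws: one scaled N(0, I) vector per input window."""
    rng = np.random.default_rng(lat.seed)
    return scale_latent(rng.standard_normal((n, lat.d_z)), lat.magnitude)


def accumulate_windows(windows: np.ndarray, shift: int, n: int) -> np.ndarray:
    """Overlap-average generated windows onto the output grid.

    ``windows[t]`` covers output indices ``t+1 .. t+shift``; returns the
    length-``n`` trace over indices 1..n where each index is the mean of its
    covering window entries.
    """
    sums = np.zeros(n + shift)
    counts = np.zeros(n + shift)
    for t in range(windows.shape[0]):
        sums[t : t + shift] += windows[t]
        counts[t : t + shift] += 1.0
    return sums[:n] / counts[:n]


def generate_trace(model, pi: np.ndarray, ra: np.ndarray,
                   lat: LatentConfig) -> np.ndarray:
    """Generate a de-normalized BG trace (mg/dL) from raw PI/RA series.

    ``model`` must expose ``normalizers`` (pi/ra/bg), ``shift`` and
    ``generate_windows(pi_norm, ra_norm, Z)``; both the trained
    :class:`~glucogan.gan.GanModel` and test stubs satisfy this.
    """
    pi = np.asarray(pi, float)
    ra = np.asarray(ra, float)
    if pi.shape != ra.shape:
        raise ValueError("pi and ra must have equal length")
    n = len(pi)
    shift = model.shift
    if n <= shift:
        raise ValueError(f"need more than shift={shift} input samples, got {n}")
    pi_n = model.normalizers["pi"].transform(pi)
    ra_n = model.normalizers["ra"].transform(ra)
    Z = draw_latents(n, lat)
    windows = model.generate_windows(pi_n, ra_n, Z)
    trace_n = accumulate_windows(np.asarray(windows, float), shift, n)
    return model.normalizers["bg"].inverse_transform(trace_n)


def tile_conditions(pi: np.ndarray, ra: np.ndarray, n_target: int,
                    samples_per_day: int = SAMPLES_PER_DAY):
    """Day-wise tile (PI, RA) inputs up to ``n_target`` samples.

    Records shorter than the requested horizon are extended by repeating
    whole days from the start of the record; returns the tiled series and a
    flag array marking tiled (non-original) samples.
    """
    n = len(pi)
    if n >= n_target:
        return pi[:n_target], ra[:n_target], np.zeros(n_target, bool)
    n_days = max(1, n // samples_per_day)
    base = n_days * samples_per_day
    reps = int(np.ceil((n_target - n) / base))
    pi_out = np.concatenate([pi] + [pi[:base]] * reps)[:n_target]
    ra_out = np.concatenate([ra] + [ra[:base]] * reps)[:n_target]
    tiled = np.arange(n_target) >= n
    return pi_out, ra_out, tiled


def synthesize_cohort(models: dict, cohort: list[PatientRecord], weeks: float,
                      lat: LatentConfig) -> list[PatientRecord]:
    """Generate one virtual patient per real patient.

    Each virtual patient uses the real patient's own PI/RA inputs and the
    leave-one-out model that excluded them; the same latent configuration is
    applied to every patient (per-patient streams are split from
    ``lat.seed`` deterministically).
    """
    n_target = int(round(weeks * 7 * SAMPLES_PER_DAY))
    virtual = []
    for k, rec in enumerate(cohort):
        if rec.patient_id not in models:
            raise KeyError(f"no model for patient {rec.patient_id!r}")
        model = models[rec.patient_id]
        pi, ra = record_to_conditions(rec)
        pi, ra, _ = tile_conditions(pi, ra, n_target)
        pat_lat = replace(
            lat,
            seed=int(
                np.random.SeedSequence([lat.seed, k]).generate_state(1)[0]
                % (2**31)
            ),
        )
        bg = np.clip(generate_trace(model, pi, ra, pat_lat), *BG_CLAMP)
        basal, _, _ = tile_conditions(rec.basal, rec.basal, n_target)
        boluses, meals, _ = tile_conditions(rec.boluses, rec.meals, n_target)
        labels, _, _ = tile_conditions(rec.meal_labels, rec.meal_labels, n_target)
        virtual.append(
            PatientRecord(
                patient_id=f"virtual-{rec.patient_id}",
                bg=bg,
                basal=basal,
                boluses=boluses,
                meals=meals,
                meal_labels=labels,
                start=rec.start,
            )
        )
    return virtual
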