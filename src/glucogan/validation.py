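"""Evaluation battery for generated cohorts.

Three families of checks, mirroring how data-driven glucose simulators are
validated against the cohorts they emulate:

* **Statistical similarity** — per-patient glycaemic outcomes (time in the
  standard BG bands, mean, STD, CV), cohort median (IQR) summaries, and a
  paired two-sided Wilcoxon signed-rank test per metric; a metric "qualifies"
  when p >= 0.05 (no detectable difference between real and generated).
* **Causality** — Granger tests (does adding lagged insulin/carb inputs
  improve an autoregression of BG?) and convergent cross mapping (simplex
  projection on a delay embedding; a relationship is causal when the
  cross-map skill is high *and* converges with library size).
* **Distribution distance** — Jensen-Shannon divergence between BG
  histograms with base-2 logarithms, so 0 means identical and 1 disjoint.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon
from sklearn.neighbors import NearestNeighbors
import statsmodels.api as sm

from .records import PatientRecord

GLYCEMIC_METRICS = (
    "pct_below54", "pct_54_69", "pct_70_140", "pct_70_180",
    "pct_180_250", "pct_above250", "mean", "std", "cv",
)

#: shared histogram grid for BG distribution comparison, mg/dL
JSD_BINS = np.arange(20.0, 600.0 + 2.0, 2.0)


@dataclass(frozen=True)
class GlycemicOutcomes:
    """Standard glycaemic outcomes of one BG trace.

    Band conventions: <54; [54, 70); [70, 180]; (180, 250]; >250 (a disjoint
    partition), plus the tight sub-band [70, 140] of the main target range.
    """

    pct_below54: float
    pct_54_69: float
    pct_70_140: float
    pct_70_180: float
    pct_180_250: float
    pct_above250: float
    mean: float
    std: float
    cv: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def glycemic_outcomes(bg: np.ndarray) -> GlycemicOutcomes:
    """Band percentages, mean, STD and CV (= 100*STD/mean) of a BG trace."""
    bg = np.asarray(bg, float)
    if bg.size == 0:
        raise ValueError("empty BG series")
    if np.any(bg <= 0):
        raise ValueError("BG must be strictly positive")
    n = bg.size
    pct = lambda mask: 100.0 * np.count_nonzero(mask) / n
    mean = float(bg.mean())
    std = float(bg.std(ddof=0))
    return GlycemicOutcomes(
        pct_below54=pct(bg < 54),
        pct_54_69=pct((bg >= 54) & (bg < 70)),
        pct_70_140=pct((bg >= 70) & (bg <= 140)),
        pct_70_180=pct((bg >= 70) & (bg <= 180)),
        pct_180_250=pct((bg > 180) & (bg <= 250)),
        pct_above250=pct(bg > 250),
        mean=mean,
        std=std,
        cv=100.0 * std / mean,
    )


def outcomes_frame(outcomes: list[GlycemicOutcomes]) -> pd.DataFrame:
    return pd.DataFrame([o.as_dict() for o in outcomes])


def cohort_summary(outcomes: list[GlycemicOutcomes]) -> pd.DataFrame:
    """Median and IQR per metric, with a "median (Q1-Q3)" display column."""
    if not outcomes:
        raise ValueError("empty cohort")
    frame = outcomes_frame(outcomes)
    rows = []
    for metric in GLYCEMIC_METRICS:
        vals = frame[metric].to_numpy()
        med = float(np.median(vals))
        q1, q3 = (float(q) for q in np.percentile(vals, [25, 75]))
        rows.append(
            {
                "metric": metric, "median": med, "q1": q1, "q3": q3,
                "display": f"{med:.2f} ({q1:.2f}–{q3:.2f})",
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def wilcoxon_compare(real: list[GlycemicOutcomes],
                     generated: list[GlycemicOutcomes]) -> pd.Series:
    """Two-sided paired Wilcoxon signed-rank p-value per glycaemic metric.

    Pairs are matched by position (patient order).  Exact null distribution
    for n <= 25 without ties or zeros, normal approximation otherwise; if all
    paired differences are zero the statistic is undefined and p = 1 is
    reported by convention (no detectable difference).
    """
    if len(real) != len(generated):
        raise ValueError("cohorts must be paired (equal size)")
    rf, gf = outcomes_frame(real), outcomes_frame(generated)
    pvals = {}
    for metric in GLYCEMIC_METRICS:
        d = rf[metric].to_numpy() - gf[metric].to_numpy()
        d = d[d != 0]
        if d.size == 0:
            pvals[metric] = 1.0
            continue
        exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
        res = stats.wilcoxon(d, alternative="two-sided",
                             method="exact" if exact else "approx")
        pvals[metric] = float(res.pvalue)
    return pd.Series(pvals, name="p_value")


# ---------------------------------------------------------------------------
# causality
# ---------------------------------------------------------------------------


def granger_test(cause: np.ndarray, effect: np.ndarray, max_lag: int = 18) -> float:
    """Granger causality p-value: does lagged ``cause`` improve an AR of ``effect``?

    The lag order is chosen by BIC of the unrestricted (augmented) regression
    over 1..max_lag, then the restricted (effect-lags-only) and unrestricted
    models are compared with the standard sum-of-squares F-test.
    """
    cause = np.asarray(cause, float)
    effect = np.asarray(effect, float)
    if cause.shape != effect.shape:
        raise ValueError("series must have equal length")
    n = len(cause)
    if n < 5 * max_lag + 10:
        raise ValueError("series too short for the requested lag order")
    if np.ptp(cause) == 0 or np.ptp(effect) == 0:
        raise ValueError("degenerate (constant) regressor")

    def lagmat(x, p, n_obs):
        return np.column_stack([x[max_lag - k : max_lag - k + n_obs] for k in range(1, p + 1)])

    n_obs = n - max_lag  # common sample across candidate lags
    y = effect[max_lag:]
    best = None
    for p in range(1, max_lag + 1):
        X_u = sm.add_constant(
            np.column_stack([lagmat(effect, p, n_obs), lagmat(cause, p, n_obs)])
        )
        fit_u = sm.OLS(y, X_u).fit()
        if best is None or fit_u.bic < best[0]:
            best = (fit_u.bic, p, fit_u)
    _, p, fit_u = best
    X_r = sm.add_constant(lagmat(effect, p, n_obs))
    fit_r = sm.OLS(y, X_r).fit()
    _, p_value, _ = fit_u.compare_f_test(fit_r)
    return float(p_value)


@dataclass
class CCMResult:
    """Convergent cross mapping outcome for one directed pair."""

    library_sizes: np.ndarray
    skills: np.ndarray       # mean cross-map skill per library size
    convergent: bool
    E: int
    tau: int

    @property
    def skill(self) -> float:
        """Cross-map skill at the largest library."""
        return float(self.skills[-1])


def _delay_embed(x: np.ndarray, E: int, tau: int) -> np.ndarray:
    n = len(x) - (E - 1) * tau
    return np.column_stack([x[(E - 1 - j) * tau : (E - 1 - j) * tau + n]
                            for j in range(E)])


def ccm(cause: np.ndarray, effect: np.ndarray, E: int = 3, tau: int = 1,
        library_sizes=None, n_boot: int = 50, seed: int = 0,
        convergence_margin: float = 0.1,
        tail_slope_tol: float = 5e-4) -> CCMResult:
    """Convergent cross mapping: can ``effect``'s attractor reconstruct ``cause``?

    The effect series is delay-embedded; for each library size L, ``n_boot``
    random L-point libraries are drawn, each point outside the library is
    simplex-projected (its E+1 nearest library neighbours, exponentially
    weighted by distance) to predict the concurrent cause value, and the
    skill is the Pearson correlation between predicted and true cause.
    Convergence holds when skill grows by at least ``convergence_margin``
    from the smallest to the largest library and the tail slope (skill per
    added library point over the last three sizes) is near zero.
    """
    cause = np.asarray(cause, float)
    effect = np.asarray(effect, float)
    if cause.shape != effect.shape:
        raise ValueError("series must have equal length")
    emb = _delay_embed(effect, E, tau)
    target = cause[(E - 1) * tau :]
    n_pts = emb.shape[0]
    if library_sizes is None:
        top = (n_pts // 100) * 100
        library_sizes = list(range(100, top + 1, 100))
    library_sizes = sorted(int(l) for l in library_sizes)
    if not library_sizes or library_sizes[-1] > n_pts:
        raise ValueError("series too short for the requested library sizes")

    rng = np.random.default_rng(seed)
    skills = np.empty(len(library_sizes))
    for li, L in enumerate(library_sizes):
        k = min(E + 2, L)
        rhos = []
        for _ in range(n_boot):
            lib = rng.choice(n_pts, size=L, replace=False)
            nn = NearestNeighbors(n_neighbors=k).fit(emb[lib])
            dist, idx = nn.kneighbors(emb)
            # exclude self-matches (a point finding its own library entry)
            self_match = (dist == 0) & (lib[idx] == np.arange(n_pts)[:, None])
            dist = np.where(self_match, np.inf, dist)
            order = np.argsort(dist, axis=1, kind="stable")[:, : E + 1]
            rows = np.arange(n_pts)[:, None]
            d = dist[rows, order]
            j = idx[rows, order]
            d = np.where(np.isinf(d), np.nan, d)
            d0 = d[:, :1]
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(d0 > 0, np.exp(-d / d0), (d == 0).astype(float))
            w = np.nan_to_num(w)
            wsum = w.sum(axis=1, keepdims=True)
            wsum[wsum == 0] = 1.0
            w /= wsum
            preds = np.nansum(w * target[lib[j]], axis=1)
            if np.ptp(preds) == 0 or np.ptp(target) == 0:
                rhos.append(0.0)
            else:
                rhos.append(float(np.corrcoef(preds, target)[0, 1]))
        skills[li] = np.mean(rhos)

    convergent = bool(
        skills[-1] - skills[0] >= convergence_margin
        and (
            len(library_sizes) < 3
            or abs(
                np.polyfit(library_sizes[-3:], skills[-3:], 1)[0]
            ) <= tail_slope_tol
        )
    )
    return CCMResult(
        library_sizes=np.array(library_sizes), skills=skills,
        convergent=convergent, E=E, tau=tau,
    )


# ---------------------------------------------------------------------------
# distribution distance
# ---------------------------------------------------------------------------


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with base-2 logarithms (in [0, 1]).

    ``p`` and ``q`` must be probability vectors on a shared support grid.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a support grid")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6) or not np.isclose(q.sum(), 1.0, atol=1e-6):
        raise ValueError("distributions must each sum to 1")
    return float(jensenshannon(p, q, base=2) ** 2)


def bg_histogram(bg: np.ndarray, bins: np.ndarray = JSD_BINS) -> np.ndarray:
    """Normalized BG histogram on the shared 2 mg/dL grid."""
    counts, _ = np.histogram(np.clip(bg, bins[0], bins[-1]), bins=bins)
    return counts / counts.sum()


def jsd_traces(bg_a: np.ndarray, bg_b: np.ndarray) -> float:
    """JSD between the BG histograms of two traces."""
    return jsd(bg_histogram(bg_a), bg_histogram(bg_b))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    summary_real: pd.DataFrame
    summary_generated: pd.DataFrame
    wilcoxon_p: pd.Series
    causality: pd.DataFrame  # per patient: granger p's, ccm skills, jsd

    def qualified(self, alpha: float = 0.05) -> pd.Series:
        """Which metrics show no detectable real-vs-generated difference."""
        return self.wilcoxon_p >= alpha

    def to_json_dict(self) -> dict:
        return {
            "summary_real": self.summary_real.reset_index().to_dict("records"),
            "summary_generated": self.summary_generated.reset_index().to_dict("records"),
            "wilcoxon_p": self.wilcoxon_p.to_dict(),
            "causality": self.causality.to_dict("records"),
        }

    def to_markdown(self) -> str:
        lines = ["# Validation report", "", "## Glycaemic outcomes (median, IQR)", ""]
        table = pd.DataFrame(
            {
                "real": self.summary_real["display"],
                "generated": self.summary_generated["display"],
                "wilcoxon_p": self.wilcoxon_p.round(4),
            }
        )
        lines += [table.to_markdown(), "", "## Per-patient causality and distance", ""]
        lines += [self.causality.round(4).to_markdown(index=False), ""]
        return "\n".join(lines)


def validation_report(real_cohort: list[PatientRecord],
                      generated_cohort: list[PatientRecord],
                      ccm_kwargs: dict | None = None,
                      granger_max_lag: int = 18,
                      ccm_subsample: int | None = 2000) -> ValidationReport:
    """Assemble the full statistical / causal / distributional comparison.

    Granger and CCM are run per generated patient on (insulin bolus series ->
    BG) and (meal series -> BG); CCM uses at most ``ccm_subsample`` samples
    per patient to bound the neighbour searches.
    """
    if len(real_cohort) != len(generated_cohort):
        raise ValueError("real and generated cohorts must be paired")
    # fewer bootstrap libraries than the single-pair default keeps the
    # per-patient report tractable; override via ccm_kwargs
    ccm_kwargs = {"n_boot": 10, **(ccm_kwargs or {})}
    real_out = [glycemic_outcomes(r.bg) for r in real_cohort]
    gen_out = [glycemic_outcomes(r.bg) for r in generated_cohort]
    rows = []
    for real, gen in zip(real_cohort, generated_cohort):
        n = min(len(gen), len(real))
        insulin = gen.boluses[:n] + gen.basal[:n] / 12.0  # U per 5-min step
        carbs = gen.meals[:n]
        bg = gen.bg[:n]
        m = min(n, ccm_subsample) if ccm_subsample else n
        row = {"patient_id": real.patient_id}
        try:
            row["granger_p_insulin"] = granger_test(insulin, bg, granger_max_lag)
        except ValueError:
            row["granger_p_insulin"] = np.nan
        try:
            row["granger_p_carbs"] = granger_test(carbs, bg, granger_max_lag)
        except ValueError:
            row["granger_p_carbs"] = np.nan
        for name, cause in (("insulin", insulin), ("carbs", carbs)):
            try:
                res = ccm(cause[:m], bg[:m], **ccm_kwargs)
                row[f"ccm_skill_{name}"] = res.skill
                row[f"ccm_convergent_{name}"] = res.convergent
            except ValueError:
                row[f"ccm_skill_{name}"] = np.nan
                row[f"ccm_convergent_{name}"] = False
        row["jsd"] = jsd_traces(real.bg, gen.bg)
        rows.append(row)
    return ValidationReport(
        summary_real=cohort_summary(real_out),
        summary_generated=cohort_summary(gen_out),
        wilcoxon_p=wilcoxon_compare(real_out, gen_out),
        causality=pd.DataFrame(rows),
    )
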