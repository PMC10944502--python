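# Methods

## The model in one paragraph

`glucogan` simulates people with type 1 diabetes (T1D) by *learning* the
glucose–insulin relationship from data instead of prescribing it with a
physiological model. A conditional sequence-to-sequence Wasserstein GAN maps
one sample of plasma-insulin approximation (PI, mU/L) and one sample of
carbohydrate rate of appearance (RA, mmol/min) — plus a normal latent vector
z — to the 18 blood-glucose (BG) samples that *follow* that input over the
next 90 minutes (18 × 5-min samples). Causality is baked into the training
data: each (PI, RA) pair at grid index *t* is paired with the strictly
future window `bg[t+1 .. t+18]`. At generation time the overlapping windows
produced by successive inputs are shifted by one sample and averaged
("recurrence averaging") to yield an arbitrarily long trace. The trained
model is wrapped in two therapy environments: open loop (replay a patient's
recorded insulin) and closed loop (a PD controller with super-bolus meal
dosing and an insulin-on-board safety loop feeds insulin back into the
model).

## Conditional inputs

Delivered insulin (basal U/h, boluses U) becomes PI through a linear
two-compartment subcutaneous chain with plasma elimination:

    S1' = u − S1/t_max_I,   S2' = (S1 − S2)/t_max_I,
    I'  = S2/(t_max_I · V_I · BW) − k_e · I

Defaults `t_max_I = 55 min`, `V_I = 0.12 L/kg`, `k_e = 0.138 /min` are the
standard published values for this pharmacokinetic family. The chain is
mass-conserving by construction; RK4 at a 1-minute internal step keeps the
cumulative-appearance error below 0.5 % (measured ~1e-13 relative).

Meal carbohydrates become RA through a gamma-shaped kernel
`f · D_mmol · t · exp(−t/t_max_G)/t_max_G²` (peak at `t_max_G`, integral
`f · D_mmol`, `D_mmol = grams/0.180`). The per-class times-to-peak
(breakfast 40, lunch 55, dinner 70, snack 30 min; bioavailability f = 0.9)
are a parametric surrogate for published mixed-meal absorption libraries,
which are not redistributable; only the qualitative class ordering (heavier,
later meals absorb slower) is carried over.

All three signals are min-max normalized to [0, 1] with scalers fitted on
the **training patients only** under leave-one-out (the held-out patient is
transformed with the fitted scaler; no leakage). Values outside the training
range map outside [0, 1] — no clipping — and constant signals raise an
explicit degenerate-signal error.

## Networks and training

The critic scores the concatenated signal `[PI, RA, bg-window]` (length 20)
through five 1-D convolution stages (channels 32-64-128-64-1, kernels
4/4/3/1/1, strides 2/2/1/1/1) collapsing to a scalar. The generator passes
`[PI, RA, z]` through a dense layer, reshapes to (8 channels × 18), and
applies four stride-1 transposed-convolution stages (channels 64-32-16-1,
kernel 3 with symmetric cropping) that preserve the 18-sample length. Layer
counts are fixed; widths are constructor arguments so tests can shrink them.

Training follows the weight-clipped WGAN recipe: critic loss
`mean(C(fake)) − mean(C(real))`, generator loss
`−mean(C(fake)) + λ·MSE(fake, real)`, RMSprop at lr 5e-5, clip c = 0.01,
5 critic updates (each followed by clipping) per generator update, batch
size 1, 50 epochs, pairs shuffled per epoch. λ defaults to 10 (the L2 term
keeps the conditional output anchored to the paired ground truth). Real
windows are labelled −1 and generated windows +1; the Wasserstein losses do
not consume the labels numerically, so they are retained as metadata of the
convention. The latent dimension defaults to 32 (values well under 100
suffice for this signal family). Everything is NumPy with hand-written
backpropagation — each backward pass is verified against central finite
differences in the test suite — so training is bit-reproducible for a fixed
seed on one machine.

Leave-one-out protocol: one model per patient, trained on all other
patients' pairs, tagged with the held-out id; generation for a patient
always uses the model that never saw them.

## Generation

One latent draw per input window (not per patient or per trace), all
patients of a run sharing the same latent configuration; per-patient streams
are split deterministically from the run seed. The trace is defined on grid
indices 1..N for N input samples; index τ averages its `min(τ, 18)`
covering window entries (no padding at the start). Averaging happens in
normalized space and is inverted afterwards — the normalizer is affine, so
the order is immaterial. Multiplying the latent draws by a magnitude m
modulates output variability; m = 0 gives the deterministic conditional
mode. Note that for barely-trained desk-scale models the CV-versus-m trend
can invert (large latents drive leaky-ReLU units into their low-gain
regime); the mechanism is therefore property-tested with an additive-latent
stub rather than asserted on a 2-epoch model.

## Closed loop

The inner loop is a PD law on the CGM error,

    u_c = max(0, k_p·Δt·[(CGM − GrefS) + τ_d·dCGM/dt] + u_basal + u_b)

with the error sign chosen so glucose above target drives insulin up, a
backward-difference derivative, and delivery clamped at zero. The meal
super bolus is `M/ICR + (next 60 min of basal) + max(0, CGM − GrefS)/CF`,
with the contributed basal suspended from delivery for the following hour.
(The printed form of the middle term in the source material is
dimensionally inconsistent — it multiplies mean basal by grams; the
standard super-bolus semantics above is implemented instead.)

The outer safety loop bounds insulin on board (IOB, linear decay over
`dia = 300 min`; exponential decay selectable): the reference is raised
proportionally to the IOB excess (`GrefS = Gref + k_sm·max(0, IOB − ĪOB)`,
a proportional stand-in for the cited sliding-mode conditioning law, whose
internals are not public) and insulin delivery is ceased entirely while IOB
exceeds the bound, so the bound can be overshot by at most one step's dose.
Defaults `k_p = 0.001 U/min per mg/dL`, `τ_d = 30 min`, `Gref = 120 mg/dL`,
`ĪOB = 6 U` are package choices; no reference values are published for this
configuration. Inside the loop the generative model is driven causally: the
CGM value at step t+1 is the average of windows generated from inputs at or
before t only.

## Synthetic cohort

Real T1D datasets of this kind are access-restricted, so the package ships
a generator that emulates their structure: a Bergman-minimal-style glucose
ODE (remote insulin action X, glucose G; RK4 at 1 min, reported at 5 min,
BG clamped to the CGM range 20–600 mg/dL) driven by the same PK chain and
meal kernels as the preprocessing stage, plus a behavioral layer — three
meals and an optional snack per day with ±30 min jitter, carb-counted
boluses with a correction term, log-normal carb-counting (sd 0.25) and
dose (sd 0.05–0.2) errors, unbolused snacks half the time, additive CGM
noise (2–8 mg/dL), day-to-day (sd 0.3) and circadian (±30 %)
insulin-sensitivity fluctuation with a dawn-phenomenon-like set-point
modulation (±12 %). Population parameters are drawn per patient from
documented log-normal/uniform ranges (e.g. ICR 8–15 g/U, CF 30–60 mg/dL/U,
basal glucose 120–165 mg/dL).

These defaults were calibrated once against the glycaemic statistics
clinical T1D cohorts report: the generator produces cohorts with median BG
~110–155 mg/dL, CV ~24–35 %, time-in-range (70–180) ~80–90 %, and occasional
level-2 hypoglycaemia. That is somewhat tighter than the restricted cohorts
the method was developed on (CV ~36–46 %, TIR ~50–66 %): exercise, stress,
illness and sensor artefacts are deliberately out of scope. Consequently,
passing tests show the pipeline learns and reproduces the *structure* of
basal-bolus therapy data, not that it matches any particular clinical
population.

## Validation battery

* **Glycaemic outcomes** — band percentages with edge conventions <54;
  [54, 70); [70, 180]; (180, 250]; >250 (a disjoint partition) plus the
  tight sub-band [70, 140]; mean, STD, CV = 100·STD/mean. Cohort summaries
  are medians with IQR; paired two-sided Wilcoxon signed-rank per metric
  (exact null for n ≤ 25 without ties, normal approximation above; all-zero
  differences report p = 1 by convention). A metric "qualifies" at p ≥ 0.05.
* **Granger causality** — restricted vs augmented OLS autoregressions,
  sum-of-squares F-test, lag order by BIC up to 18 (the causal horizon).
  Type-I error on white noise measures 5–6 % at α = 0.05.
* **Convergent cross mapping** — delay embedding of the effect (defaults
  E = 3, τ = 1), simplex projection with E+1 exponentially-weighted nearest
  neighbours, skill = Pearson correlation between reconstructed and true
  cause, averaged over bootstrap libraries in 100-sample increments;
  convergence requires both growth from the smallest to the largest library
  and a flat tail. On unidirectionally coupled logistic maps (coupling
  0.15) the causal direction converges to skill > 0.95 while the reverse
  stays below 0.15. At coupling ≳ 0.3 the driven map partially
  synchronises and the reverse skill rises — a known CCM regime, which is
  why the benchmark uses weak coupling.
* **Jensen–Shannon divergence** — base-2 logs on BG histograms with shared
  2 mg/dL bins over [20, 600], so 0 = identical and 1 = disjoint.

## Problem sizes and numerical choices

Desk-scale runs (tests and the acceptance script) use 2 patients × 7 days,
2 training epochs, 1 generated week and a 2-day closed loop — chosen as the
smallest configuration that exercises every pipeline stage end to end;
statistical similarity at this scale is reported, not asserted. The
reference protocol (50 epochs, 4 generated weeks, cohorts of 10–27
patients) is reached by changing configuration only. Ties in the CCM
neighbour search are broken by stable sort; Wilcoxon zero differences are
dropped before ranking; the first closed-loop step uses a zero derivative
and a configurable warm-up CGM value (default 140 mg/dL) before the first
generated sample exists.

## Known limitations

* The cohort generator omits exercise, stress, illness, menstrual-cycle
  effects and CGM dropouts/artefacts; its variability is below real cohorts'.
* A 2-epoch desk-scale model generates plausible but over-smooth traces
  (high time-in-range, JSD ~0.5 against its target patient).
* The critic/generator widths, λ, latent dimension and PD gains are
  package defaults, exposed in configuration, not reproductions of any
  published setting.
* CCM embedding parameters are defaults; no automatic embedding selection
  (e.g. false-nearest-neighbours) is performed.
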