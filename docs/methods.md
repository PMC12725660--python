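# Methods

## Model and units

The model couples blood glucose `G` (mg/dL), blood insulin `I` (ng/mL), a
transient insulin-independent glucose store `stG` (mg/dL-equivalent,
capacity `k7`), and cumulative uptake `AG`. Concentrations enter the
EGP-suppression denominator `1 + I + k8·G` as bare numbers in measurement
units; the rate constants absorb all unit conversions. This phenomenological
convention keeps the printed equations literal and puts every parameter on a
per-minute scale. `AG` counts glucose the moment it leaves the blood (flux 2
and flux 5, net of EGP); later consumption of the store (flux 6) moves mass
within the body and does not enter `AG`.

Infusion bookkeeping converts pump rates (µL/g/min of a 25% = 0.25 mg/µL
glucose solution) through body weight to mg/min and then through the
circulating blood volume (72 mL/kg, in dL) to the model's f(t) in mg/dL/min.
The infused volume is assumed not to change the blood volume — the same
simplification implicit in converting `AG` to mass with a fixed volume.
Because the model distributes glucose over blood volume only, absolute
infusion masses are smaller than whole-body clamp data would give; all
downstream checks are therefore about shapes and ratios, not absolute GIR.

## Initial conditions

`G(0)` and `I(0)` are estimated parameters, not assumed steady states: an
overnight-fasted mouse is not at the model's fixed point. The store starts
empty by default (`stg0_mode="fasted"`). This is a deliberate choice: if
`stG(0)` is placed at its conditional equilibrium for the fasting levels,
the ratio of store drain to store fill, `k6·I/(k5·G)`, is the same before
and during a clamp whenever `I(0)` sits on the insulin nullcline — in that
regime the early insulin-independent burst of uptake can never occur. An
emptied store after an overnight fast both matches the physiology and
produces the observed transient. `stg0_mode="conditional_ss"` is available
for steady-state analyses, and `basal_steady_state()` solves the full
three-balance fixed point for consistency tests.

## Reference parameter set and cohort generator

`REFERENCE_CD` (k1=3, k2=1e-2, k3=2.08e-4, k4=2.5e-2, k5=3e-4, k6=1e-3,
k7=600, k8=3e-3, G0=120, I0=0.5) describes a lean chow-fed mouse:

* fasting glucose 120 mg/dL, fasting insulin 0.5 ng/mL, insulin relaxation
  time 1/k4 = 40 min — slow enough that insulin (and with it the
  insulin-dependent infusion demand) keeps rising well past the mid-clamp
  dip, fast enough that the insulin asymptote `k3·G/k4` is reached within
  the record. The latter matters statistically: with a relaxation time
  comparable to the clamp length the asymptote is an extrapolation and the
  secretion constant k3 becomes unrecoverable at realistic insulin assay
  noise. Real mouse insulin clearance is faster still, so 40 min is
  conservative;
* at the clamp target (320 mg/dL) the store fills with time constant
  1/(k5·G) ≈ 10 min and saturates near 99% of `k7`, because its
  insulin-dependent drain (`k6·stG·I`) is weak. The sharp-saturation regime
  was chosen on two grounds: it reflects the interpretation of the store as
  concentration-equilibrating diffusion/GLUT2 transport, which stops when
  inside and outside concentrations meet; and identifiability profiling at
  the generator's measurement noise showed that when drain and fill are
  comparable, `k5`, `k6` and `k7` form a likelihood ridge that makes the
  store capacity unrecoverable, whereas in the saturating regime the early
  uptake burst pins `k7` directly.

The cohort generator draws each mouse's rate constants log-normally (ln-σ
0.15) around group medians, which are the reference values shifted by
age-trend multipliers for the four parameters that change with obesity
progression (k2 down to 0.25×, k3 up to 3×, k5 down to 0.4×, k7 up to 2× at
36 weeks of high-fat diet), with fasting glucose/insulin and body weights
drawn truncated-normally per group (fasting insulin rising from 0.5 to
4.5 ng/mL; body weight 27 g to 55 g). Group sizes of the full design are
13/13/16/13/10/10 (control then five HFD ages); priming rates are
0.15 µL/g/min for controls, 0.1 for young HFD, 0.13 for old HFD. Measurement
noise is multiplicative log-Gaussian, CV 5% for glucose and 10% for insulin
(conventional glucometer/ELISA figures); doses are recorded to 0.1 mg.
What the generator does *not* emulate: non-stationary measurement drift,
missed samples, catheter failures, within-mouse correlation of errors, and
any distribution volume beyond blood — so passing tests demonstrate
pipeline correctness under the stated error model, not robustness to every
artifact of real clamp data.

## Clamp controller

The experimental titration rule behind published clamps is never specified,
so the simulator uses a deterministic, seeded controller updated only at
the glucose measurement times: the commanded rate is a model-predictive
feedforward — the average net disposal over the upcoming interval with G
pinned at the target, obtained by integrating the insulin/store
sub-dynamics with a short fixed-step RK4 — plus an interval-normalized PI
correction (kp=0.6 dimensionless, ki=0.005), clamped at zero with integral
anti-windup. Priming runs at the protocol's initial rate until the target
(fasting + 200 mg/dL) is first reached at a measurement time. On the
reference mouse this holds the clamp within ~1% of target after attainment;
the fast-priming protocol (4 µL/g/min) massively overshoots, as expected
when the distribution volume is blood only, and is used solely for
qualitative ordering of time-to-target.

## Estimation

The objective sums squared residuals of three streams — G at the 29-point
clamp grid, I at the 14-point sampling grid, and AG(ti) reconstructed from
the recorded doses minus the change in circulating glucose mass. By default
each glucose and insulin residual is divided by its own observed value:
glucometer and ELISA errors are multiplicative, so relative residuals are
the maximum-likelihood weighting and, unlike a per-stream constant, do not
down-weight the precise low-insulin early samples that pin the secretion
parameters. AG residuals are divided by the stream's mean magnitude.
Per-stream mean/max constants and unnormalized residuals are selectable.
The recorded doses are replayed open-loop; the clamp feedback is never
simulated during fitting. Integration uses LSODA with the dose breakpoints
passed as critical points (rtol 1e-7 during the global search, 1e-8 in the
local stage; the finite-difference Jacobian needs the lower solver noise
floor, and the relative step is held at 1e-3 in log10 space for the same
reason).

The global stage is meta-evolutionary programming in log10 parameter space:
per-coordinate self-adaptive mutation scales with the conventional
τ = 1/√(2√n), τ′ = 1/√(2n) lognormal update, reflection at the box bounds,
(μ+μ) survivor selection by stochastic q-tournament (q=10) with the
incumbent best always retained. Default bounds span 4 decades around
physiological priors for the rate constants and ±20% of the first observed
values for G(0)/I(0) — except k1, k6 and k8, which get 2 decades. Those
three sit on structural near-degeneracies of clamp data (flux1 depends only
on the ratio k1/k8 once k8·G dominates its denominator, and k6·k7·I mimics
k2·G·I once the store has saturated), so unbounded they absorb each other's
and k2's signal; a one-decade leash either side of the prior is the
standard regularization-by-prior-knowledge an analyst would apply, and it
is what makes the fitted k2 group trends stable at realistic noise. The local stage is bounded trust-region least squares
from the best candidate; `fit_mouse` falls back to the global best if the
local stage ever fails to improve it, so refinement is non-worsening by
construction. Fits are pure functions of (record, config) including the
seed; results carry the seed and a config digest.

Defaults follow the conventional large-budget settings (population 200,
500 generations). The test suite and the acceptance script run documented
scaled-down budgets (population 24–32, 20–30 generations) — on this
problem the global stage only needs to land in the basin, and the local
stage is what sets the final accuracy; the scaled budgets recover the
identified parameters (k2, k3, k4, k5, k7) to ≪5% on noise-free data.

An identifiability report computes the residual Jacobian's singular values
and approximate CI half-widths at the optimum and flags parameters whose
relative half-width exceeds 100%; k1, k6 and k8 are weakly identified from
clamp data alone and should be interpreted with that caveat.

## Statistics

* Quartiles use linear interpolation of order statistics (numpy's default);
  the outlier fence is Q1 − 1.5·IQR / Q3 + 1.5·IQR, applied per group, and
  the rule degrades to a no-op with a warning below 4 values.
* Welch's t with Satterthwaite df; BH adjustment over all pairwise
  comparisons of one parameter (one family per parameter, matching
  per-panel star annotation); identical degenerate samples get p = 1 by
  convention. Stars at 0.05/0.01/0.001/0.0001.
* Williams' trend test uses the classical amalgamated suffix-mean statistic
  with pooled within-group variance. Published critical-value tables only
  cover equal group sizes, so tail probabilities come from a seeded
  Monte-Carlo null (default 1e5 replicates, cached per group-size
  signature) — exact up to simulation error at any design. Step-down starts
  at the highest group and stops at the first non-rejection, so rejections
  are always a contiguous suffix. Reported rows carry the seed and
  replicate count. Monte-Carlo p-values are accurate to ~1/√n_mc and are
  not meant to match any table to the third decimal.
* Spearman correlation uses average ranks; p-values are exact (full
  permutation enumeration) for n ≤ 9 and the t approximation otherwise;
  zero rank variance is reported as undefined (NaN) rather than guessed.

## Numerical choices and degenerate inputs

Simulation tolerances default to rtol 1e-8 / atol 1e-10 (halving them moves
clamp outputs by <1e-4 relative). Invalid candidate parameter vectors
during the global search return a 1e12 penalty instead of raising. Records
with all-zero doses and flat glucose fit to an essentially basal model.
Windows for flux decomposition are 10 min wide ending at 10/20/60/120/180
min, integrated trapezoidally on the dense solver grid with interpolated
endpoints. AUC windows follow each experiment's span ([0,10]+[10,180] for
clamps, [10,90] tail for IVGTT).

## Statistical power of the scaled-down pipeline

End-to-end checks run three groups (control, 18-week and 36-week high-fat
diet) of 8 mice — a deliberate reduction of the six-group, 75-mouse design
to keep the full cohort→fit→comparison loop to minutes. At this size the
monotone trends in insulin secretion (k3), glucose effectiveness (k5) and
store capacity (k7) are detected by Williams' test at the oldest group in
every replicate we have run. The insulin-sensitivity trend (k2) is the
weakest: per-mouse k2 carries roughly 50–100% multiplicative uncertainty
(the structural degeneracies above), so its top-step rejection has roughly
75–85% power per replicate — occasionally a replicate shows the correct
ordering of group means without reaching significance. With the full
design's group sizes the contrast is comfortably detected; at the reduced
size the k2 decision should be read as marginal by construction.

## Known limitations

Single glucose compartment (blood volume only) — absolute infusion masses
are not comparable to whole-body GIR data. No glucagon, catecholamine,
cortisol or FFA effects on EGP. Insulin secretion is linear in glucose, so
clamped insulin saturates at (k3/k4)·G with no explicit first-phase burst
machinery beyond the priming transient. The somatostatin-suppression
scenario is emulated by setting k3 ≈ 0 rather than modelled
pharmacologically. Mice are fitted independently; there is no hierarchical
pooling.
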