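# Methods

`dgephys` analyzes whole-cell current-clamp recordings of dentate gyrus
(DG) granule neurons: it detects action potentials, extracts the standard
per-cell feature battery, sorts cells into the firing-defined type I /
type II strata, and compares experimental groups with the matching
statistical procedures.  Because recordings of this kind are rarely
deposited, the package ships a generative model that produces labeled
cohorts with exact ground truth, so every estimator is validated by
parameter recovery rather than by eye.

## Measurement definitions

All measurements operate on episodic voltage sweeps (mV, sampled at
10–20 kHz) evoked by square current steps (pA).

- **Spike detection.** Candidate spikes are local voltage maxima above
  0 mV (the overshoot criterion) separated by at least 2 ms.  Each
  candidate must also pass the threshold criterion below; depolarized
  plateaus without a fast upstroke are discarded.
- **Voltage threshold (V_trh).** The voltage at the *last* upward
  crossing of dV/dt ≥ 10 mV/ms within 5 ms before the peak, with the
  derivative taken by central difference.  Using the last crossing makes
  the measure robust to slow pre-depolarization noise.
- **Current threshold (I_trh, rheobase).** The smallest step amplitude
  with at least one overshooting spike.
- **First-spike latency.** Threshold-crossing time of the first spike at
  I_trh minus the step onset.  Referencing the threshold crossing rather
  than the peak marks spike initiation; the difference is sub-millisecond.
- **Input–output curve.** Per step: overshooting spike count, the ordered
  inter-spike intervals (ISIs, peak-to-peak), and the averaged
  instantaneous firing frequency.  The frequency is the arithmetic mean
  of the reciprocal ISIs (Hz); the alternative convention
  (count−1)/(t_last−t_first) is available via `freq_mode`.
- **Triphasic AHP.** From an isolated spike (no other spike within
  120 ms): fAHP = (minimum V within 10 ms after the peak) − V_trh;
  ADP = (maximum V between the fAHP trough and peak+60 ms) − trough;
  sAHP = (minimum V in peak+[60, 120] ms) − V_trh.  The 60-ms ADP upper
  bound makes the three phases partition the 120-ms epoch.  Signs:
  fAHP ≤ 0 ≤ ADP, sAHP ≤ 0.
- **Resting potential (MRP).** Mean voltage over a zero-current epoch;
  any overshooting spike there marks the cell as spontaneously firing and
  fails QC.
- **Passive properties.** R_in is the ordinary-least-squares slope of the
  steady-state voltage (mean of the last 50 ms of each 200-ms step)
  against step current, over −120…+20 pA in 20-pA increments; sweeps
  containing spikes are excluded from the regression.  τ comes from a
  single-exponential fit to the first 100 ms of the −40 pA step
  (the fit window is fixed at 100 ms within the conventional
  100–150 ms range).  C_m = 1000·τ/R_in (pF), the per-cell τ = RC
  identity; no independent capacitance measurement exists in this
  protocol.

### Quality control

A cell passes QC when its MRP is strictly more negative than −50 mV *or*
its holding current lies within ±25 pA (inclusive).  The disjunction is
the literal reading of the recording criteria; the physiologically
conservative conjunction is available as `rule_mode="and"`.  Boundary
semantics are deliberate: −50.0 mV exactly fails ("more negative than"
is strict), ±25 pA exactly passes ("between" is inclusive).  Three
further rules (no spontaneous firing at rest, triphasic AHP present,
firing adaptation present) are evaluated only when their evidence is
supplied.  A stable-access-resistance rule has no established quantitative
criterion; series resistance is stored in the metadata but does not gate
QC by default.

## Classification

Type I granule cells (presumptively less mature) reach their maximum
spike count at moderate currents and lose firing above ~150 pA through
depolarization block; type II cells (more mature) fire throughout the
range with counts growing to the strongest step.  The package
operationalizes this with three thresholds on the input–output curve:

- type I ⇔ the count maximum sits at ≤ 150 pA **and**
  N(max step)/N_max < 0.6;
- type II ⇔ N(max step)/N_max ≥ 0.9 **and** Spearman ρ(current, count)
  ≥ 0.8 over suprathreshold steps;
- anything between is `unclassified` and excluded from proportions.

The numeric cutoffs (0.6, 0.9, ρ ≥ 0.8) are this package's
operationalization of qualitative criteria and are exposed in
`ClassifierThresholds`.  R_in and I_trh differences between the types are
treated as validation statistics, not classification inputs.  Protocol
note: the firing family extends to 220 pA (the amplitude at which
sustained firing is assessed), in 10-pA increments from −20 pA, 500-ms
steps.

## Statistics

`dgephys.stats` implements the full battery from the formulas, with scipy
supplying only distribution functions: one-proportion Z (null-SE
denominator, no continuity correction, one-sided by default — the variant
consistent with Z = 2.1 for 19/27), pooled-variance Student t, one-way
ANOVA, Kruskal–Wallis with tie correction, and three many-to-one post hoc
procedures (Dunnett, Fisher LSD, Dunn).  Dunnett's familywise adjustment
is computed by seeded Monte Carlo on the exact joint null of the
maximum-|t| statistic — group means drawn N(0, 1/n_i) with a shared
chi-square variance — which handles arbitrary unbalanced designs and is
reproducible given the seed (default 2×10⁵ draws; critical values are
stable to ~3 decimals at 10⁶).  Dunn's p-values are unadjusted by
default, with Bonferroni available.  Group summaries report mean ± SE
(sample SD, n−1).

Per-variable test routing (ANOVA+Dunnett vs KW+Dunn vs ANOVA+Fisher LSD)
is configuration; the default map sends the type I ADP and sAHP through
KW+Dunn (skewed in practice), V_trh, C_m and the type II ADP through
ANOVA+Fisher LSD, and everything else through ANOVA+Dunnett, with
wild-type as the control group for all comparisons.  Cells are treated as
independent units even though several cells may come from one animal; no
hierarchical correction is applied, mirroring standard practice in this
literature — a known limitation.

## The synthetic neuron

The generator is a hybrid adaptive leaky integrate-and-fire model with a
pasted spike waveform (units mV, pA, pF, nS, ms):

    C dV/dt = −gL (V − EL) + I_inj + I_noise − w + I_post
    dw/dt   = −w/τ_w                    (w += w_b at each spike)
    dh/dt   = (h∞(V) − h)/τ_h,  h∞(V) = 1/(1 + exp((V − h_V)/h_k))
    I_post  = −a_f e^(−t/τ_f) + a_d e^(−t/τ_d) − a_s e^(−t/τ_s)

When V crosses VT with h ≥ h_min, a stereotyped 2-ms biphasic template is
pasted — cubic rise (0.6 ms, peak slope well above 50 mV/ms, crossing
10 mV/ms within ~0.4 mV of VT) to a peak of VT + A·h, half-cosine fall to
the reset Vr — and the three AHP/ADP current amplitudes and the
adaptation current increment.  When V ≥ VT but h < h_min no spike is
emitted and the voltage relaxes to a depolarized plateau: depolarization
block.  Integration is fixed-step Euler at 0.05 ms (spike-triggered
amplitudes decay by exact exponential factors); a step above 0.1 ms with
spiking enabled is rejected.  Current noise is drawn per 1-ms block with
SD `noise_sd_pA` (default 5 pA).  Identical seeds give bit-identical
traces.

The hybrid design trades biophysical realism for exact ground truth:
every quantity the pipeline estimates (VT, R = 1/gL, τ_m = C/gL, C,
spike times) is a generator parameter, so recovery is testable to
fractions of a percent.  What the model does *not* emulate: conductance-
based spike shapes (width, upstroke velocity), subthreshold Na⁺
amplification (hence absolute rheobases run higher than in real granule
cells, and first-spike latencies shorter), sag/rebound, synaptic
bombardment, and channel-level mechanisms of the disease phenotype.
Passing recovery tests therefore demonstrates that the estimators are
correct for data obeying the stated measurement model — not that they
are robust to every artifact of real recordings.

### Availability dynamics and block

The availability midpoint sits *above* threshold (h_V = −40 mV,
k = 2.5 mV), so h depletes almost exclusively during the pasted waveform
and recovers between spikes.  The short early-train ISIs at strong steps
then drive h below h_min within a few spikes, and the depolarized plateau
(where h∞ ≈ 0) makes the block self-sustaining for the remainder of the
step — successive peaks (VT + A·h) shrink before emission ceases, the
characteristic phenomenology of type I cells.  At moderate steps the longer
ISIs let h recover each cycle and firing is sustained.  Type II presets
disable the mechanism (h_V = +100 mV ⇒ h∞ ≈ 1 everywhere).  The Tg2576
type I preset carries a higher gate (h_min = 0.98 vs 0.95): its larger
capacitance slows the early-train ISIs that drive depletion, and without
the co-shift the block boundary would drift above the 150-pA
classification anchor — the gate preserves type I membership under the
disease group's passive parameters.

### Group presets

Eight presets cover the four arms (WT, TG, TG_RSG, WT_RSG) × two cell
types; wild-type and both rosiglitazone arms share distributions (rescue
by construction), and the Tg2576 presets shift only documented effects.
Passive parameters reproduce the reference cohort's group means: R_in = 1/gL
(e.g. 443 MΩ type I vs 297 MΩ type II in wild-type), τ = C/gL, EL set to
the group MRP.  VT is derived from the rheobase identity
VT = MRP + I_trh·R_in rather than from the reference V_trh means, which
are mutually inconsistent with a linear subthreshold model (a type II
cell with R_in 297 MΩ and V_trh −45 mV would have a rheobase near
80 pA, double the reference I_trh).  For the same reason the step
protocols run from the cell's resting potential with zero holding
current, which makes the model's rheobase land on the reference I_trh
scale (~25 pA for wild-type type I).

Disease effects are injected as: larger adaptation increment w_b (fewer
type I spikes), smaller w_b (more type II spikes), and shifted
spike-triggered currents for the ADP.  The three AHP phases are
mechanically coupled through the fAHP trough — the sensitivity matrix of
(fAHP, ADP, sAHP) to (a_f, a_d, a_s, τ_d) has rank 2 — so a pure ADP
shift is impossible; the presets therefore co-adjust a_s (type I) or a_f
(type II) to keep the flanking phases near the wild-type scale, and the
residual drift (deeper type I fAHP/sAHP in the disease arm) matches the
direction of the reference cohort's non-significant point estimates.  Per-cell
heterogeneity uses truncated-normal draws (±2.5 SD) with CVs of ~10% on
passive parameters and 12–15% on spike-triggered currents — deliberately
below the spread of real cohorts so the two firing phenotypes remain
separable; real data would blur the strata, as the reference cohort's ~8.5%
unclassified fraction suggests.

The rheobase "gradual injection" protocol for the isolated-AHP spike is
realized as a 10-pA-increment search returning the first amplitude whose
first overshooting spike has a ≥120-ms spike-free tail inside the step
(the ramp rate of the original protocol is not specified anywhere; this
stand-in is a stated substitute).  Default cohort design: 15 animals per
group, 1–4 cells per animal drawn uniformly, type I fraction 0.70
(wild-type and rescue arms) or 0.58 (Tg2576).

## Numerical choices and edge cases

- Euler at 0.05 ms keeps the noiseless steady-state deflection within
  0.1% of I·R and the fitted τ within 2% of C/gL; accuracy is asserted in
  tests rather than controlled adaptively, for bit-reproducibility.
- The steady-state window for R_in (last 50 ms of the 200-ms step)
  leaves a residual charging transient of e^(−150/τ); for the slowest
  cells (τ ≈ 45 ms) this biases individual R_in estimates by up to ~2%,
  while the cohort-mean error stays below 1%.
- The exponential fit uses `scipy.optimize.curve_fit` with endpoint-based
  initial values, parameter tolerance 1e-8 and box bounds; a flat
  response raises rather than returning a meaningless τ.
- Ties in the count maximum resolve to the lowest amplitude; Spearman ρ
  is undefined (and type II therefore unreachable) when fewer than three
  suprathreshold steps exist or counts are constant.
- Degenerate statistics (zero variance, all-identical observations)
  return flagged results (t = 0, p = 1; H = 0) instead of raising.
- The even-count median of cells/animal is the mean of the middle two.
- QC `reasons` lists the violated rules only when the cell fails
  overall, so `passed ⇔ reasons == []` holds in both rule modes.

## Benchmarks

`dgephys.validation` regenerates every headline number from a seed:
passive-property recovery (mean errors ≈ 0.3% R_in, 0.1% τ, 0.3% C_m on
50 noiseless cells), V_trh recovery (mean |error| ≈ 0.4 mV, dominated by
the one-sample discretization of the criterion crossing), classification
agreement with generator truth (100% noiseless, ≥95% at the default
5-pA noise on ~100-cell cohorts), simulated-null type-I error of each
statistical procedure at 10⁴ replicates (t: n=10/group; ANOVA and
Dunnett familywise: k=3, n=8; KW: k=3, n=12, where the chi-square
approximation is adequate), and effect-direction recovery (four injected
disease-vs-control signs plus rescue proximity) over 10 pipeline
replicates of 14 animals × 2–3 cells per group.  Problem sizes were
chosen so the full benchmark set completes in a few minutes on one core.
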