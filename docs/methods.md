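# Methods

## The problem

Dentate granule cells fire late: a slowly inactivating, subthreshold,
dendrotoxin (DTX)-sensitive potassium current — the delay current, I_D,
carried by Kv1-family channels — holds the membrane below spike threshold
for hundreds of milliseconds after a step-current onset. In experimental
temporal-lobe epilepsy (intrahippocampal kainate injection), granule cells
upregulate Kv1.1 transcription, the delay current grows, and first-spike
delays lengthen several-fold. This package implements the full quantitative
chain used to establish that link: current-clamp feature extraction,
voltage-clamp characterization of the subtracted current, multi-level qPCR
quantification, ROI densitometry, and the statistics tying phenotype to
expression — all exercised end-to-end on data from a conductance-based
granule-cell simulator.

## The simulated cell (`gdelay.dgsim`)

A single compartment:

    C_m dV/dt = -(I_L + I_Na + I_Kdr + I_Kir + I_D) + I_inj + I_noise
    I_D = g_D * a * b * (V - E_K)

with first-order gates relaxing toward Boltzmann steady states,

    a_inf(V) = 1/(1 + exp((V50_act - V)/k_act))      (activation, rising)
    b_inf(V) = 1/(1 + exp((V - V50_inact)/k_inact))  (inactivation, falling)

with fixed time constants. Both slope factors are positive; the sign of the
exponent carries the direction. This convention is used consistently by the
generator and all fitting code.

Parameters and their provenance:

| parameter | naive | KA | origin |
|---|---|---|---|
| V50_act / k_act (mV) | -32.3 / 17.1 | -46.0 / 17.0 | measured population means |
| V50_inact / k_inact (mV) | -41.7 / 14.1 | -43.8 / 13.7 | measured population means |
| tau_inact (ms) | 250 | 378 | measured population means |
| tau_act (ms) | 5 | 5 | free (not measured); fast relative to tau_inact |
| E_K (mV) | -104.3 | -104.3 | Nernst of the recording solutions (155/2.5 mM K+, 293.15 K) |
| C_m (pF) | 88 | 88 | back-computed from the printed amplitude/density pair (14.9 pA / 0.17 pA per pF = 87.6) |
| g_D (nS) | 2.0 | 5.0 | free; set so preset delays land in the observed range (see below) |
| g_Kir (nS) | 0.4 | 1.2 | free; inward rectifier dominates the resting-conductance difference |
| g_L, E_L | solved | solved | calibrated (see below) |
| V_rest / R_in targets | -82.4 mV / 602 MOhm | -83.8 mV / 449 MOhm | measured population means |

**Passive calibration.** `calibrate_passive` solves (g_L, E_L) in closed form
so each preset rests exactly at its target potential with its target input
resistance: the leak absorbs whatever slope conductance the gated currents do
not supply at rest, and E_L balances their standing current. This *is* the
preset "tuning script" — it is deterministic, in-library, and unit-tested,
so the calibration is reproduced on every preset construction rather than
frozen into magic constants.

**Spike currents.** Na/K-dr kinetics are Hodgkin-Huxley rate functions of the
hippocampal-interneuron family with instantaneous Na activation, shifted
+20 mV (`spike_v_shift_mV`) so threshold sits in the granule-cell range and
the delay mechanism engages: the delay current only postpones spikes if
threshold lies where a_inf is appreciable. With this shift the naive preset
yields a ~413 ms delay at the standard 80 pA step that collapses to ~60 ms
under full DTX block, and the KA preset ~1200 ms at 130 pA — the observed
regime. The side effect is a depolarized measured AP threshold (about
-22 mV vs the measured -45 mV); we preferred matching the delay/block
phenomenology over the threshold value, since delays are what the pipeline
quantifies.

**Magnitude of g_D.** The printed whole-cell I_D amplitudes (14.9 pA naive,
185 pA KA at 0 mV) imply sub-nanosiemens somatic conductances that cannot
delay spikes by hundreds of ms in a single compartment; in the real cell
much of the current is axonal and poorly clamped. The presets therefore
treat g_D as a free functional parameter (2 and 5 nS) chosen for the delay
phenomenology, while the printed amplitude/density pair is kept only to fix
C_m. Simulated clamp currents are consequently larger than the printed ones;
no acceptance quantity depends on absolute current amplitude.

**Integration.** Current clamp: fixed step, exponential Euler for gates,
explicit update for V, dt = 25 us (halving dt moves the delay by <0.05%).
Voltage clamp is solved exactly: with a piecewise-constant command, every
gate is a closed-form exponential relaxation, so clamp families carry no
integration error and the subtraction identity (control minus fully blocked
equals the pure g_D current) holds to machine precision. Clamp families
include only leak + Kir + I_D, mirroring the experimental cocktail (TTX,
XE991, forskolin) that silences spike currents. Current noise is an
Ornstein-Uhlenbeck process (stationary SD in pA, tau 3 ms), which keeps the
noise statistics independent of dt; presets default to noise-free, and the
deterministic phenomenology checks (monotonicity, convergence) are run in
the noise-free limit by design.

## Feature extraction choices (`gdelay.ccfeat`)

* AP peak criterion: local maximum above 0 mV (overshoot), 2 ms lockout.
* Threshold: membrane potential at the last upward crossing of the dV/dt
  criterion before the peak. The conventional criterion is exposed in mV/s;
  the historical figure of 20 mV/s is almost certainly a misprint of
  20 mV/ms, so both are supported and tests of threshold use 20 mV/ms.
* Width at -5 mV by linear interpolation of the two crossings.
* R_in: least-squares slope of steady-state dV vs I over steps within
  +/-10 mV of baseline, steady state = final 20% of the step; spiking sweeps
  excluded.
* tau_m: double-exponential fit of a <5 mV averaged charging response,
  slower component reported; if the slower component carries <2% of the
  amplitude the response is treated as single-exponential.
* Rheobase: ascending grid (default 5 pA), >= 1 AP within 1 s.
* Delay: onset to first AP peak within a 2 s window; absence is a censoring
  flag, never a sentinel, and censored cells never enter group means.
* Jitter: sample SD (and SD/mean = CV) of first-spike delays over >= 3
  repeated trials.

## Voltage-clamp estimators (`gdelay.vcfeat`)

* Subtraction blanks the first 5 ms of each step before peak search.
* **Onset-extrapolated amplitudes.** The raw in-step peak underestimates the
  available current by a voltage-dependent factor because inactivation has
  already begun by peak time (b_inf falls with V, so depolarized steps lose
  more). Fitting A exp(-t/tau) + C after the activation rise and evaluating
  at step onset removes the bias exactly in this model (the extrapolate is
  g_D a_inf b0 (V - E_K)); with it, noiseless midpoint recovery is good to
  0.1 mV where the raw peak left a ~1 mV deficit. The decay fit constrains
  tau to be resolvable beyond the skipped rise, otherwise extrapolation on a
  noise-only trace is unbounded.
* Boltzmann fits are multi-start (5 jittered restarts) bounded least
  squares. Activation points are weighted by driving force (sigma
  proportional to 1/|V - V_rev|): a fixed current error maps to a
  conductance error ~1/|driving force|, so near-reversal points carry
  little weight. At SNR 20 the slope factor still carries a small
  noise-induced positive bias (~4%); midpoints are unbiased to ~0.3 mV.
* Reversal: linear fit over (-110, -80) mV by default — the most
  hyperpolarized limb bracketing the crossing. Wider ranges drag the
  crossing depolarized because the Boltzmann rise curves the I-V upward
  (the same bias visible in measured reversal potentials). When the
  crossing's standard error is wide, or per-family currents are too small,
  `driving_reference` falls back to the Nernst potential of the known
  solutions; the recovery workflow uses the Nernst reference outright.
* tau_inact: mono-exponential with offset, fitted after the peak; traces are
  decimated to ~2-4k points for fitting (the decay needs resolution, not
  20 kHz).

## qPCR conventions (`gdelay.qpcr`)

* QC: samples failing melt-curve/primer-dimer checks are dropped; all
  samples of a cell whose reference gene (GAPDH) was undetected are dropped.
  Censored CTs are excluded from means, not imputed.
* Efficiency: E_amplification = 10^(-1/slope) (2.0 = perfect doubling) and
  the conventional E = that minus 1 are both reported; the 0.9-1.05
  acceptance band is applied to the conventional E, the only reading under
  which a perfect assay (E = 1.0) sits inside the band.
* Fold change: group-mean CTs, dCT against the reference, fold =
  (1+E)^(-ddCT) with E defaulting to 1. A `dct_only` mode skips the
  reference for single-cell absolute-CT comparisons. Computed on mean CTs
  (which reproduces the printed pearl-level 6.1 from 2^2.6); per-cell
  averaging of dCTs is the likely source of small discrepancies in
  single-cell fold values and is not reproducible from group means alone.
* Co-expression: CTs are standardized per gene across cells (CT is already
  a log2-domain quantity), Pearson r on cells with both genes detected.

## The synthetic cohort (`gdelay.stats_report.build_cohort`)

Each simulated cell draws a lognormal delay-conductance multiplier
(sigma = 0.25 in log space). That multiplier is the latent factor: it scales
g_D (hence the measured delay) and lowers the cell's Kv1.1 CT by log2(mult).
The group-level difference is programmed separately: KA cells carry a
log2(10.4)-cycle CT drop (the transcript fold exceeds the functional
conductance ratio — transcript abundance and conductance need not scale
1:1), with CT noise of 0.6 cycles and a GAPDH reference at 34.8. Delays are
measured at 80 pA (naive) / 130 pA (KA) standard steps; a silent cell is
re-probed at 1.3x and 1.7x before being recorded as censored, as an
experimenter would. At 32 cells per group the pooled delay-expression
correlation comes out near r = 0.55 and is detected at p < 0.01.

What the generator does *not* emulate: electrode/seal artifacts and series
resistance errors, multi-compartment cable effects, channel stochasticity,
amplification-curve (raw fluorescence) shapes, image vignetting or uneven
illumination. Passing tests therefore demonstrate the correctness of the
estimators and the internal consistency of the chain on idealized data, not
robustness to every acquisition pathology.

## Statistics (`gdelay.stats_report`)

Shapiro-Wilk (alpha 0.05) gates each two-group comparison into Student's
t (paired/unpaired) or the matching rank test; the gate's type-I error is
verified at the nominal 5% on 2000 normal-null replicates. Curve families
are compared with the extra-sum-of-squares F-test (shared vs separate
parameters on a common x grid). Correlation significance uses the exact
t-transform of Pearson's r, bracketed into the conventional star levels (the
brackets are checked against the exact beta-distribution null). No
multiple-testing correction is applied, matching the source analysis; the
study report carries the count of tests run. Reports are JSON + CSV; figure
generation is left to the caller (nothing in the report pipeline requires a
plotting backend).

## Problem sizes used in validation

Gating recovery: 50 seeded replicates per condition (100 families per
protocol) at SNR 20, defined as the largest family amplitude over the
per-sweep measurement-noise SD. Fold recovery: 200 cells/group, CT SD 1.0,
averaged over 10 replicate tables (a single table scatters ~10% because four
noisy group means enter the double delta). Null false-positive rates: 1000
reduced-size replicates (20 cells each). Gate calibration: 2000 replicates
of 10 + 10. Phenomenology: conductance scalings 0.1-10x at a 300 pA step
(chosen so the 10x cell still fires inside the 2 s window), amplitudes
80-250 pA at 1x.

## Known limitations

* The measured AP threshold of the model is depolarized relative to granule
  cells (consequence of instantaneous Na activation plus the +20 mV shift).
* Simulated absolute I_D amplitudes are not comparable to printed whole-cell
  currents (see "Magnitude of g_D").
* The slope-factor estimator carries a ~4% positive bias at SNR 20.
* The E_K reference value corresponds to 293.15 K; between 22 and 25 C the
  Nernst potential moves linearly with absolute temperature, about
  -0.36 mV/K (i.e. up to ~1.7 mV away from the 20 C value at 25 C).
* Single-cell fold changes computed from group-mean CTs cannot reproduce
  per-cell-averaged published values exactly; both conventions are provided.
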