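# Methods

## The model cell and its synaptic drive

The simulator is a single-compartment conductance-based neuron meant to
stand in for an On-type primate retinal ganglion cell during loose-patch
and whole-cell recording. Its membrane equation is

    C dV/dt = −[ G_exc(t)(V−E_exc) + G_inh(t)(V−E_inh)
               + G_NMDA(t)·B(V)(V−E_exc) + g_leak(V−E_leak) ],

with C = 60 pF, g_leak = 4 nS, E_leak = −65 mV, E_exc = 0 mV and
E_inh = −70 mV. Units are fixed package-wide (mV, pA, nS; nS × mV = pA;
inward current negative). Spiking is threshold-and-reset
(integrate-and-fire: threshold −52 mV, reset −62 mV, 2-ms refractory)
with a stereotyped 80-mV half-sine transient pasted onto the voltage
trace at each spike, because the downstream analyses need accurate
spike *times* and realistic detector input, not action-potential
biophysics. The integrator refuses time steps coarser than one tenth of
the membrane time constant.

The synaptic drive has four components, each scaled by a per-condition
multiplicative factor:

- **Tonic excitation** — Poisson shot noise: unitary conductance events
  of amplitude A = 0.6 nS with instant rise and single-exponential
  decay τ = 2 ms, at a baseline rate ν = 1000 Hz whose instantaneous
  value is modulated multiplicatively by the Weber contrast of the
  stimulus (up during the On-phase, down during Off). The mean tonic
  conductance is ν·A·τ = 1.2 nS, i.e. ≈72 pA of standing inward
  current at −60 mV and ≈24 Hz of dark firing — the magnitudes the
  real On-midget recordings report. These defaults were set from the
  published physiology (standing current ~70 pA, background rate
  ~24 Hz, baseline current SD tens of pA) and define the study
  conditions for every simulation-based check.
- **Transient excitation** — a deterministic, rectified 8-nS
  exponential transient (5-ms latency, 40-ms decay) fired at
  positive-going contrast steps only. It models the cone-driven onset
  input that survives CP-AMPAR blockade.
- **NMDA component** — a fixed fraction (default 0.2) of the total
  excitatory drive is routed through a conductance multiplied by the
  Mg²⁺-block factor B(V) = 1/(1 + (Mg/c)·exp(−V/k)). The constants
  c = 3.57 mM and k = 16.13 mV at Mg = 1 mM are the standard published
  values for this sigmoidal form; they are configuration, recorded in
  every fit report, and can be replaced wholesale.
- **Transient inhibition** — a 2-nS transient at On-onset (10-ms
  latency, 30-ms decay), modeling the brief feedforward inhibition at
  the start of the On-phase.

Pharmacology is parameter algebra, not kinetics: each condition maps to
factors on the four components (IEM-1460 → tonic 0; D-AP5 → NMDA 0;
MFA → tonic 0, because the gap-junction route carries the tonic drive;
inhibitory cocktail → inhibition 0). Factors compose multiplicatively,
which makes occlusion exact: two conditions that each zero the tonic
component leave nothing for the other to remove.

The stimulus is a square wave at 1 Hz and 80% contrast about a
~600 Rh*/rod/s background, with contrast defined as
100·(L_max − L_min)/L_background and the modulation split symmetrically
about the background (the convention under which an 80% contrast on a
600 background swings 840/360). The first half-cycle is the On-phase.

### Exactness of the shot-noise generator

Event counts per sample are Poisson(ν·Δt); each event receives a
uniform sub-sample time and enters the trace through the exponential
kernel evaluated at its true lag, so the sampled trace is an exact
sampling of the continuous-time shot-noise process. Its moments are
therefore unbiased for Campbell's theorem,

    mean = ν·A·F·τ,   variance = ν·(A·F)²·τ/2,

(F the driving force; ∫w = τ and ∫w² = τ/2 for the exponential
kernel), which is the closed-form oracle the tests check the simulated
tonic current against at the junction-corrected −76 mV holding
potential. A warm-up pad of 10τ makes the trace stationary from
sample 0.

## Analysis stages

**Spike detection** takes the first difference of the trace (removing
slow drift), sets the threshold at 3× the full-trace derivative SD, and
takes positive-going crossings with a 1-ms lockout. Note the rule is
not false-positive-free on pure noise — a 3-SD threshold on ~10⁴
Gaussian derivative samples must cross occasionally (Rice's formula);
its selectivity in practice comes from spikes dominating the derivative
SD, and against simulator ground truth it achieves ≥99.9% sensitivity
with zero extra detections at the default signal-to-noise.

**Blanking** replaces [t−1 ms, t+3 ms] around each spike with the
straight line between the window-edge samples, merging overlapping
windows first (which makes the operation idempotent) and clipping
windows at trace edges. Blanking precedes any baseline SD measurement
on current-clamp voltage.

**PSTHs** use 20-ms bins over a positive multiple of 20 trials;
bin rate = total count/(n_trials × bin width), so the histogram
conserves spike counts exactly. Across-block SDs come from block-wise
PSTHs. The background/peak/sustained windows are a declared convention
(300 ms pre-stimulus; max bin in the first 150 ms of On; mean of the
last 250 ms of On) because the source recordings mark them only
graphically; the windows used are recorded in every result.
Reported percent changes are rounded half-away-from-zero to integers,
full precision retained internally.

**Conductance analysis**: per holding potential, the trial-averaged
current minus its own pre-stimulus (300-ms) baseline mean gives the net
light-evoked current — per-potential subtraction removes leak and tonic
offsets, which is also why fitted conductances can legitimately be
negative (suppression of baseline input during the Off-phase). Net
currents are averaged in 10-ms bins across −110..+50 mV (20-mV steps,
nine potentials), and each bin's I-V relation is solved by unweighted
least squares for (G_exc, G_inh, G_NMDA) with the reversal potentials
fixed by assumption, not refit. The NMDA column B(V)·(V−E_exc) is
optionally dropped for cells with linear excitatory I-V relations. The
design-matrix condition number is reported and a warning raised when
the supplied potentials make the NMDA and linear columns nearly
collinear (e.g. only depolarized potentials where B ≈ 1).
Non-negativity is deliberately not imposed. On full-rank noise-free
input the decomposition inverts the forward model to machine precision;
with shot noise and 20 trials per potential, component recovery RMSE
stays within ~7% of the true peak (≤15% is the acceptance bound).

Drug-difference conductances are component-wise control − drug on a
shared grid and Mg-block record. Time-course similarity between two
traces reports the closed-form least-squares scale s = Σab/Σb² and the
Pearson correlation; on two model cell types whose tonic drives differ
4-fold, the antagonist-sensitive excitatory components return a scale
of ~4 with correlation ≈0.99.

**Statistics**: Shapiro-Wilk normality is advisory (a warning, never a
test switch, since the source pipeline reports none); comparisons are
two-tailed paired or unpaired t-tests with Bonferroni adjustment
p_adj = min(1, m·p) and α = 0.05. Degenerate zero-variance comparisons
report p = 1 with a flag. Calibration is verified by simulation:
type-I error within binomial error of 0.05, and family-wise error under
Bonferroni at or below 0.05 within Monte-Carlo error.

**Expression summaries**: cluster mean and SD on the log(TPM+1) scale
include zeros (the printed cluster means with large SDs are consistent
with zero-inflated per-cell values; an expressing-only mean is
available behind a flag). The "log fold difference between means" is
implemented as the ratio of mean log(TPM+1) values, the reading under
which the printed pairs reproduce (0.90/0.85 → 1.06). One printed pair
does not reproduce exactly under rounded inputs (1.07/0.97 → 1.10
versus a printed 1.11, presumably computed from unrounded means); the
discrepancy is documented, not patched. The synthetic generator draws
a Bernoulli expressing mask times Gamma-distributed positive values
whose moments are solved from the overall targets; targets whose SD is
too small for the requested zero inflation are rejected as infeasible.
The AII-amacrine cluster's moments are a synthetic stand-in (mean 0.31,
SD 0.45, 40% expressing) chosen to be consistent with the reported
~3-fold lower GRIA2 means in that cluster; the ganglion-cell cluster
moments are the printed ones.

## What the synthetic data does and does not establish

The generator reproduces the *statistical structure* the analyses
assume — Poisson shot-noise baselines, square-wave-locked modulation,
component-wise drug action, ideal voltage clamp (series resistance
uncompensated in the source recordings, omitted here so ground truth is
exact), linear summation of conductances. Passing tests therefore
demonstrate that the analysis chain recovers known ground truth under
those assumptions. They do not validate the assumptions themselves
against real retina: no series-resistance or space-clamp error, no
receptor kinetics or desensitization, no gap-junction biophysics, no
spike-shape variability, no cell-to-cell parameter spread beyond seeds.
Peak firing rates of the model (~200 Hz in the peak bin) run higher
than typical recorded peaks (~130–175 Hz); the directional and
proportional structure, not absolute peak rate, is what the end-to-end
checks rely on.

## Problem sizes and numerical choices

Simulations run at 10 kHz. The standard checks use 20-trial PSTH
blocks (2.3-s sweeps), 100 seeded runs for detector performance and for
the Campbell comparison, 20 trials × 9 potentials for decomposition
recovery, and 1000 repeats for t-test calibration — sizes at which
every Monte-Carlo bound sits well inside its tolerance while the whole
suite runs in well under a minute. Least squares uses
`numpy.linalg.lstsq`; linear I-V fits use `scipy.stats.linregress`;
statistical tests delegate to `scipy.stats`. Ties and degenerate
inputs: a constant trace yields an empty spike train (not an error); a
flat I-V yields conductance 0 with the reversal flagged undefined; a
zero reference trace leaves the similarity scale NaN-flagged; double
junction correction is a state error. Dataset round-trips are exact on
metadata and good to ~1e−9 relative on signals (`%.10g` formatting).

## Open choices made here

- The −16 mV (recording) and −13 mV (conductance-analysis) junction
  corrections are carried as dataset metadata presets, never assumed,
  since the source protocol applies different values at different
  stages without stating why.
- NWB input is not supported; the native TSV+JSON sweep-table format
  (plus MTX/CSV for expression) covers the pipeline's needs and keeps
  fixtures inspectable and diff-able. The samples table carries a
  `sweep_id` column so that several sweeps of one cell under one trial
  index but different conditions stay distinguishable.
- Drug conditions are factor maps rather than kinetic schemes; this is
  exactly what makes occlusion and component-difference analyses exact
  and testable.
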