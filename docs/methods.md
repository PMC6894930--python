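# Methods

This note records the quantitative conventions the package implements, the
choices made where more than one reading was defensible, and what the
synthetic-data tests do and do not establish about recorded data.

## Trace model and preprocessing

A trace ensemble is a matrix of raw fluorescence values, one row per
stimulus pulse, with a shared frame rate (default 10 fps), a half-open
stimulus window `[stim_onset, stim_offset)` in 0-based frame indices, and
per-row labels (neuron, condition, animal, pulse 1/2, block).  Rows
containing non-finite values — tracking artifacts upstream — are flagged
and excluded from analysis without renumbering the survivors.

* **ΔF/F₀**: `dff[t] = (raw[t] − F₀)/F₀` with F₀ the *median* of the 100
  frames (10 s at 10 fps) immediately before stimulus onset.  The median
  makes the baseline robust to isolated artifacts; a zero median is an
  error, not a silent NaN.
* **Smoothing**: 5-point centered running mean.  Within two frames of
  either trace end the window is truncated to the frames that exist, so
  length is preserved and constants are fixed points.  Smoothing is linear.
* **Min–max scaling** (inhibition calling only): affine map of the trace to
  [0, 1].  The scaling window defaults to the full trace; a window around
  the pulse epoch can be supplied instead, since the source convention is
  ambiguous.  Constant traces are rejected.
* **Bleach correction** (for long recordings dominated by photobleaching):
  a least-squares line is fitted to all frames outside the stimulus
  windows and the corrected trace is `(raw − line)/line`.  Division is by
  the fitted line, not by F₀, so the output is a fluorescence change
  relative to the decaying baseline; a non-positive fitted line is an
  error.  Only linear drift is modeled.

## Response calling

Baseline statistics (mean and SD, sample SD with ddof = 1) are computed on
the pre-stimulus frames *of the signal the criterion is stated on*: the
smoothed ΔF/F₀ for activation, the scaled trace for inhibition.  The
"mean time derivative over frames t … t+w" is the mean of the forward
differences in that span, `(x[t+w] − x[t])/w`; baseline derivative
statistics use the differences lying entirely inside the baseline window
(99 of them for a 100-frame baseline).  All comparisons are strict
inequalities; a zero baseline SD degenerates the threshold to strict
exceedance of the baseline mean and is flagged on the call.

Onsets are searched over the stimulus window.  The look-ahead mean window
may dangle past the stimulus offset but not past the trace end; frames
whose window would leave the trace are ineligible, so a late transient too
close to the end of the recording is (correctly) not callable.

Latency in seconds is `(onset_frame − stim_onset)/frame_rate`.

**Timing bias.**  The magnitude criterion looks 12 frames ahead, so it is
satisfied up to ~1.3 s before a true onset; the derivative criterion
(1 baseline SD) then gates timing, but baseline derivative noise exceeds
1 SD on ~16% of frames regardless of the noise amplitude (the threshold is
scale-free).  The net effect is a small systematic *early* bias of the
detected onset, typically 2–5 frames (0.2–0.5 s) depending on rise shape,
plus the ~2-frame lead introduced by centered smoothing.  This is a
property of the published rule, not of this implementation; it is why
onset-accuracy tests assert a median error bound rather than unbiasedness,
and why profile-convergence tests use ground-truth onsets.  Comparisons
*between* conditions analyzed with the same rule are unaffected to first
order.

**Threshold sweep.**  `threshold_sweep` computes response counts over a
grid of (magnitude multiplier, derivative multiplier) pairs.  On
responder-free data counts fall monotonically with the magnitude
multiplier; on mixed data they plateau near the true responder count in a
band around the defaults, and at the default magnitude threshold they are
nearly independent of the derivative multiplier — the inflection-point
rationale for the shipped constants.  For inhibition sweeps the grid value
replaces the long-window derivative multiplier and the short-window
disjunct is disabled so that counts are monotone in both axes; ordinary
detection keeps the published disjunction.

## Population statistics

* **Cumulative profile**: fraction of *all* trials responded by time t,
  evaluated on the frame grid over a 10 s horizon.  Non-responders count
  in the denominator only (right-censored at the horizon).
* **KS comparison**: D is the maximum absolute gap between two profiles on
  the shared grid; n₁, n₂ are total trial counts.  The p-value is the
  asymptotic Kolmogorov tail `Q(λ) = 2Σ(−1)^{k−1}exp(−2k²λ²)` at
  `λ = √(n₁n₂/(n₁+n₂))·D`, truncated when terms fall below 1e−12 and
  clamped to [0, 1]; λ ≤ 0 returns p = 1.  The Stephens small-sample
  adjustment of λ was considered and rejected: the plain form reproduces
  the reference worked example (D = 0.470, n = 28/24 → p ≈ 0.0066 ≈ 0.007)
  while the adjusted form gives 0.0041.  The asymptotic tail is
  conservative at modest n — at n = 40 per group its null rejection rate
  at p < 0.05 is ~2–3%, and even the exact permutation test achieves only
  ~3% because the null distribution of D is discrete.  Evaluating D on the
  frame grid matches the pipeline's frame-quantized latencies exactly.
* **50% response time**: first frame at which the cumulative curve reaches
  0.5 — no interpolation, so lags are multiples of the frame period.
* **Bootstrap lag**: downstream minus upstream 50%-response time; whole
  trials are resampled with replacement (default 1000 resamples, single
  user seed), both 50% times recomputed per resample, and the SD of the
  resampled lags reported as the standard error.  Resamples in which
  either group fails to reach 50% are counted and excluded from the SD —
  with response probabilities near 0.5 this count is substantial and is
  part of the result, not a nuisance.
* **Magnitudes**: either mean of the final 10 in-pulse frames minus mean
  of the 10 frames before onset (sign-free; sensory-style), or the
  within-pulse maximum (robust to adaptation).  **Rise time** is the first
  crossing of 66% of peak minus the first crossing of 33% of peak, at or
  after the detected onset.
* **Pulse pairs**: animals contribute two pulses; the 2×2 contingency of
  (pulse-1 responded) × (pulse-2 responded) and, among double responders,
  Pearson correlations of magnitudes and latencies.

## Synthetic generator

`raw = F_base·(1 + signal(t))·bleach(t) + F_base·noise(t)` with i.i.d.
Gaussian frame noise (optional AR(1) correlation, default off), linear
bleach (default off), and per-trial Bernoulli responder status.  Responder
onsets are drawn from a configurable latency law (default shifted
lognormal, median ≈ 1.2 s after onset — fast but variable, as for a
strongly driven sensory neuron) and quantized to the frame grid so the
ground-truth onset frame is exact.  The rise is a step, linear ramp,
saturating exponential (default, τ = 0.5 s — indicator-like kinetics) or
sigmoid, with optional exponential adaptation; amplitude defaults to
1 ΔF/F₀ with 20% trial jitter over a 0.02 ΔF/F₀ noise floor.  Inhibition
ensembles carry a tonic +1 ΔF/F₀ elevation that responders lose after
onset.  Default geometry: 300 frames at 10 fps, stimulus at frames
100–200.

What the generator does *not* emulate: indicator nonlinearity and
saturation, correlated motion artifacts, baseline drift other than a
line, spontaneous transients, and multi-event trials.  Tests passing on
synthetic data therefore establish the statistical machinery (criteria
evaluated exactly, calibrated false-positive rate, convergence of the
estimators), not robustness to every failure mode of real recordings.

## Membrane model

Single compartment, `C·dV/dt = −I_ss(V) − g_cl·s_cl·(V−E_Cl) +
g_gap·(V_awa−V) + I_inj`, units pF/nS/mV/pA/ms.  The intrinsic steady-state
I–V is the cubic `I_ss(V) = a(V+80)(V+50)(V+20)` — the simplest smooth
N-shape with stable zeros at −80 and −20 mV and a negative-slope
(high-resistance) region between.  The single calibration constant
`a = 2.117·10⁻⁴ pA/mV³` places the resting-branch knee (saddle-node) at
2.20 pA, chosen from the switching anchors: a sustained 2 pA step must not
switch, 3 pA must, and 15 s ramps must transition near 2 pA.  Simulated
ramp transitions occur at 2.28 pA (0→5 pA) and 2.32 pA (0→10 pA) — the
static knee plus a small dynamical delay that shrinks with ramp slope —
both rounding to 2 pA.  `scripts/calibrate_membrane.py` regenerates and
verifies the constant.

Capacitance defaults to 2 pF (a small unmyelinated neuron), giving
millisecond-scale relaxation; absolute conductance and capacitance scales
are otherwise unconstrained by the switching anchors and only their ratios
matter for the thresholds.  The chloride reversal is −80 mV, at rest, so
the open shunt acts by lowering input resistance rather than by
hyperpolarizing; 1 nS of open shunt linearizes the I–V completely
(monostable near rest).  A consequence worth noting: because the
depolarized branch can only sink ~2.2 pA, even a ~0.05 nS leak to −80 mV
annihilates the plateau fixed point — shunting is an extremely effective
veto in this regime.  The gap junction (0.1 nS) with the presynaptic
command at −15 mV supplies ~6.5 pA of drive at rest, supra-threshold only
when the shunt is closed: of the four (drive × disinhibition)
combinations, only (on, on) reaches the plateau.

At zero input the depolarized branch remains stable, so the default
calibration is *persistent* (hysteretic): the cell stays up after a
suprathreshold step ends.  Whether the biological cell does this is not
constrained by the anchors; `hysteresis_regime` reports which regime any
given parameterization produces rather than asserting one.

Integration is fixed-step RK4 at dt = 0.1 ms (explicit solvers are
adequate: the stiffest relaxation is ~2 ms).  Transition times are
solver-step-invariant (dt vs dt/2 within dt) and agree with an adaptive
implicit reference integration within 10 ms.  Fixed points are bracketed
on a 0.1 mV grid and polished to |I| < 10⁻⁶ pA; stability is the sign of
the net-current slope.  Non-finite states abort with a diagnostic.  The
calcium proxy is a sigmoid of V (half-activation −50 mV, slope 5 mV),
capturing the bimodal all-or-none correspondence between voltage and
indicator signal without modeling indicator kinetics.

## Problem sizes and numerical conventions

Test and validation runs use ensembles of 30–500 traces, 1000-trace oracle
sweeps, 1000-replicate null simulations and 20–50k bootstrap resamples;
biophysical protocols simulate 10–60 s of membrane time.  Ties cannot
occur in onset calling ("first frame" is unique); all random stages take a
single integer seed (`numpy.random.default_rng`), with per-stage substream
seeds derived by hashing in the pipeline, and every output records its
seed.

## Known limitations

* The detection rule's early-onset bias (above) is inherited by design;
  absolute latencies carry a ~0.2–0.5 s systematic component.
* The asymptotic KS p-value is conservative below n ≈ 50 per group.
* The membrane model is a phenomenological minimal model: no channel
  identities, no AWA action-potential dynamics (the presynaptic command is
  a square pulse), no morphology, no stochastic gating; the cubic I–V's
  depolarized branch is shallower than a real plateau conductance, so
  voltages above the plateau rise more with strong input than recorded
  cells do.
* Bleach correction assumes linear decay; exponential bleaching is out of
  scope.
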