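# Methods

## The folding model

Conformational dynamics of an xrRNA molecule are modeled as a
continuous-time Markov chain (CTMC) on three states — L (unfolded),
I (partially folded), H (folded) — with six first-order rate constants
k_L→I, k_L→H, k_I→L, k_I→H, k_H→L, k_H→I (s⁻¹). The dwell time in a
state is exponential with mean 1/(sum of its exit rates), and the
branch taken at each jump is proportional to the individual rates.
Nothing in the estimators assumes detailed balance; when the generating
rates do satisfy the Kolmogorov cycle condition the free-energy
"closure residual" (below) is zero up to estimation error, and this is
used as a diagnostic.

## Synthetic data generator

`xrfret.synth` produces every input with known ground truth.

* **State paths** come from exact (Gillespie) jump simulation.
* **Traces**: each frame of length Δt (default 0.025 s, the standard
  camera resolution for these measurements) reports the
  occupancy-weighted mean FRET over the frame — a camera necessarily
  integrates, and this is what creates blurred frames at transitions.
  An instantaneous-sampling switch (`integrate_frames=False`) exists
  for estimator-oracle studies free of camera blur. Donor and acceptor
  are total·(1−E) and total·E (default total 1000 photons/frame) plus
  independent Gaussian channel noise; the default channel s.d. of 70
  photons corresponds to ≈0.05 s.d. on the FRET axis at mid-range
  efficiency, matching the apparent state widths of real histograms.
  State FRET centers default to 0.3/0.5/0.9 (the reported values for
  the three conformations). Photobleaching is single-step and
  per-channel with exponential waiting times (donor bleach kills both
  channels; acceptor bleach un-quenches the donor); bleach rates
  default to 0 so benchmark ensembles have full-length traces.
* **Mg²⁺ rate law**: the unfolding-direction rates k_I→L and k_H→I
  decay as power laws in Mg²⁺, k(c) = k_ref·(c/1 mM)^(−0.5), while
  folding-direction rates are constant — the simplest positive law
  reproducing the observed trend that high Mg²⁺ stabilizes the folded
  state both thermodynamically and kinetically. The reference rates
  (k_L→I=1, k_L→H=0.02, k_I→L=1, k_I→H=0.8, k_H→L=0.02, k_H→I=0.4 s⁻¹
  at 1 mM) put the H/L population crossover near 0.5 mM, inside the
  experimentally scanned window (0.001–100 mM). Rates are clipped to
  [10⁻⁴, 8] s⁻¹; a guard warns when any rate exceeds 0.2/Δt, beyond
  which idealization is unreliable.
* **Movies**: spots are symmetric 2D Gaussians on a uniform background;
  the acceptor channel is the donor spot set mapped through a rigid
  transform. Poisson and/or Gaussian read noise are optional.
* **Decay traces**: the +Xrn1 channel decays exponentially
  (rate in min⁻¹); any multiplicative drift is shared with the −Xrn1
  control, so control normalization cancels it identically.
  Multiplicative Gaussian noise, t=0 kept noise-free as the
  normalization anchor.
* **Scattering**: ideal Guinier curves I(q) = I₀·exp(−q²Rg²/3).

What the generator does **not** emulate: donor leakage and γ
(detection-efficiency) corrections — none are applied in the analysis
either, so E = I_A/(I_A+I_D) throughout; blinking; spectral crosstalk;
multi-step bleaching; non-Gaussian photon statistics in traces. Tests
passing on this generator therefore validate the estimators, not those
instrument non-idealities.

## Idealization

One Gaussian-emission HMM is fitted per condition, shared across all
traces (ensemble histograms and TDPs are ensemble-level objects), with
Baum–Welch and a convergence tolerance of 10⁻⁴ on the log-likelihood.
Emission means initialize on a linear grid between the 2nd and 98th
percentiles of the pooled FRET values (occupancy-weighted quantiles
would collapse onto a dominant state); the transition matrix starts at
0.95 self-probability. After fitting, states are relabeled by
ascending mean so L < I < H regardless of initialization. Decoding is
Viterbi by default (posterior decoding available). The state count is
fixed at 3 by default; a BIC-based selector (1–4 states) covers
constructs whose ensembles collapse to fewer resolvable states.
Bleaching is detected as the least-squares two-segment change point on
total intensity, accepted when the post-step mean falls below half the
pre-step mean by more than four pooled standard deviations; traces are
truncated there. FRET values are clipped to [0,1]; all-zero frames are
masked and split dwell bookkeeping.

## Kinetics

Dwells are maximal runs of one state label; the first and last dwell of
every trace are censored and excluded from lifetime fits (standard
practice for boundary-truncated dwells). Every observed state change
counts as one transition, including changes adjacent to censored
dwells. Lifetimes default to the closed-form exponential MLE
(τ = mean uncensored dwell, s.e. τ/√n); a binned least-squares fit of
A·e^(−t/τ) is available since histogram fitting is also common.
The six rates follow the branching-fraction equations literally, so
k_X→Y + k_X→Z = 1/τ_X is an algebraic identity. Rate uncertainties
combine the lifetime s.e. with the binomial branching error.

Free energies use ΔG_b − ΔG_a = −k_B T·ln(k_a→b/k_b→a) with ΔG_L = 0,
at T = 298.15 K (25 °C) by default; k_B T = 0.5925 kcal/mol. ΔG_H is
computed along the sequential pathway (L↔I then I↔H), matching the
dominant folding route; the alternative direct H↔L determination is
reported as the cycle-closure residual, a detailed-balance diagnostic.
Barriers use the illustrative convention −k_B T·ln(k) + 1.8 k_B T with
rates in s⁻¹ (plotting only; the offset makes absolute values
unit-convention-dependent). No barrier is drawn for direct L→H, whose
rate is too rarely sampled to be reliable.

TDPs place one count per transition at (mean FRET of the departing run,
mean FRET of the arriving run), normalized by total transitions, with
0.02 bins on both axes — the same default bin width as FRET histograms.
Hill fits f(c) = baseline + amplitude·cⁿ/(Kⁿ + cⁿ) are performed for
the H- and L-state fractions only (the intermediate fraction is
conventionally not fitted; an override exists). The critical Mg²⁺ is
the first upward crossing of the fitted H fraction over the L fraction,
located on a log grid and refined by bisection; boundary cases are
flagged (range minimum when H leads everywhere, +∞ when it never does).

## Known estimator biases at finite time resolution

Frame discretization biases the dwell-counting estimator for
transitions that are rare or fast relative to Δt, and no correction is
applied (missed-event corrections are out of scope). Two mechanisms,
both quantified by simulation in the test suite:

* **Camera blur (integrated frames)**: a direct L↔H jump mid-frame
  produces one frame at intermediate apparent FRET, which the Viterbi
  path decodes as a one-frame I dwell roughly half the time, splitting
  the direct event into L→I→I→H. At the benchmark conditions
  (rates {2, 0.05, 1, 0.8, 0.1, 0.4} s⁻¹ at 25 ms) this depresses
  k_H→L by ~40% and k_L→H by ~20–30%, and inflates k_H→I by ~10–15%,
  while the four sequential-pathway rates stay within a few percent.
* **Double jumps (instantaneous sampling)**: two jumps within one
  frame interval (L→I→H) appear as a single direct transition,
  inflating k_L→H by ~35% at the same conditions (computable exactly
  from the matrix exponential of the generator).

Consequently recovery benchmarks assert 15% accuracy for the
sequential-pathway rates, and separate tests pin the documented *sign*
of the direct-rate biases. The same blur physics deposits ~0.2–0.4% of
TDP mass in the direct L↔H corners even when the generating direct
rates are exactly zero, so corner occupancy is asserted to be ≪1%
rather than literally empty. The cycle-closure residual inherits the
direct-rate biases (~0.2 kcal/mol at benchmark scale), which sets the
tolerance used in the detailed-balance diagnostic test.

## Movie front end

Spot candidates are local maxima above threshold; each is refined by
least-squares 2D Gaussian fitting (position, amplitude, width,
background) over the 9×9-pixel window centered on the maximum, with
window-border medians as the background start value and width bounds
rejecting non-spot fits; edge-clipped windows are skipped. Channel
registration accumulates votes over the translations implied by all
donor/acceptor spot pairs (0.5 px bins), takes the modal bin, matches
inliers one-to-one by nearest residual and refines the translation by
least squares; rotation refinement is off by default. Per-frame
intensities are background-subtracted Gaussian volumes 2π·A·σ² refit at
fixed position (per-frame shape refit by default, frozen-σ mode
available); diverged frames fall back to a windowed sum. Trace
selection requires signal in both channels, donor–acceptor Pearson
r ≤ −0.3 over the pre-bleach segment, and a single-step bleach if one
is detected. Coordinates are 0-based pixel indices of Gaussian
centers.

## Decay and SAXS

Decay traces are normalized as
F(t) = (F_exp(t)/F_exp(0)) / (F_con(t)/F_con(0)) and fitted with
F(t) = p + (1−p)·e^(−kt). The plateau p is fixed at 0 by default (a
plain single exponential); the free-plateau mode is appropriate for
strongly resistant constructs whose normalized fluorescence levels off
at the protected fraction — with p fixed, such traces yield an
effective (slower) rate. A configurable start time trims the
pre-enzyme binding window. Construct rates are reported relative to
the malachite-green-aptamer control at matched Mg²⁺, canceling the
Mg²⁺ dependence of Xrn1 activity; ratio uncertainties are propagated
in quadrature. Correlation reports (Pearson r, two-sided p, fitted
slope) default to linear axes with optional log transforms.

Guinier fits are weighted linear regressions of ln I on q² over the
largest low-q window satisfying q·Rg ≤ 1.3 (the community convention
for compact particles), iterated to self-consistency; Rg = √(−3·slope)
with delta-method standard errors. A non-negative slope raises "no
Guinier region". The dimensionless Kratky transform
(qRg)²·I(q)/I(0) vs qRg is parameter-free for ideal Guinier scatterers
(peak at √3, height 3/e), which the tests assert numerically.

## Problem sizes

Benchmark ensembles in the tests use 100–300 traces of 30–60 s at
25 ms/frame (1–7×10⁵ frames per condition) — enough that state-mean
errors are ≲0.003 and sequential-rate errors are dominated by the
systematic effects above rather than counting noise. The acceptance
script uses 300 traces × 30 s at one condition.

## Design choices that were genuinely open

* ΔG_H via the sequential (L↔I, I↔H) pathway, with the direct pair as
  a closure diagnostic rather than an average of the two routes.
* Dwell lifetimes by MLE rather than histogram fitting (both exposed).
* One shared HMM per condition rather than per-trace fits.
* Translation-only channel registration (rotation refinement exists
  but defaults off) — the simplest transform consistent with a
  two-channel split-view optical path.
* No γ/leakage corrections anywhere, so synthetic and analyzed FRET
  scales agree by construction.
* Every stochastic entry point takes a seed, and composite runs derive
  child seeds from a single master sequence, making manifests
  byte-reproducible.

## Limitations

Rates approaching 1/Δt are not recoverable (guarded by a warning, not
corrected); direct-rate estimates carry the biases quantified above;
the decay model is single-exponential (no processivity modeling); SAXS
support is limited to Guinier/Kratky (no pair-distance distributions or
shape reconstruction); channel registration does not model optical
distortion beyond a rigid transform.
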