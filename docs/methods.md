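# Methods

This note documents the models implemented in `sifi`, the assumptions and
numerical choices behind them, and what the synthetic-data generators do
and do not emulate.

## TCSPC forward model and reconvolution fitting

A recorded decay is modelled as the circular convolution, over one pulse
repetition period `T = 1/rep_rate`, of the normalised instrument response
with a discrete multi-exponential decay plus a flat background:

    F(k) = [IRF(·−s) ∗ m](k) + b,
    m(t) = Σᵢ Aᵢ exp(−t/τᵢ) / (1 − exp(−T/τᵢ))

The geometric factor accounts exactly for emission excited by all earlier
pulses wrapping into the observation window (at 10 MHz and ns lifetimes the
wrap is small but nonzero). The sub-channel timing shift `s` between IRF
and decay recordings is a free parameter applied by fractional-channel
linear interpolation of the IRF. The convolution is evaluated by FFT on the
full-period channel grid; an O(N²) direct-sum oracle in the test suite
confirms agreement to 1e-10 relative.

**Weighting.** The default χ² uses Neyman weights `1/max(n,1)`, the
convention of commercial TCSPC fitting software, so that "reduced χ² close
to 1" retains its conventional meaning. A signed Poisson-deviance option
(`weighting="mle"`) is provided for low-count work; at ≥5 counts per
fit-range channel the two agree closely.

**Fit range.** From 10 channels before the IRF peak to the last channel
whose counts reach `max(background estimate, 5)`. The background is
initialised from the pre-peak channels.

**Optimisation.** Trial lifetimes are log-spaced over the resolvable range
(amplitudes and background then solved by non-negative weighted least
squares), followed by bounded least-squares refinement of all parameters;
up to 5 restarts perturb the lifetime seeds, stopping early once the
reduced χ² is within 3·√(2/dof) of 1, i.e. statistically indistinguishable
from a correct model. Lifetimes are reported in descending order, and
component identity across samples (long/intermediate/short) is assigned by
that ordering. Fits whose adjacent lifetimes differ by less than a factor
1.2 are flagged as possibly degenerate.

**Acceptance of a fit.** Reduced χ² in `[1−δ, 1+δ]` (δ = 0.2 by default)
and a Wald–Wolfowitz runs test on the signs of the weighted residuals at
the 1% level; `select_n_components` returns the smallest component count
passing both, falling back (with a flag) to the best-χ² count. Noiseless
fits (χ²_red < 1e-6) are treated as perfect: their residuals are numerical
rounding, not noise, so the runs test is skipped.

**Average lifetimes.** ⟨τ⟩ = Σαᵢτᵢ/Σαᵢ (proportional to steady-state
intensity), τ̄ = Σαᵢτᵢ²/Σαᵢτᵢ (mean excited-state residence), and
fᵢ = αᵢτᵢ/Σαⱼτⱼ with Σfᵢ = 1. τ̄ ≥ ⟨τ⟩ always, with equality only for a
single effective component; the discrete-component description is a
modelling choice — three distinct microenvironments and narrow lifetime
distributions around three centres are not distinguishable at these photon
counts.

## Synthetic TCSPC data

The IRF is Gaussian with configurable FWHM (default 120 ps on 8 ps
channels), centred 0.6 ns into the window; only the FWHM of the real
response is specified by the measurement conditions, and a Gaussian is the
standard analytically checkable stand-in. Decays are generated by scaling
the analytic expected curve so the expected peak-channel count equals the
acquisition target (default 20 000) and drawing Poisson counts once —
reproducing the "accumulate to N peak counts" stopping rule without
event-by-event simulation. A flat background (default 1 count/channel) is
included. Not emulated: dead-time and pile-up distortions, afterpulsing,
IRF asymmetry and drift, and scattered-light contamination; passing
recovery tests therefore validates the estimator under ideal counting
statistics, not robustness to those instrument artefacts.

The reference photophysics preset for the abasic-series hairpins is
τ = (2.65, 1.3, 0.3) ns with populations (0.25, 0.25, 0.5) for the
stacked/intermediate/unstacked conformers; a single-lifetime preset stands
in for the non-isomerizing Cy3B control.

## Single-molecule traces and two-state kinetics

The hidden state is a two-state continuous-time Markov chain
(open ⇌ closed, rates `k_close`, `k_open`). Because photoisomerization
(~10 µs) and stacking exchange are far faster than the 50 ms frame time,
each frame reports a time-average: the generator integrates the exact
within-frame occupancy of the chain, so transition frames carry genuinely
intermediate intensities. Emission is Poisson per frame (optionally plus
Gaussian read noise); photobleaching is a single irreversible exponential
step to the background level.

**Segmentation.** A two-component Gaussian mixture on the intensity
histogram sets the threshold at the midpoint of the component means. A
trace is declared static when the one-component model wins by BIC or the
modes are closer than 2 pooled standard deviations. Terminal photobleaching
is detected before the mixture fit, as a trailing run (≥ 5 frames) below
30% of the early-trace level; bleached frames are excluded everywhere. A
hidden-Markov segmenter would be the natural extension for poorly separated
levels; at the 2.5× contrast of interest the threshold is accurate to
~99.6% of frames.

**Dwell times and rates.** Consecutive same-state runs become dwells; the
first and last dwell of each trace are flagged censored and excluded from
fitting by default. Rates are estimated by treating the frame-labelled
sequence as the chain *sampled* at the frame period, for which the
per-frame flip probabilities are exact functions of (k_open, k_close);
inverting them corrects both the half-frame discretisation bias and events
missed entirely because a dwell was shorter than a frame (>20% of dwells at
k·Δt = 0.25). Standard errors come from the geometric-likelihood Fisher
information by the delta method. A histogram least-squares mode (1-frame
bins, empty leading bin excluded, √n weights) is kept for parity with
conventional dwell-histogram fitting. Dwells are pooled across molecules
rather than averaged per molecule, matching how pooled dwell histograms are
fitted in practice.

**Censoring.** Simulation with ground-truth dwell sequences shows that for
exponential dwells the censored boundary dwells are *not* short-biased —
memorylessness plus the inspection paradox make their mean slightly exceed
1/k — while interior dwells in a finite window are selection-biased short
by ≈ 2/(kT). Excluding censored dwells is nevertheless the default: it is
the safe choice for non-exponential kinetics and for last dwells truncated
by photobleaching rather than by the kinetics. The practical consequence,
asserted in the tests, is that any dwell-based estimate is biased high for
windows much shorter than ~50 mean dwells.

**Enhancement factor.** The closed/open ratio of background-subtracted
state-conditional mean intensities, with frames adjacent to a state switch
excluded (they mix both levels and would bias the ratio toward 1); the
standard error propagates the two conditional-mean errors.

## Accessible volume

The duplex is an ideal B-form helix (rise 3.4 Å, twist 36°/bp) coarse-
grained to three spheres per nucleotide — backbone (radius 8.9 Å from the
axis, clash 3.2 Å), sugar (6.3 Å, 2.8 Å) and base (2.4 Å, 3.3 Å) — with
the two strands' spheres at ±(77°, 55°, 15°) from each base pair's
reference azimuth, placing the backbones 154° apart across the minor
groove. Gap features delete the named nucleotides' spheres; an overhang
deletes one strand's spheres while the single-stranded partner stays in
place; a nick is sterically silent. The dye attachment point (pyrimidine
C5) sits at 4 Å radius on the major-groove face of its base pair.

The dye is a sphere on a linker of maximum length L. A grid point (spacing
0.9 Å by default) belongs to the accessible volume when (a) a clash-free
path of width `linker_width` and geodesic length ≤ L connects it to the
attachment, and (b) the dye sphere fits there without clashing. Geodesics
are computed by Dijkstra on the 26-connected clash-free grid, seeded with
the exact Euclidean distance for every point in unobstructed line of sight
of the attachment — this removes the lattice-metric overestimate, makes the
free-space volume match the analytic sphere to <0.5%, and leaves obstructed
distances as tight upper bounds. The attachment nucleotide's own base
sphere is excluded from the clash set (the linker is bonded to it; in the
coarse model its sphere would bury the attachment atom).

Default linker/dye parameters (20 Å length, 4.5 Å width, single 3.5 Å dye
radius, in the style of FRET-positioning accessible-volume calculations for
a sulfo-Cy3 NHS-ester dye on its long linker) are modelling assumptions
recorded in the configuration, not measured values; an AV3-style triple
radius can be supplied. **Axial reach** counts the base-pair centres the
dye centre can come level with along the helix axis (floor of max |Δz| /
rise): on a blunt duplex the measured maximum displacement is 15.3 Å =
4.5 bp, i.e. the dye reaches the fourth base pair away but not the fifth.
**Stacking fraction** is the share of the AV within 5 Å of the junction
terminal base sphere's surface, restricted to within 9 Å of the helix axis
so that points on the outer helix surface — near in distance but not on the
exposed stacking face — are not counted. All conclusions drawn from this
model are coarse geometric ones (reach, ordering of junction proximity);
it is not an all-atom description.

## Abasic-position profiles and periodicity

The generator's ground truth for the intensity-weighted lifetime at abasic
position x (bp from the nick, 1-based) is

    τ(x) = b + A cos(2πx/P − φ) e^{−x/λ} − d·exp(−(x−1)²/2w²)

with defaults b = 1.9 ns, A = 0.12 ns, P = 10 bp, φ = π (peak at 15 bp),
λ = 25 bp, and a near-nick dip of depth 0.45 ns, width 2 bp. The cosine-
times-exponential is a stand-in parametric shape, not a mechanistic claim:
the measured profile peaks mid-range and returns to baseline, and the
damping expresses that the modulation fades over roughly two helical
turns. The damping default was initially set shorter (12 bp); that choice
suppressed the far-field modulation to ~2× the replicate SEM, inconsistent
with the clearly resolved peak the experiment shows at 15 bp, and was
revised once to 25 bp.

Each of the 12 positions (1–21 bp) carries 13 replicate decays split 4/4/5
across 3 experiments, plus an identical fully complementary control
(position 0). A replicate's target lifetime is truth + N(0, 0.05 ns),
realised *physically* as population exchange between the stacked and
unstacked conformers (intermediate population held at 0.25, component
lifetimes jittered 2% per decay to mimic sample-to-sample variation) — so
the fractional intensities inherit the stacked/unstacked anticorrelation by
construction. In `decays` mode every replicate becomes a full simulated
TCSPC decay (2048 × 8 ps channels, a window spanning >6 lifetimes of the
slowest component, keeping the 169 per-decay fits fast) routed through the
reconvolution fitter; `summary` mode emits the exact per-decay summaries
for fast statistical tests.

**Aggregation.** Per-position mean ± SEM over decay-level summaries;
positions with fewer than 2 replicates are dropped with a warning; the
experiment grouping is preserved for bootstrapping (experiments resampled,
then decays within experiments).

**Period fit.** Near-field positions (< 6 bp) are excluded by default —
there the dye inserts directly into the abasic site, a different mechanism
from through-backbone modulation (the invariance of the fitted period to
this exclusion is tested). For fixed (P, λ) the model is linear in
(baseline, A cos φ, A sin φ), so the fit is a grid search over P ∈ [6, 16]
bp in 0.1 bp steps crossed with a coarse damping grid, with weighted linear
least squares inside, then bounded nonlinear refinement of all five
parameters. Weights are 1/SEM (median-SEM fallback where a bootstrap
resample leaves a single replicate). An amplitude consistent with zero
(|A| < 2·SE) flags "no significant modulation". With 8 far-field positions
the five-parameter fit is weakly identified at low signal-to-noise; at the
default conditions the fitted period lands within ±1 bp of truth in
≥ 93% of runs for true periods 8–12 bp.

**Peak and crossings.** The peak is the argmax of the fitted model beyond
the exclusion window; baseline crossings are sign changes of (profile −
control) located by linear interpolation, with an explicit flag when the
profile is identical to the control.

**Anticorrelation.** Pearson r between per-position mean f_short and
f_long, with a replicate bootstrap CI, computed for all positions or for
near-field (≤ 5 bp)/far-field windows separately (≥ 5 positions required).

## Spectroscopy utilities

Beer–Lambert concentration `c = A/(εl)` with ε(Cy3, 550 nm) =
150 000 M⁻¹cm⁻¹; absorbances above 0.1 trigger an inner-filter warning,
the working limit for undistorted fluorescence intensities.

## Reproducibility and suite scale

Every generator is a deterministic function of its integer seed, and the
full CLI pipeline is byte-identical across reruns at a fixed seed. The test
suite sizes its simulation studies to run in minutes on one CPU: 20-seed
fit ensembles for the recovery and χ² statistics, 100-molecule trace
ensembles (~9500 transitions), 50–100 seeded runs per period-recovery
condition, and a single end-to-end 169-decay profile. `scripts/acceptance.py`
re-simulates everything from scratch under its `--seed` and reports the
recovered quantities.

## Known limitations

* Discrete exponential components only; no lifetime-distribution (MEM) or
  global multi-dataset fitting (the per-sample lifetime variation that
  makes global fits fail is part of the generator).
* Threshold segmentation assumes well-separated intensity levels; an HMM
  hook is the natural extension below ~1.5× contrast.
* The salt dependence of hairpin kinetics is not modelled: closed fraction
  and rates are direct parameters.
* The AV model is coarse-grained geometry, not an all-atom or MD
  description; no FRET distance calculations are included.
* The damped cosine is a descriptive model of the position profile; the
  fit estimates phase freely and makes no claim about the mechanical origin
  of the modulation.
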