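# Methods

This note documents the models, conventions, parameter choices, and
known limitations behind `cosmofret`. It is the package's account of
its own science; every number quoted as an output here is computed by
the test suite or the example scripts.

## The simulated reaction

Each surface location evolves independently in continuous time over a
record of `n_frames_per_color × frame_interval` seconds (default
600 × 2.6 s = 1,560 s ≈ 26 min, the alternating green/red excitation
clock of the emulated experiments: ~1.3 s per frame, 2.6 s per
same-color frame).

- **Specific arrival.** A DNA is active with probability `A_f`
  (`active_fraction`, default 0.8). Active DNAs draw the first
  Mcm2-7–Cdt1 arrival from Exponential(`k_specific`); the default
  0.0047 s⁻¹ corresponds to an unphosphorylated-ORC reaction, and
  `phos_orc_config()` switches to 0.0020 s⁻¹ with the other
  phosphorylation-dependent overrides.
- **Background.** Every location (DNA or control) receives nonspecific
  surface binders as a Poisson process at `k_background`
  (default 2×10⁻⁴ s⁻¹) with exponential dwells of mean 5 s. The dwell
  family of nonspecific binding is not constrained by the emulated
  data; exponential is assumed.
- **Ordered sub-events.** Cdc6 arrives an exponential lead (mean 20 s)
  before the first Mcm2-7 and departs an exponential dwell (mean 30 s)
  after it, delimiting the OCCM. Cdt1 departs after an exponential
  wait (mean 90 s); with probability `p_productive` the release is
  productive (Cdt1-only; 0.47 unphosphorylated, 0.15 phosphorylated),
  otherwise Cdt1 and its Mcm2-7 leave at the same instant (offset
  exactly 0 s — detecting "simultaneous" is purely an analysis-side
  tolerance question).
- **Post-release retention and the MO.** A productive Mcm2-7 is
  retained with exponential mean 584 s when the MO intermediate forms
  (probability `p_mo` = 0.45 given a productive release, 0 when ORC is
  phosphorylated) and mean 100 s otherwise. 584 s is the scale of the
  long post-Cdt1 retentions in the emulated system; the retention of
  molecules that never form the MO is an order-of-magnitude choice.
- **Gate dynamics.** The Mcm2-5 gate is a two-state CTMC over each
  first-Mcm2-7 episode: open→closed at 0.033 s⁻¹ (closing typically
  25–45 s after arrival), closed→open at 0.04 s⁻¹ before the MO forms
  and 0.001 s⁻¹ after (MO-dependent stabilization). Apparent FRET
  centers: 0.20 open, 0.37 closed; the ORC–Mcm2-7 MO assay uses 0.15
  (OCCM) and 0.65 (MO).
- **Second events.** Given an MO, with probability 0.75 a second Cdc6
  (exponential delay, mean 30 s) and then a second Mcm2-7 (mean 60 s)
  arrive; the second hexamer is collapsed to a retained terminal state
  (both hexamers persist to the record end, flagged salt-stable).
  Double-hexamer internals and the ORC flip are not simulated.
- **Censoring.** Everything extending past the record end is clipped
  and flagged censored.

RNG discipline: a single root seed; per-location substreams spawned
deterministically, with separate spawn keys for trace rendering and
image rendering, so timelines, traces and images are bit-reproducible
and independent of iteration order.

## Rendering

Traces discretize continuous occupancy with a half-open [start, end)
convention: a fluorophore contributes to a frame iff its visible
interval covers at least half the frame. This keeps noiseless
trace→interval round trips exact and is verified as such. Labeling is
Bernoulli per fluorophore (default efficiency 1; set
`label_efficiency={"Cdc6": 0.8}` etc. to emulate incomplete labeling)
and photobleaching is a per-fluorophore exponential clock (default
10⁻⁴ s⁻¹, the triplet-quencher regime) that ends fluorescence but not
occupancy — the real confound. FRET pairs split donor-excited emission
so A/(A+D) equals the current state center exactly at zero noise;
`efret_sd` (0.05) adds frame-wise apparent-FRET jitter and `noise_sd`
(0.15 single-fluorophore units) adds camera noise per channel.

Image stacks render pixel-integrated Gaussian PSFs (σ = 1.2 px) at
drifting positions with Poisson + read noise, plus bright fiducial
beads visible in every channel and fluorescent impurities in the
green/red reference frames.

## Analysis conventions

- **Spot classes.** DNA = blue-reference detections, impurities =
  green+red-reference detections, fiducials = bright coincidences of
  the two (brightness ratio ≥ 2 over the typical DNA spot — a dim
  coincidence is a DNA sitting on an impurity and is excluded with
  reason "impurity colocalization"; default exclusion radius 1.5 px).
  DNA pairs closer than 5 px are excluded as unresolvable. Non-DNA
  controls are grid-sampled ≥ 5 px from every DNA.
- **Drift.** Per-frame translation = mean of fiducial windowed
  centroids (local-border-median background subtraction), tracked
  recursively, smoothed with a 5-frame running mean, reported relative
  to frame 0.
- **Extraction.** The 5×5 window follows the *fractional*
  drift-corrected position: the integrated flux is computed from the
  bicubic/quintic-interpolated cumulative image, which makes the
  extracted intensity independent of where the window edges fall
  within a pixel (integer-rounded windows modulate the flux by ~2% as
  drift accrues). Background = per-frame median of the 9×9-minus-5×5
  annulus sampled at the fractional position, ×25, smoothed with a
  9-frame running median. The annulus abuts the window, so PSF tails
  couple a percent-level, slowly varying term into the background
  estimate; transients of that size appear for a few frames around
  binding transitions.
- **Normalization.** Traces are already background-subtracted, so the
  residual baseline is taken from an intensity mode near zero (within
  3 noise SD, estimated from successive differences) or left at 0 — a
  trace bound nearly the whole record must not have its bound level
  mistaken for background. The unit level prefers a (u, 2u) KDE peak
  pair (bound levels are integer multiples of one fluorophore), else
  the lowest prominent mode.
- **Interval calling.** Hysteresis thresholds 0.5/0.3 of the unit
  level; level ≥ 1.5 marks stoichiometry-2 stretches; episodes
  touching the last frame are censored. No minimum episode length is
  imposed at this stage; noisy-data analyses use `min_frames=2`.
- **OCCM identification.** An Mcm2-7 episode counts as an OCCM landing
  when a Cdt1 interval starts within one frame of the Mcm2-7 arrival
  (the complex arrives as one unit); this separates specific landings
  from background events automatically, where the emulated analysis
  relied on manual curation.
- **Release classification.** Simultaneous iff the Cdt1 and Mcm2-7 end
  times differ by ≤ 1 frame (≈2.6 s) by default; the tolerance is a
  parameter and the 0/1/2-frame sensitivity is a packaged diagnostic
  (`classify_release(..., tolerance_frames=n)`). A censored Cdt1
  signal is unresolved and excluded from denominators.
- **Second events.** Second Mcm2-7 = stoichiometry-2 stretch of ≥ 2
  frames during the first episode (single-frame doublings are
  indistinguishable from noise), classed short/long at 15 s, counted
  once per DNA using the longest. A brief *background* binder stacked
  on the specific Mcm2-7 is genuinely indistinguishable from a short
  second landing; the automated step-doubling rule is a stand-in for
  the emulated study's manual identification and this disagreement
  mode is inherent. Second Cdc6 = a new Cdc6 interval starting after
  the first ends while the first Mcm2-7 persists; when comparing to
  simulation truth under incomplete labeling, expectations are scaled
  by the configured Cdc6 label efficiency.
- **E_FRET.** Valid frames require both fluorophores present (total
  donor-excited emission and directly excited acceptor both called
  bound), exclude the first and last frame of each episode, and stop
  at a second-Mcm2-7 arrival. No gamma/leakage/direct-excitation
  corrections — the apparent ratio is the quantity of interest. State
  calls use strictly consecutive valid frames; runs interrupted by a
  single masked frame are *not* bridged.
- **Mixture fitting.** ML fit of the five-parameter two-Gaussian
  density to samples in [0.1, 0.7]; initialization by quantile split
  at the median with 10 jittered restarts, best likelihood wins, ties
  to the lower μ_low; σ floored at 0.01 and flagged; μ ordering
  enforced by relabeling. By default the *untruncated* density is fit
  to in-window samples (the simplest reading of the emulated
  procedure); `truncated=True` renormalizes the likelihood to the
  window. The window clips ~2% of the low component's tail, biasing
  σ_low slightly under the plain mode, so parameter-recovery tests use
  the truncated mode; both modes agree on the centers to < 0.01 for
  interior mixtures. Bootstrap SEs resample individual frame values
  (molecule-level bootstrap is available as an option).
- **Survival and proportions.** Kaplan-Meier with Greenwood 95% CI
  (via lifelines); median = earliest t with S(t) ≤ 0.5, reported as a
  lower bound under censoring and as "> record length" when S never
  reaches 0.5. Proportions use the binomial SEM. Note that a
  published-style "49% ± 7% (94/191)" is *not* reproduced by the
  binomial SEM (≈3.6%); the error model behind such larger quoted
  uncertainties (possibly a molecule- or field-level bootstrap) is not
  specified by the emulated analysis, and this package reports the
  binomial value rather than silently matching.

## Problem sizes and test design

Validation uses desk-scale problem sizes chosen to give clean
statistical power: 10,000-location sampling checks for closed-form
oracles, 1,000 DNA + 1,000 control locations for arrival-rate recovery
(2-SE criterion), 400–900 locations for release-branch recovery (3
binomial SE), and mixture recovery at three window sample sizes (900 /
1,700 / 1,500 frames — the scale implied by ~160 molecules sampled at
2.6 s over 0–15 / 15–50 / 50–100 s windows) with 1,000-sample
bootstraps. Because ML mixture parameters are strongly correlated, a
single 3-SE center check fails by chance in ~3% of draws; the recovery
test therefore requires 2 of 3 independent replicates to pass, which
keeps the criterion while making the test statistically meaningful.

## What passing tests do and do not show

The simulator emulates the *structure* of the real data — ordered
stochastic events, censoring, background binding, bleaching, partial
labeling, frame quantization, camera noise, drift — with exponential
waiting times throughout. It does not emulate triplet blinking,
nucleotide-state-dependent kinetics, non-exponential dwell families,
spatially varying illumination, or the high-salt-wash biochemistry
(represented only as a per-event salt-stable flag). Parameter-recovery
results therefore certify the analysis implementation, not the
biological model; on real data the same code faces confounds (e.g.,
bleaching-vs-release ambiguity, manual second-Mcm curation) that the
clean-condition tests deliberately switch off. Real-data medians such
as the long post-Cdt1 retentions depend on the mixture of MO and
non-MO pathways and on censoring and are not targets of the synthetic
validation.

## Numerical choices

Arrival-model stage 2 uses Nelder-Mead from three starts (A_f ∈
{0.5, 0.9, 0.99}) with SEs from a finite-difference observed-information
matrix; k_ns ≥ k_a is flagged as low signal. The least-squares
comparison fit on the empirical curve agrees with the MLE within 1 SE
on clean simulations and is exposed as `fit_first_binding_ls`. The
likelihood-ratio screen for "any specific binding" references χ²(2) and
is conservative (boundary null). Heat-map slice normalization divides
by the trapezoidal area per slice (exactly 1 ± 10⁻⁶ by construction on
the default 401-point E_FRET grid); the remaining-fraction curve is the
raw step fraction of molecules still contributing valid frames, with no
smoothing.
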