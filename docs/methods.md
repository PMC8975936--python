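# Methods

This note documents the models and numerical choices behind `optocontract`,
what the synthetic generators do and do not emulate, and the known
limitations of each component.

## Dense optical flow (`flowcore`)

**Model.** Each grayscale frame is locally approximated by a quadratic
polynomial, f(x) ≈ xᵀAx + bᵀx + c, estimated per pixel by weighted least
squares with a Gaussian applicability of standard deviation σ (default
1.5 px, kernel radius ⌈3σ⌉). Because the applicability is symmetric, the
6×6 normal matrix of the basis {1, x, y, x², y², xy} decouples into a 3×3
block for (c, x², y²) and scalars for x, y, xy; the solution is computed by
nine separable correlations and one precomputed 3×3 inverse. On images that
are polynomials of degree ≤ 2 the expansion is exact (to round-off) at
pixels whose support window lies inside the image; a replicate-padding
border band of width ⌈3σ⌉ is only approximate.

**Displacement estimation.** For a local translation d between frames the
two expansions give the constraint A d = Δb, A = (A₀ + A₁∘warp)/2,
Δb = −½(b₁∘warp − b₀) + A·d_prior, where ∘warp denotes bilinear sampling of
the second frame's coefficients at x + d_prior. Pointwise constraints are
aggregated over a Gaussian averaging window (default 15 px, σ = (w−1)/4)
and the resulting 2×2 normal system G d = h is solved in closed form per
pixel. G is regularized by +εI with ε = 10⁻⁶·tr(G); pixels with condition
number above 10⁶, non-positive determinant, or an out-of-bounds warp are
masked invalid and retain the prior. Displacements larger than the
expansion support are handled by a coarse-to-fine pyramid (default 3
levels, scale 0.5, 3 fixed-point iterations per level; flow upsampled and
rescaled between levels).

**Readout.** |V| is the mean of √(dx²+dy²) over valid pixels (optionally
restricted to an ROI). It is invariant to additive offsets and
multiplicative gain of both frames, because both A and b scale together and
the regularization scales with tr(G).

**Accuracy.** On band-limited noise textures the engine recovers global
translations up to 4 px with mean endpoint error well below 0.2 px, and
agrees with an independent dense-flow implementation
(`skimage.registration.optical_flow_ilk`) to a median of ~0.02 px on
synthetic contracting-cell pairs. One known bias: |V| averages vector
*magnitudes*, so where true displacements are small relative to the
estimation jitter (~0.02 px), E|d̂| > |d| and the readout runs a few
percent high; on the default synthetic movie the peak |V| is ~10% above
truth. This is a property of the |V| statistic itself, not of the solver.

**Hyperparameters.** The defaults (3 levels, scale 0.5, 3 iterations,
σ = 1.5 px, window 15 px) are conventional for this algorithm family and
are exposed in `FlowParams`; the source experiments did not require more
than a few px/frame of motion, for which these settings are comfortable.

## Trace quantification (`traces`)

- **Contraction events.** One event per pacing cycle: amplitude = peak |V|
  in the cycle minus the 10th percentile of |V| in the 200 ms before the
  pacing pulse (robust to slow drift); negative values clip to 0.
  Contractility change is 100·(post−pre)/pre over n_pre = n_post = 5 cycles
  around the light pulse.
- **Beat-rate responses.** Instantaneous rate is 60/RR. The embryoid-body
  readout uses a 30 s pre-stimulus baseline and reports the (first) maximum
  post-stimulus rate and its latency. The intact-heart readout averages the
  RR intervals of 7 sinus beats before illumination and of 7 sinus beats
  centered on the fastest sinus beat after illumination; premature beats
  are removed *before* windowing, so windows extend across excluded
  extrasystoles — which makes the statistic exactly invariant to flagged
  extrasystoles. Centering on the fastest beat is one of two defensible
  readings of "around the peak"; it is a documented interpretation.
- **Extrasystole flagging.** Sequential rule: each beat's interval is
  measured from the previous *sinus* beat and flagged premature when
  shorter than 0.7× the running median of the last 7 sinus intervals. A
  centered-median variant also flags the compensatory interval after each
  premature beat, which is why the sequential form is used. The 0.7
  threshold is a standard premature-beat heuristic and is configurable.
- **Inhibitory (rate-slowing) responses.** RR traces smoothed by 1 s
  averaging; statistic = minimum rate in the 30 s after illumination
  relative to the minimum in the 30 s before, signed percent.
- **ΔF/F₀.** F₀ is the mean of the first 5 background-subtracted samples
  ("start of measurement" needs a finite window); the trace is
  (F−bg−F₀)/F₀. Invariant under joint gain on F and background.
- **Decay half-time.** Default is a single-exponential fit after the event
  with half-time ln2·τ; a linear-fit variant is provided because both
  conventions exist for cAMP luminescence decays. The exponential form is
  the default as it is the one used for the reported 50%-decay statistic.
- **Force responses.** Pulse-type stimuli (light, field stimulation): max
  force from onset to 10 s after offset, minus the pre-stimulus mean. Bath
  applications (carbachol, K⁺): max after minus max before.

## Stimulus–response models (`respmodels`)

- **4PL (Hill).** R(d) = bottom + (top−bottom)/(1+(half/d)^slope). On a log
  axis the model is parameterized in log₁₀(half) so the optimizer works on
  the plotted coordinate; initialization: slope ±1 by data trend, half at
  the geometric median dose, top/bottom at the response extremes; half
  bounded to [min dose/10, max dose·10]. R² = 1 − SS_res/SS_tot on the
  fitted axis. Standard error of half is delta-method transformed back to
  the dose scale. Equivalent (top/bottom swapped, slope negated) solutions
  are normalized to top ≥ bottom. Constant responses raise a fit failure;
  poor fits (R² < 0.5) warn.
- **Govardovskii template.** A1 alpha-band constants A = 69.7, B = 28,
  b = 0.922, C = −14.9, c = 1.104, D = 0.674,
  a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940). The beta band is omitted:
  the fitted data span 370–550 nm where the alpha band dominates, and the
  template is used as a shape prior, not an absorbance model. λmax is
  grid-seeded at 1 nm over 350–600 nm and refined by bounded scalar
  minimization; the amplitude scale has a closed-form solution per λmax, so
  the fit is deterministic.
- **Recovery.** One-phase exponential toward a plateau;
  half-recovery = ln2·τ by identity. Fits with R² ≤ 0.7 are returned with
  `included=False` rather than discarded silently.
- **Duty cycle.** Duty = pulse length × repetition rate (%). Peak forces
  are baseline-subtracted (mean cyclic height of 1 min of endogenous
  activity) and normalized to continuous illumination before the Hill fit;
  the fit is unconstrained (a bottom = 0 constraint can be imposed by
  pre-anchoring but was not needed on the generator data).

## Synthetic generators (`synthdata`)

All generators are deterministic per seed and export ground truth.

- **Contracting video.** A textured elliptical "cell" (band-limited noise,
  strong inside, weak outside) on a canvas warped by a time-dependent
  radial scaling about the cell center; the boundary point on the
  semi-major axis moves by `peak_displacement_px` (default 2 px) at full
  contraction, following a raised-cosine time course over 40% of each beat
  cycle (default 1 Hz at 50 fps). The per-frame-pair displacement field is
  analytic (d(x) = (s₁/s₀−1)(x−c)), so the exported mean displacement is
  exact. Not emulated: out-of-plane motion, photobleaching, shot noise
  statistics, sarcomere-level inhomogeneity — so flow-accuracy results on
  these movies bound performance on clean recordings, not on low-SNR data.
- **Force trains.** Activation state A rises during light (τ = 60 ms) and
  decays in the dark (τ = 1 s); a desensitization resource D depletes in
  proportion to A (τ = 8 s) and recovers while the receptor is idle
  (τ = 6 s, i.e. ~4 s half recovery); force is (A·D) convolved with an
  alpha-function kernel (τ = 0.8 s). Consequences, all emergent rather than
  programmed: pulse trains summate toward the continuous-illumination bound,
  the duty-cycle response is Hill-like with a half-max of ~4.6% at 1 Hz,
  desensitization grows with pulse duration, and paired-pulse ratios after
  a depleting pulse follow ≈ 1−exp(−Δt/6 s). Depletion is tied to receptor
  drive rather than to the light gate itself because a purely light-gated
  resource lets high-duty trains slightly exceed the continuous bound.
- **Beats.** Renewal process with rate 60/RR from a base rate (default
  300 bpm, a mouse heart) plus an exponential-approach response to light;
  optional RR jitter; extrasystoles inserted at 45% of the local RR without
  resetting the sinus schedule, labels exported.
- **Plates.** Category mixture (double/agonist-only/light-only/inactive)
  per compound; true inhibitions ~N(80, 8)% for affected channels, N(0, 4)%
  otherwise; raw signal = DMSO level × (1−inh/100) + read noise (additive
  Gaussian default, log-normal option). Each plate carries 16 DMSO, 2
  full-block and 2 receptor-block wells. Not emulated: edge effects,
  dispense failures, compound fluorescence artifacts.

What passing round-trip tests show is that the analysis operations invert
the generator models at realistic noise levels — not that they are robust
to every artifact of real instruments.

## Screening analysis (`hts`)

Per-plate, per-channel linear anchoring: DMSO mean → 0% inhibition,
full-block control mean → 100% (receptor-block wells are carried through as
records). Classification thresholds each channel at 50% inhibition by
default — consistent with the observation that the light-only candidates in
the source screen all showed <50% inhibition — and is configurable; a
robust-Z style cut would be a reasonable alternative but no statistical
rule was published. Summary percentages use half-up decimal rounding to two
places (the convention that reproduces printed screen fractions such as
0.17% and 1.35%). Frequent-hitter/PAINS status is accepted as an external
annotation, not computed, since compound structures are unavailable.

## Problem sizes used in tests

The default test suite and acceptance script run on deliberately small
problems chosen to exercise every code path: 64–100 px frames and movies of
60–150 frames for the flow engine, 5–16-point ladders for fits, 10⁴-well
plates for mixture recovery, 100 simulated specimens for the recovery-τ
sweep. These sizes are the package's own test design; all operations accept
full-size data.

## Known limitations

- The flow engine assumes locally smooth, brightness-conserving motion;
  it is not suitable for blinking fluorescence or large (> ~¼ frame)
  displacements.
- `detect_contractions` requires a pacing protocol; spontaneous-activity
  event detection beyond beat-frequency estimation is out of scope.
- The spectral fit estimates a single alpha-band pigment; mixtures or beta
  bands are not modeled.
- Hit classification is a fixed-threshold rule on normalized inhibition;
  it does not model plate-level spatial artifacts.
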