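# optocontract

Analysis toolkit for optogenetic Gq-signaling experiments: video-based
contractility quantification by dense optical flow, trace-level readouts
(beat rate, isometric force, Ca²⁺ fluorescence, GIRK currents), parametric
stimulus–response fitting (Hill/4PL, visual-pigment action-spectrum
templates, desensitization/recovery kinetics), and dual-stimulus
high-throughput screening (HTS) hit classification. Every input class has a
seeded synthetic generator with exported ground truth, so the full pipeline
is testable end to end without instrument data.

It is written for labs using UV-sensitive opsins (e.g. human Neuropsin) to
drive Gq/PLCβ signaling in cardiomyocytes, smooth muscle and HEK-cell
assays, and for screening groups replacing pharmacological receptor
activation with light.

## What it computes

**Contractility (`flowcore`).** Every frame neighborhood is approximated by
a quadratic form f(x) ≈ xᵀAx + bᵀx + c with Gaussian applicability
(Farnebäck polynomial expansion). For two frames related locally by a
translation d, the expansions satisfy A d = Δb with A = (A₀+A₁∘warp)/2 and
Δb = −½(b₁∘warp − b₀) + A·d_prior; the per-pixel 2×2 normal system is
aggregated over a Gaussian window and solved coarse-to-fine over an image
pyramid. The scalar readout is |V|, the mean displacement-vector magnitude
per frame pair — a brightness-invariant contraction signal.

**Stimulus–response models (`respmodels`).**
- 4PL/Hill: R(d) = bottom + (top−bottom)/(1 + (half/d)^slope), fitted on a
  log axis for intensities and concentrations. Yields eLi50 (half-maximal
  effective light intensity), IC50/pIC50 = −log₁₀ IC50, half-maximal pulse
  duration and duty cycle.
- Action spectra: the Govardovskii A1 alpha-band template
  S(x) = 1/(e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D), x = λmax/λ, fitted
  over (λmax, scale) by grid-seeded least squares.
- Desensitization: paired-pulse ratios and one-phase recovery
  y(t) = plateau − (plateau−y₀)e^{−t/τ} with half recovery ln2·τ and an
  R² > 0.7 inclusion filter.
- Light energy dose: intensity × duration in µW·s/mm².

**Trace rules (`traces`).** Per-pacing-cycle contraction amplitudes and
percent contractility change around a light pulse; beat-rate responses
(7-sinus-beat averages with premature-extrasystole exclusion; 1-s-smoothed
RR minima for inhibitory receptors); ΔF/F₀ normalization; exponential decay
half-times; force response windows (max force from stimulus onset to 10 s
after its end, minus baseline).

**Screening (`hts`).** Per-plate control anchoring (DMSO → 0% inhibition,
full channel block → 100%), quadrant classification into double /
agonist-only / light-only / inactive at a per-channel threshold (default
50%), summary fractions, and per-compound concentration–response IC50s.

## Worked example

```python
import numpy as np
from optocontract.synthdata import gen_contracting_video, gen_dose_response
from optocontract.flowcore import video_to_trace
from optocontract.traces import (StimulusProtocol, StimulusEvent,
                                 detect_contractions, beat_frequency)
from optocontract.respmodels import hill_fit

# a 3 s movie of a textured cell beating at 1 Hz, 2 px peak boundary motion
stack, truth = gen_contracting_video(fps=50.0, beat_rate_hz=1.0,
                                     peak_displacement_px=2.0,
                                     seed=1, n_frames=150)
trace = video_to_trace(stack)
print(f"beat frequency: {beat_frequency(trace):.2f} Hz")
print(f"peak |V|: {trace.v.max():.3f} px/frame "
      f"(truth {truth['mean_disp'].max():.3f})")

pacing = StimulusProtocol([StimulusEvent(t_on=k, duration=0.002, kind="pacing")
                           for k in range(3)])
amps = [e.amplitude for e in detect_contractions(trace, pacing)]
print(f"contraction amplitudes: {np.round(amps, 3)}")

# light-intensity dose-response at the HEK sensitivity
data, _ = gen_dose_response(3.0, [0.1, 0.3, 1, 3, 10, 30, 100, 300])
print(f"eLi50: {hill_fit(data).half_max_dose:.3f} uW/mm^2")
```

Output:

```
beat frequency: 1.00 Hz
peak |V|: 0.177 px/frame (truth 0.160)
contraction amplitudes: [0.177 0.177]
eLi50: 3.000 uW/mm^2
```

The beat frequency equals the generator rate exactly; the peak |V| sits
within the expected small-displacement bias of magnitude averaging (~10%
here); the noiseless Hill fit returns the generating eLi50.

The same operations are available from the shell:

```bash
optocontract synth video --seed 1 --out scratch/movie/
optocontract flow --input scratch/movie/video.tif --fps 50 --out trace.csv
optocontract fit hill --in dose.csv --out fit.json
optocontract hts classify --in plate.csv --threshold 50 --out hits.csv
```

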