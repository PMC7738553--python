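# iridoptics

Structural colour and cell behaviour of zebrafish iridophores, as a
tested, seeded Python library.

Adult zebrafish stripes and interstripes owe their colours partly to
two architecturally distinct iridophore subtypes ("crystallotypes").
Loose iridophores in stripes hold 20–30 parallel guanine platelets of
thickness 27 ± 7 nm separated by cytoplasm gaps of 131 ± 24 nm — a
near-periodic Bragg reflector that looks blue.  Dense iridophores in
interstripes hold 30–40 platelets (25 ± 8 nm) with highly variable
spacings (186 ± 81 nm) — a disordered stack with broad, silvery
reflectance.  This package models those stacks and the statistics
around them:

- **`tmm`** — characteristic-matrix reflectance of a multilayer.  Each
  layer *j* carries the 2×2 matrix
  `m_j = [[cos βⱼ, −(i/nⱼ) sin βⱼ], [−i nⱼ sin βⱼ, cos βⱼ]]` with
  `βⱼ = (2π/λ) nⱼ dⱼ`; the stack matrix is the ordered product over the
  2k layers of k crystal/cytoplasm double layers, and the reflectance
  is `R = |((m₁₁+m₁₂) − (m₂₁+m₂₂)) / ((m₁₁+m₁₂) + (m₂₁+m₂₂))|`
  (an `|r|²` convention is available behind a flag).  Disorder is
  handled by Monte Carlo: reflectance averaged over 500 stacks sampled
  from the measured thickness distributions, at normal incidence or
  across 0–70°.
- **`stack_synth`** — seeded generators for layer stacks and platelet
  morphometry (lengths, aspect ratios), plus the rank-sum comparison
  between crystallotypes.
- **`colorimetry`** — 3-point smoothing, peak wavelength, FWHM, CIE
  1931 chromaticity and a stripe/interstripe contrast metric.
- **`physiology`** — the quarter-wave relation `λ = 2(n₁d₁ + n₂d₂)`
  (447.2 nm at the mean ordered geometry) and a norepinephrine (NE)
  response model: NE dilates the ordered type's cytoplasm spacing by a
  calibrated factor 1.35, shifting the peak from ~450 to ~570 nm, while
  the disordered type is refractory.
- **`cell_dynamics`** — synthetic time-lapse tracks and the behaviour
  statistics: axial division-plane orientation (doubled-angle circular
  stats, Rayleigh test), migration bias with bootstrap CIs, and
  per-class proliferation rates with exact Poisson CIs.
- **`config` / `io` / `pipeline` / `cli`** — JSON configuration,
  CSV/JSON readers and writers, seeded run manifests and the `irido`
  command-line wrapper (`simulate-spectrum`, `ne-response`,
  `sample-morphometry`, `generate-tracks`, `analyze-tracks`,
  `run-all`).

## Worked example

```python
from iridoptics import DISORDERED, ORDERED, MonteCarloConfig, NEModel, ne_response

report = ne_response(ORDERED, DISORDERED, NEModel(),
                     MonteCarloConfig(n_runs=500, rng_seed=1))
print(report.ordered.peak_pre_nm, report.ordered.peak_post_nm)
print(report.contrast_pre, report.contrast_post)
```

`examples/02_ne_response.py` formats the same computation; at seed 1 it
prints:

```
   ordered: peak 448 -> 570 nm (shift +122 nm)
disordered: peak 388 -> 388 nm (shift +0 nm)
  contrast: 0.075 -> 0.046 (CIE xy distance)
```

The ordered (stripe) crystallotype shifts ~120 nm from blue to
green-yellow under NE while the disordered (interstripe) type does not
move, so the chromaticity contrast between the two cell types drops —
the optical signature of the stripe pattern fading under NE.

The `examples/` directory holds one short script per capability
(spectra, NE response, morphometry, cell tracks, angle dependence);
each builds its own input, runs the method and explains the numbers it
prints.

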