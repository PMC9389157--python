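# tenmech

Quantification toolkit for tendon-mechanics experiments on developing
(embryonic chick) tendon: how enzymatic collagen crosslinking — driven by
lysyl oxidase (LOX) — stiffens the tissue. It implements, as a tested
reusable library, the full analysis chain such a study needs:

- **Force-volume AFM → modulus maps.** Per-pixel force-displacement curves
  are reduced to Young's moduli by contact-point detection and Hertzian
  fitting. For a four-sided pyramidal tip,
  `F = C·tan(α)·E/(1−ν²)·δ²` (Bilodeau coefficient C = 0.7453; a spherical
  `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` model is also available), with
  `F = k·(d−d₀)` and indentation `δ = (z−z₀) − (d−d₀)`. Maps are summarized
  by their **median** (soft-tissue modulus distributions are right-skewed)
  and relative-frequency histograms on shared bin edges.
- **Tensile testing.** Engineering stress/strain from load-displacement
  traces; elastic modulus as the slope of an automatically detected linear
  region; peak stress and the strain at peak stress.
- **Histology.** Picrosirius-red (PSR) stained-area collagen content;
  polarized-light collagen *maturity* via the red:green intensity ratio
  (pixel red/mature if I_R/I_G ≥ 1.8, green/immature if ≤ 1.1, yellow
  between); TUNEL viability `(N_total − N_apoptotic)/N_total × 100` by
  threshold + connected-component nucleus counting; H&E cell density per
  120×120 µm² tile.
- **SHG image analysis.** Fibrillar collagen content, density, and fiber
  orientation statistics (peak angle and dispersion) from the Fourier power
  spectrum.
- **Crosslink statistics.** Pyridinoline (HP/LP) crosslink densities
  (content / dry mass); exponential-plateau dose-response fits
  `Y = Y_M − (Y_M − Y₀)·e^{−k·x}`; modulus-vs-crosslink linear regression
  with Pearson correlation; Student t-tests and one-way ANOVA with Tukey HSD.
- **Synthetic data.** Every input class can be generated with known ground
  truth (`tenmech.synthetic`), so each stage is verifiable end-to-end by
  parameter recovery — no instrument data required.

The library API is the primary interface; `examples/` holds one short
narrative script per capability, and a thin `tenmech` CLI (`run`,
`simulate`) drives the end-to-end pipeline from a YAML config.

## Worked example

```sh
python examples/shg_directionality.py
```

```
collagen content (mean intensity):  44.67 a.u.
collagen density (area fraction):   0.210
peak orientation:  27.88 deg (true 30.0)
dispersion:        14.92 deg (sample sd 13.87)
peak-fit goodness r^2: 0.95
```

A fiber field was generated at mean orientation 30° with 15° angular spread;
the Fourier orientation histogram recovers the predominant direction within
about one bin and the dispersion within ~1° of the realized angle sample sd.
Lower dispersion means better-aligned collagen. Similarly,

```sh
python examples/afm_modulus_map.py
```

```
fitted 256 of 256 pixels
median modulus:         36.34 kPa
soft-phase median:      15.01 kPa (true 15)
stiff-phase median:     60.04 kPa (true 60)
```

recovers both phases of a two-phase stiffness field to well under 1% from
noisy synthetic force-volume data.

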