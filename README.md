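# nucleophys

Label-free physicochemistry of the nucleolus, on synthetic data.

Nucleoli are dense, membrane-less nuclear bodies whose material state —
macromolecular density and internal fluidity — shifts under osmotic
stress, ATP depletion and transcription inhibition.  Two label-free /
minimally-invasive readouts capture this state in live cells:

* **Optical diffraction tomography (ODT)** reconstructs a 3D map of the
  refractive index (RI), a proxy for local macromolecular
  concentration.  Compartments are delineated by *RI bands* (half-open
  intervals `[lo, hi)`); nucleoli are the high-RI band's 26-connected
  components with equivalent spherical diameter ≥ 2 µm; mean RI is read
  either as the band midpoint `(lo+hi)/2` (the rendering-band
  estimator) or as the voxel mean over the mask; volumes are voxel
  counts × voxel volume.  Time-lapse series yield percent changes
  `100·(after−before)/before` and the nucleolus-to-cytoplasm fold-ratio
  of RI change.

* **Fluorescence correlation spectroscopy (FCS)** infers probe mobility
  from intensity fluctuations in a confocal volume.  The
  autocorrelation ("+1" convention) is fitted with the 3D diffusion
  model

  ```
  G(τ) = 1 + (1/N) Σᵢ yᵢ (1 + τ/τ_Dᵢ)⁻¹ (1 + τ/(s²τ_Dᵢ))⁻¹ᐟ²
  ```

  (optional triplet factor `(1−T+T·e^(−τ/τ_T))/(1−T)`), with model
  order chosen by a nested F-test.  Diffusion times convert to
  coefficients via `τ_D = w²/(4D)` or by rhodamine-6G reference
  calibration `D = 280 µm²/s · τ_ref/τ_probe`; in the nucleolus the
  slow component of a two-component fit is the characteristic mobility.

Because the corresponding instrument data are not publicly depositable,
the package ships first-class synthetic generators: voxel-exact RI
phantoms (`phantom`) and Brownian-dynamics photon traces through a 3D
Gaussian detection volume (`fcs_sim`), which provide ground truth for
every analysis operation (`tomo_quant`, `fcs_analysis`,
`condition_compare`).  It targets quantitative cell biologists and
biophysicists who want a tested, scriptable reimplementation of this
analysis style, and methods developers who need calibrated synthetic
benchmarks.

## Worked example

```python
import nucleophys as np_

# --- ODT side: a cell with five nucleoli plus a sub-threshold speck
cell = np_.five_nucleoli_cell(seed=0, noise_sd=0.001)
seg = np_.segment_by_bands(cell, [np_.RIBand("nucleolus", 1.356, 1.370)])
nucleoli = np_.detect_nucleoli(seg)          # >= 2 um rule
print(len(nucleoli), [round(c.equivalent_diameter_um, 2) for c in nucleoli])
print(round(np_.band_median_ri(seg.band_set[0]), 3),
      round(np_.voxel_mean_ri(cell, seg.band_mask("nucleolus")), 4))

# --- FCS side: simulate a 10 s measurement and recover D
vol = np_.DetectionVolume(w=0.2, s=5.0)
spec = np_.SimSpec(components=((25.0, 1.0),), mean_particles_in_volume=2.0,
                   duration=10.0, dt=2e-6, seed=1000)
trace = np_.simulate_trace(spec, vol)
fit = np_.fit_faf(np_.autocorrelate(trace), n_components=1, w=vol.w)
print(round(fit.D[0], 2), round(fit.N, 3))
```

prints

```
5 [3.0, 2.7, 2.5, 2.3, 2.11]
1.363 1.363
25.63 1.987
```

— the five true nucleoli are detected (the 1.5 µm distractor is
rejected), both RI estimators sit at the nucleolar 1.363, and the fit
recovers the simulated D = 25 µm²/s and mean molecule number N = 2
within a few percent from a single 10 s trace.

A full pipeline run (phantom → segmentation → FCS → ATP-depletion-style
time lapse, with manifest) is:

```sh
nucleophys run --out demo_out          # bundled demo config
```

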