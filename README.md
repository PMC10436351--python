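# mpsim — first-principles simulation of mass photometry

Mass photometry (MP) infers the mass of single, label-free biomolecules
from the interferometric contrast they produce when landing on a
glass–water interface: light scattered by the molecule interferes with
the partially reflected illumination, and a partially transmissive mask
in the back focal plane (BFP) boosts the tiny ratiometric contrast
`C = (I_det − I_bkg)/I_bkg ≈ 2(|s|/|r|√|τ|²)·cos φ` into a measurable
signal that is linear in the molecular polarizability — and hence, to a
few percent, in mass.

`mpsim` is for instrument builders and method developers who want to
simulate that measurement end to end and for anyone who wants the
closed-form performance limits:

* **`field_optics`** — Fourier-optics image formation at the interface:
  Weyl expansion of the dipole field, Fresnel transmission (including
  supercritical emission), BFP mask, √cosθ apodization, defocus/Gouy and
  index-mismatch phases, zoomed-DFT detector images.
* **`scatterers`** — Rayleigh spheres (Clausius–Mossotti,
  `α = 3V(n_p²−n_m²)/(n_p²+2n_m²)`) and atomistic 3×3 polarizability
  tensors from PDB structures via an exact coupled-dipole solve, with
  rotations (`R = R_z R_y R_x`) and uniform orientation sampling.
* **`rough_substrate`** — correlated cover-glass roughness
  (~±0.8 nm over ~100 nm), its reflected-field phase `ψ = 2k₀n_g·Δh`, and
  the resulting speckle background.
* **`landing_sim`** — synthetic landing-assay movies: Poisson arrivals,
  coherent field accumulation, shot noise, detector binning.
* **`ratiometric_pipeline`** — the analysis chain: sliding ratiometric
  frames, radial-symmetry event detection, sub-pixel PSF contrast fits,
  local reflectivity correction, Gaussian peak fitting and contrast→mass
  calibration.
* **`snr_budget`** — the analytic photon budget: `SNR = √(2N_sca)`,
  detection limit `m_q`, quantum Cramér–Rao mass resolution
  `σ_m = m/(√2·SNR)`, the excess-noise ceiling `m/σ_exc`, and the
  interface enhancement factor γ from the dipole-at-interface emission
  pattern.

See `docs/methods.md` for the model, unit conventions and numerical
choices.

## Worked example

```python
import numpy as np
from mpsim import (OpticalConfig, SphereScatterer, SnrParameters,
                   axial_contrast_sweep, shot_noise_snr,
                   detection_limit_mass, qcrlb_resolution)

# image formation: Hsp16.5 24-mer as a 5.6 nm sphere, 1 % mask, 445 nm
cfg = OpticalConfig(pixel_size=57e-9, grid_size=70, mask_transmission=0.01)
sphere = SphereScatterer(radius=5.6e-9, n_particle=1.480)
z = np.arange(-2e-6, 2e-6, 57e-9)
z_star, c_star, profile = axial_contrast_sweep(cfg, sphere, z)
print(f"peak |C| = {abs(c_star)*100:.2f} % at {z_star*1e9:+.0f} nm defocus")

# analytic budget at 0.1 MW/cm^2, 100 ms, 66 kDa
p = SnrParameters()
print(f"SNR = {float(shot_noise_snr(p)):.1f}, "
      f"m_q3 = {detection_limit_mass(p, 3.0):.1f} kDa, "
      f"sigma_m = {qcrlb_resolution(p):.1f} kDa")
```

prints

```
peak |C| = 0.61 % at -183 nm defocus
SNR = 20.8, m_q3 = 9.5 kDa, sigma_m = 2.2 kDa
```

i.e. a 396 kDa particle produces a ~0.6 % ratiometric contrast whose
optimum sits ~190 nm from the nominal focus (Gouy-phase tuning), and at
0.1 MW/cm² × 100 ms a 66 kDa protein is detected at SNR ≈ 21 with a
photon-statistics floor of ≈ 2.2 kDa on its mass estimate.

The full landing assay (rough glass, 0.1 % mask, shot noise, detection,
reflectivity correction, four-point mass calibration) runs in ~20 s:

```python
from mpsim.benchmarks import bsa_landing_assay
r = bsa_landing_assay(seed=1)
print(f"monomer peak {r['monomer_mu_kda']:.1f} ± {r['monomer_sigma_kda']:.1f} kDa "
      f"from {r['n_corrected']} events")
# monomer peak 66.9 ± 3.8 kDa from 281 events
```

The same machinery is scriptable from the shell:

```bash
mpsim simulate-psf --z-sweep "-2e-6:2e-6:5e-8" --out psf_out
mpsim make-surface --grid 128 --seed 1 --out surface.h5
mpsim simulate-landing --surface surface.h5 --seed 1 --out movie_out
mpsim analyze --movie movie_out/movie.tif --out analysis_out
mpsim polarizability --pdb structure.pdb --out tensor.json
mpsim snr-budget --excess-kda 5 --out budget_out
```

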