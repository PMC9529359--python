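# friedel-water

Water confined in a quasi-one-dimensional nanochannel (a narrow carbon
nanotube, a graphene slit, a biological pore) and disturbed by a localized
perturbation — a baffle, a wall charge, a neck — develops pronounced axial
density oscillations that decay with distance, a classical analog of Friedel
oscillations around a defect in a metal.  This package implements the
analytical model of those oscillations, the trajectory statistics that
characterize them, and the free-energy machinery that connects them to ion
transport.  It is aimed at people modelling nanofluidic channels and
channel-confined water who want a closed-form density prediction, a way to fit
it to simulated profiles, and self-contained synthetic data to test against.

## The model

Each confined water molecule sits in an approximately quadratic potential
well; the stationary solution of the corresponding Fokker–Planck equation
makes its axial distribution normal,

```
rho_i(z) = 1/(sigma_i sqrt(2 pi)) * exp(-(z - i*lambda)^2 / (2 sigma_i^2)),
```

with wells on a lattice of spacing λ = 2.9 Å (the oxygen–oxygen distance) and
an empty site at the perturbation (i = 0).  Perturbation strength and
dipole-network correlation enter through two parameters: σ = σ±1, the width of
the first well, and g = σ|i|/σ|i|+1, the decay ratio, so that
σᵢ = σ / g^(|i|−1), clipped at σᵢ ≤ 2 Å.  The normalized density is the
λ-weighted sum of the per-well normals.  Two closures remove all free
parameters for a channel of diameter d and perturbation height h (both in
nm):

```
sigma = 0.3 - 0.4 log10(h)          g = 0.52 + 1/(27 ln d) = 2 <cos theta>
```

where ⟨cos θ⟩ is the mean cosine between dipole vectors of axially adjacent
waters.

Around the model the package provides:

- `oscillation` — closed-form profile evaluation, superposition of several
  perturbations, peak-wavelength and decay-extent observables;
- `fitting` — constrained least-squares recovery of (σ, g[, λ]) from observed
  profiles, with block-bootstrap uncertainties and closure-consistency checks;
- `trajectory` — axial and cylindrical densities, dipole ±z states, dipole
  chain-state statistics (N₋z/N₊z), ⟨cos θ⟩, single-molecule stepped traces,
  and permeation flux from XYZ trajectories;
- `synthetic` — Brownian-dynamics chains of coupled quadratic wells,
  channel-water trajectory generation with prescribed density and dipole
  statistics, and exact umbrella-window sampling;
- `wham` — self-consistent WHAM combination of umbrella windows into a PMF,
  Boltzmann inversion of densities, and entrance-barrier extraction;
- `pipeline`/CLI — config-driven orchestration with reproducible manifests.

## Worked example

```python
import numpy as np
import friedel_water as fw

# closed-form prediction for a (9,9)-sized tube: d = 1.22 nm, h/d = 0.5
geom = fw.GeometryParams(d=1.22, h=0.61)
z = np.linspace(-15, 15, 601)
profile = fw.parameter_free_profile(geom, z)
print(f"sigma(h=0.61) = {fw.sigma_from_h(0.61):.3f} A")
print(f"g(d=1.22)     = {fw.g_from_d(1.22):.3f}")
print(f"wavelength    = {fw.peak_wavelength(profile):.3f} A")
print(f"decay extent  = {fw.decay_extent(profile, 0.05)/10:.2f} nm")

# synthetic trajectory with known (sigma, g), analyzed and fitted back
model = fw.OscillationModel(sigma1=0.4, decay_ratio=0.8, n_wells=10)
spec = fw.ChannelWaterSpec(geometry=geom, model=model, n_chains=4,
                           target_cos_theta=0.7, n_frames=5000, seed=1)
traj = fw.generate_channel_water(spec)
prof = fw.axial_density_profile(traj, bin_width=0.2)
fit = fw.fit_profile(prof.cropped(-26.1, 26.1), n_wells=10, seed=1)
print(f"fitted sigma  = {fit.sigma_hat:.3f} +- {fit.sigma_uncertainty:.3f} A")
print(f"fitted g      = {fit.g_hat:.3f} +- {fit.g_uncertainty:.3f}")
print(f"<cos theta>   = {fw.adjacent_dipole_correlation(traj, n_chains=4):.3f}")
```

prints

```
sigma(h=0.61) = 0.386 A
g(d=1.22)     = 0.706
wavelength    = 2.925 A
decay extent  = 1.18 nm
fitted sigma  = 0.394 +- 0.001 A
fitted g      = 0.799 +- 0.001
<cos theta>   = 0.679
```

The first block says that for this geometry the first wells are sharp
(σ ≈ 0.39 Å), widths grow by 1/g ≈ 1.42 per well, the oscillation period is
the molecular spacing (≈ 2.9 Å, the small excess reflects peak drift where
neighboring wells overlap), and at a 5% peak-to-valley contrast threshold the
oscillation stays visible for ≈ 1.2 nm.  The second block closes the loop on
synthetic data: the fit recovers the generator's σ = 0.4 and g = 0.8 within
2%, and the measured adjacent-dipole correlation sits close to the Markov
generator's nominal 2p − 1 = 0.7 (slightly below it, because wide outer wells
let molecules swap axial order).

The same workflow is available from the shell:

```
friedel-water predict --d 1.22 --h 0.61 --zmax 30 --dz 0.05 --out run/
friedel-water demo --d 1.22 --h 0.61 --out run_demo/   # simulate+analyze+fit
friedel-water wham --windows windows.csv --bin 0.1 --temp 300 --out run_wham/
```

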