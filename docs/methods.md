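# Methods

## The Gaussian-comb density model

The model treats each water molecule in a perturbed 1D channel as a particle
trapped in a quadratic well.  The stationary Fokker–Planck solution of an
overdamped particle in a quadratic well is a normal density, so the
time-averaged axial oxygen density is a sum of normals ("a comb") at lattice
positions μᵢ = iλ, i ∈ {−N..−1, 1..N}, with no well at the perturbed site
i = 0:

ρ(z) = Σᵢ λ/(σᵢ√(2π)) · exp(−(z − iλ)²/(2σᵢ²)),  σᵢ = min(σ/g^(|i|−1), σ_cap).

- **λ = 2.9 Å** is the oxygen–oxygen spacing of channel water and fixes the
  oscillation wavelength.
- **σ (Å)** is the width of the wells adjacent to the perturbation; smaller σ
  means a stronger perturbation and a sharper first peak (height λ/(σ√2π)).
- **g (dimensionless)** is the ratio of successive widths. g < 1 makes widths
  grow away from the perturbation, so the oscillation contrast decays
  approximately as 2·exp(−2π²σᵢ²/λ²); g = 1 gives an undamped comb.
- **σ_cap = 2 Å** clips the cascade: water's limited diffusivity lets
  molecules exchange positions but not spread arbitrarily, so beyond the
  cap the comb becomes a periodic, nearly flat profile.  The clip is a hard
  minimum applied before any evaluation.
- The λ prefactor gives each well integral λ per lattice spacing λ, which
  normalizes the profile to unit mean.  This is exact over whole-wavelength
  windows wherever σ is locally constant.  Where σ grows geometrically, the
  wider outer wells leak more mass inward than the inner wells leak outward,
  so short windows in the growth region average slightly above 1 (about +1%
  for the d = 1.22/h = 0.61 cascade).  `interior_mean` documents this and the
  unit-mean tests are run where the property genuinely holds.

Two empirical closures remove the free parameters for a channel of diameter d
and perturbation height h, both nondimensionalized by 1 nm:

σ = 0.3 − 0.4·log₁₀(h)   and   g = 0.52 + 1/(27·ln d) = 2⟨cos θ⟩.

The σ(h) relation is read with a minus sign and base-10 logarithm (the
companion relation spells out a natural log explicitly, so the bare "log" is
decimal).  σ carries units of Å, not multiples of λ: with σ in λ units the
first-well contrast would already be below 10%, inconsistent with the
pronounced first peaks the closures are calibrated against.  g(d) is singular
at d = 1 and exceeds 1 just above it, so the implementation refuses d below
d_min = 1.05 rather than extrapolating silently.  ⟨cos θ⟩ is the mean cosine
between dipole vectors of axially adjacent waters and measures the
hydrogen-bond-network correlation that propagates the perturbation.

### Profile observables

- **Peak wavelength** — mean spacing of consecutive *interior* peaks on one
  side of the perturbation.  Peaks are strict local maxima on the grid
  (plateaus resolve to their lowest-z point), and only maxima bracketed by a
  local minimum on each side count: where the oscillation has washed out into
  a monotone envelope (wells wider than ≈ λ/2 no longer produce their own
  maximum), the terminal rise drifts outward and is a boundary shoulder, not
  an oscillation peak.  Grid spacing of λ/20 or finer is required.
- **Decay extent** — the largest |z| at which a peak's local peak-to-valley
  contrast (ρ_peak − ρ_valley)/(ρ_peak + ρ_valley), measured against the
  adjacent valley on the side away from the origin, still reaches a threshold
  (default 0.05; "visible to the eye" has no unique formalization, so the
  threshold is a parameter).  All strict maxima participate here, terminal
  ones included.
- **Superposition** — several perturbations each spawn a capped cascade;
  every candidate well is claimed by its nearest source, and where cascades
  coincide the smaller σ wins (the stronger localization).  A single source
  reduces exactly to the basic comb.  Between two sources this rule keeps
  wells sharper and raises the oscillation *contrast*; the absolute peak
  height can still drop in the strongly overlapped regime because sharper
  neighbours contribute less baseline.

## Profile fitting

`fit_profile` minimizes the unweighted sum of squared deviations between an
observed normalized profile and the comb over σ ∈ (0, σ_cap], g ∈ (0, 2] (and
optionally λ ∈ [2.5, 3.3] Å, off by default since λ is set by molecular size
and shifts only under flow).  Normalization puts every profile on the same
scale, so no weighting or amplitude/offset nuisance parameters are used.  A
deterministic 3×3 multi-start grid (σ₀ ∈ {0.3, 0.5, 0.8}, g₀ ∈ {0.6, 0.8,
1.0}) guards against local minima; the best-cost solution is reported.  The
comb truncation defaults to wells filling the profiled region
(N = ⌊max|z|/λ⌋) and can be overridden to match a known generator.
Uncertainties come from a seeded block bootstrap of the fit residuals with
one-wavelength blocks (200 resamples by default): residuals of an oscillating
profile are spatially correlated on the λ scale, so i.i.d. resampling would
understate the errors.

## Trajectory statistics

Trajectories are O positions plus unit dipole vectors (the O–H bond-bisector
direction), channel axis along z, z = 0 at the perturbation.  XYZ files with
O,H,H triplets are read with MDAnalysis; O-only files require a sidecar CSV of
dipoles.

- **Axial density** — histogram of O z-coordinates over frames, divided by the
  mean count per bin over the *occupiable* region: the channel interior minus
  ±λ/2 around each perturbation (the perturbed site is excluded because the
  model leaves it empty).
- **Cylindrical map** — counts per annular (r, z) bin divided by the annular
  volume, normalized by the occupiable-bin mean; its z-marginal reproduces the
  axial profile exactly because both come from the same counts.
- **Dipole states** — sign of the dipole z-component; an exactly zero
  component is labeled +z by convention and counted in a tie statistic.
- **Chain states** — molecules are assigned to n_chains fixed azimuthal
  sectors anchored by a seeded k-means (greedy farthest-point initialization,
  robust when a whole chain shares one azimuth) on the first frame; a chain's
  orientation per frame is the majority label of its molecules and the
  N₋z/N₊z state fractions are time fractions (they always sum to 1).
- **⟨cos θ⟩** — molecules are z-sorted within each chain (or globally when no
  chain count is given) and consecutive unit dipoles contribute their dot
  product; the reported value is the average over all pairs and frames.
- **Stepped trace** — fraction of frames a molecule spends within λ/4 of the
  nearest lattice site: ≈ 1 for well-trapped motion, ≈ 0.5 for free diffusion
  (the λ/4 neighborhoods cover half of each period).
- **Flux** — a crossing is a molecule observed left-reservoir → channel →
  right-reservoir (or the reverse) without returning past its entry boundary;
  single-boundary re-crossings and frame-to-frame jumps straight across both
  boundaries do not count.  Rates are per ns of trajectory.

## Synthetic generators

The generators produce every input the tests use; all are bitwise
reproducible under a fixed seed.

- **Brownian chain** — overdamped first-order (Euler–Maruyama) dynamics of
  particles in quadratic wells with optional nearest-neighbor harmonic
  coupling, z ← z − (dt/γ)∇U + √(2k_BT·dt/γ)·ξ.  The friction default
  γ = 0.5 kcal·mol⁻¹·ps·Å⁻² keeps a 1 fs step stable up to
  k = 10 kcal/mol/Å², with a hard pre-run check dt < 0.1·γ/k_max; burn-in
  defaults to ten times the slowest relaxation time γ/k_min.  The model
  itself supplies no dynamics parameters, so these are conventions.  The
  first-order discretization inflates the stationary variance of an
  uncoupled particle by 1/(1 − k·dt/2γ); tests compare against this exact
  discrete-time value.  `stationary_variance` provides the continuous-time
  k_BT·K⁻¹ reference for coupled chains.
- **Channel water** — each of n_chains azimuthally anchored chains carries
  one molecule per comb well; O z-positions are drawn independently per frame
  from the per-well Gaussians (so the ensemble axial density is the comb by
  construction), and dipoles follow a per-chain two-state ±z Markov chain
  along the well ordering with stay probability p = (1 + ⟨cos θ⟩_target)/2,
  giving E[cos θ] = 2p − 1 between index-adjacent molecules.  Hydrogens are
  placed at 0.9572 Å and 104.52° (rigid four-site-water geometry, used for
  XYZ realism only).  The channel half-length is (M + ½)λ — wells fill the
  channel — and the chain radius defaults to 0.35× the channel radius.
  Two deliberate idealizations: chains are independent (no inter-chain
  dipole coupling, although the collective 2/2-state physics implies some),
  and molecules do not diffuse between wells across frames, so the generator
  reproduces densities and orientation statistics but not transport
  dynamics — flux tests use crafted trajectories instead.  When outer wells
  are wide (σᵢ ≳ λ/2) adjacent molecules can swap axial order, so the
  *measured* z-sorted ⟨cos θ⟩ falls slightly below 2p − 1; the estimator
  checks use tight wells where the identity holds.
- **Umbrella windows** — exact inverse-CDF draws from the biased Boltzmann
  density ∝ exp(−(U(z) + ½k(z−z₀)²)/k_BT) on the tabulated grid; windows
  whose biased density is truncated at the grid edge are flagged with a
  warning.

## WHAM and free energies

`wham_solve` iterates the standard self-consistency equations on histograms
with 0.1 Å bins (default): the unbiased bin probability is the count-weighted
sum over windows divided by Σ_l N_l f_l exp(−w_l/k_BT), and the window
constants follow from the unbiased estimate; convergence is declared when no
constant moves by more than 10⁻⁶ kcal/mol (max 10⁵ iterations).  Window
histograms must form a connected overlap graph, checked up front.  Bins with
zero combined counts are masked, never interpolated.  The PMF is −k_BT ln p,
anchored so its minimum is 0 (barriers are differences, so anchoring is
immaterial to them); k_B = 0.0019872 kcal/mol/K and T defaults to 300 K.
Accuracy comparisons against a known potential align the arbitrary offset by
the mean over the compared bins rather than by the noisy minimum bin, and are
restricted to well-sampled bins (≥ 50 combined counts in the tests): outside
the window centers the biased distributions leave bins nearly empty and the
estimate is dominated by shot noise.

`pmf_from_density` is the Boltzmann-inversion bridge F(z) = −k_BT ln ρ(z)
between the density and free-energy views; `barrier_height` is the maximum
free energy in an entrance region minus a baseline (0 by default, or the mean
over a reservoir-side interval).

## Problem sizes and tolerances

The test suite runs entirely on synthetic data at desk scale: density
round-trips use 3000–5000 frames × 80 molecules (statistical errors on σ and
g of ~1–2%, comfortably inside the 10% recovery check), Brownian-chain checks
use 10⁵ correlated samples with standard errors computed from the relaxation
time, WHAM recovery uses 25 windows × 10⁴ samples (RMSE ≈ 0.02 kcal/mol
against toy potentials, checked against a 0.1 kcal/mol bound), and the
dipole-correlation check uses > 10⁵ Markov pairs (±0.01).  The closed-form
comb evaluation is verified against a brute-force double loop at 10⁻¹².

## Known limitations

- The closures are calibrated for sub-3-nm channels; g(d) is unusable below
  d ≈ 1.05 nm and the package refuses it rather than extrapolating.
- The comb model leaves the perturbed site empty, which deepens valleys
  relative to simulated profiles where molecules exchange through the site.
- Synthetic channel water has no inter-chain coupling, no flow, no ions and
  no frame-to-frame dynamics; conclusions about real transport require
  molecular dynamics, which is outside this package's scope.
- Interior peak positions drift outward by a fraction of a grid step where
  neighboring wells overlap strongly; the wavelength estimator excludes
  terminal shoulder peaks for this reason.
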