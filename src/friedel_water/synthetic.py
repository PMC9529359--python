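"""Synthetic generators for channel-water analyses.

Three generators provide all test inputs for the package:

* ``simulate_langevin_chain`` — overdamped Brownian dynamics of particles in
  quadratic wells with optional nearest-neighbor harmonic coupling.  This is
  the microscopic picture behind the comb model: the stationary marginal of an
  uncoupled particle is exactly the normal law with variance k_B T / k.
* ``generate_channel_water`` — 3D channel-water trajectories with a prescribed
  oscillating axial density (per-well Gaussians of the comb model), a
  prescribed number of axial dipole chains, and a tunable adjacent-dipole
  correlation <cos theta> realized by a two-state +-z Markov chain along each
  chain (stay probability p = (1 + <cos theta>)/2, so <cos theta> = 2p - 1).
* ``sample_umbrella_windows`` — exact draws from the biased Boltzmann density
  of a tabulated potential under harmonic umbrella windows, via inverse-CDF
  sampling on a fine grid.

All generators are bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .oscillation import (
    KB_KCAL_PER_MOL_K,
    LAMBDA_ANGSTROM,
    GeometryParams,
    OscillationModel,
    sigma_sequence,
)
from .trajectory import ChannelTrajectory
from .wham import UmbrellaWindow


# --- Brownian dynamics of the quadratic-well chain -------------------------


@dataclass
class LangevinChainSpec:
    """Overdamped chain of particles in quadratic wells.

    Units: kcal/mol for energies, Angstrom for lengths, ps for times, K for
    temperature.  ``k_well`` may be a scalar or a per-particle sequence;
    ``well_positions`` defaults to the lattice i*lambda, i = 1..n_particles.
    ``friction`` (gamma) defaults to 0.5 kcal/mol ps/A^2, which keeps a 1 fs
    step stable up to k = 10 kcal/mol/A^2 (requires dt < 0.1 gamma / k_max).
    ``burn_in`` defaults to ten times the slowest relaxation time gamma/k_min.
    """

    n_particles: int
    k_well: float | np.ndarray = 1.0
    k_coupling: float = 0.0
    temperature: float = 300.0
    dt_ps: float = 0.001
    n_steps: int = 10_000
    friction: float = 0.5
    lambda_spacing: float = LAMBDA_ANGSTROM
    well_positions: np.ndarray | None = None
    burn_in: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        k = np.broadcast_to(
            np.asarray(self.k_well, dtype=float), (self.n_particles,)
        ).copy()
        if np.any(k <= 0):
            raise ValueError("all well stiffnesses must be positive")
        self.k_well = k
        if self.k_coupling < 0:
            raise ValueError("k_coupling must be >= 0")
        if self.temperature <= 0 or self.dt_ps <= 0 or self.friction <= 0:
            raise ValueError("temperature, dt_ps and friction must be positive")
        if self.well_positions is None:
            self.well_positions = (
                np.arange(1, self.n_particles + 1) * self.lambda_spacing
            )
        else:
            self.well_positions = np.asarray(self.well_positions, dtype=float)
            if self.well_positions.shape != (self.n_particles,):
                raise ValueError("well_positions must have length n_particles")
        if self.burn_in is None:
            tau_slow = self.friction / float(self.k_well.min())
            self.burn_in = int(math.ceil(10.0 * tau_slow / self.dt_ps))

    @property
    def k_max(self) -> float:
        return float(self.k_well.max()) + 2.0 * self.k_coupling

    def stationary_variance(self) -> np.ndarray:
        """Exact stationary marginal variances k_B T K^{-1} of the chain."""
        kT = KB_KCAL_PER_MOL_K * self.temperature
        K = np.diag(self.k_well).astype(float)
        for i in range(self.n_particles - 1):
            K[i, i] += self.k_coupling
            K[i + 1, i + 1] += self.k_coupling
            K[i, i + 1] -= self.k_coupling
            K[i + 1, i] -= self.k_coupling
        return kT * np.diag(np.linalg.inv(K))


def simulate_langevin_chain(spec: LangevinChainSpec) -> np.ndarray:
    """Overdamped (first-order) Brownian dynamics of the well chain.

    Update: z <- z - (dt/gamma) dU/dz + sqrt(2 k_B T dt / gamma) xi with
    U = sum_i k_i/2 (z_i - mu_i)^2 + sum_i k_c/2 (z_{i+1} - z_i - l_i)^2,
    where l_i are the rest lengths implied by the well lattice.  Returns
    positions of shape (n_steps, n_particles) recorded after the burn-in.

    Raises before running if dt >= 0.1 gamma / k_max (unstable step).
    """
    if spec.dt_ps >= 0.1 * spec.friction / spec.k_max:
        raise ValueError(
            f"dt = {spec.dt_ps} ps is unstable: require dt < 0.1 gamma/k_max = "
            f"{0.1 * spec.friction / spec.k_max:.3g} ps"
        )
    rng = np.random.default_rng(spec.seed)
    kT = KB_KCAL_PER_MOL_K * spec.temperature
    mu = spec.well_positions
    rest = np.diff(mu)
    z = mu.copy()
    mobility = spec.dt_ps / spec.friction
    noise_amp = math.sqrt(2.0 * kT * spec.dt_ps / spec.friction)
    n_total = spec.burn_in + spec.n_steps
    out = np.empty((spec.n_steps, spec.n_particles))
    for step in range(n_total):
        grad = spec.k_well * (z - mu)
        if spec.k_coupling > 0 and spec.n_particles > 1:
            stretch = np.diff(z) - rest
            grad[:-1] -= spec.k_coupling * stretch
            grad[1:] += spec.k_coupling * stretch
        z = z - mobility * grad + noise_amp * rng.standard_normal(spec.n_particles)
        if step >= spec.burn_in:
            out[step - spec.burn_in] = z
    return out


def langevin_chain_to_csv(positions: np.ndarray, path) -> None:
    """Write a chain trajectory as long-format CSV: step,particle,z."""
    n_steps, n_particles = positions.shape
    s, p = np.meshgrid(np.arange(n_steps), np.arange(n_particles), indexing="ij")
    pd.DataFrame(
        {"step": s.ravel(), "particle": p.ravel(), "z": positions.ravel()}
    ).to_csv(path, index=False)


# --- channel-water trajectory generator ------------------------------------


@dataclass
class ChannelWaterSpec:
    """Prescription for a synthetic channel-water trajectory.

    Each of ``n_chains`` axial chains carries one molecule per well of the
    comb model (wells at +-i*lambda, i = 1..model.n_wells); oxygen z-positions
    are drawn from the per-well Gaussians, so the ensemble axial density is
    the model profile by construction.  Dipoles follow a per-chain two-state
    +-z Markov chain with stay probability (1 + target_cos_theta)/2.

    ``chain_radius`` defaults to 0.35 x the channel radius; the effective
    (water-occupiable) radius defaults to the channel radius minus 1.4 A of
    wall exclusion.
    """

    geometry: GeometryParams
    model: OscillationModel
    n_chains: int = 4
    target_cos_theta: float = 0.7
    n_frames: int = 1000
    molecules_per_chain_side: int | None = None
    chain_radius: float | None = None
    effective_radius: float | None = None
    frame_interval_ps: float = 2.0
    initial_orientation: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.target_cos_theta < 1.0:
            raise ValueError("target_cos_theta must lie in (-1, 1)")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        radius_a = self.geometry.d * 10.0 / 2.0  # nm -> A
        if self.chain_radius is None:
            self.chain_radius = 0.35 * radius_a
        if self.effective_radius is None:
            self.effective_radius = max(radius_a - 1.4, 0.5)
        if self.chain_radius >= self.effective_radius:
            raise ValueError(
                f"chain radius {self.chain_radius:.2f} A does not fit inside the "
                f"effective radius {self.effective_radius:.2f} A"
            )
        if self.molecules_per_chain_side is None:
            self.molecules_per_chain_side = self.model.n_wells
        if self.molecules_per_chain_side > self.model.n_wells:
            raise ValueError("molecules_per_chain_side cannot exceed model.n_wells")
        if self.initial_orientation not in (None, 1, -1):
            raise ValueError("initial_orientation must be None, +1 or -1")


def generate_channel_water(spec: ChannelWaterSpec) -> ChannelTrajectory:
    """Synthesize a channel-water trajectory with prescribed statistics.

    Molecule ordering is (chain 0 wells -M..-1, 1..M), (chain 1, ...), ...;
    each molecule keeps its chain and well identity across frames.
    """
    rng = np.random.default_rng(spec.seed)
    m_side = spec.molecules_per_chain_side
    lam = spec.model.lambda_spacing
    sig = sigma_sequence(spec.model)[:m_side]
    # well indices -M..-1, 1..M and their scales (symmetric)
    idx = np.concatenate([-np.arange(m_side, 0, -1), np.arange(1, m_side + 1)])
    sigmas = np.concatenate([sig[::-1], sig])
    centers = idx * lam
    n_mol_chain = 2 * m_side
    F, C = spec.n_frames, spec.n_chains

    z = centers + sigmas * rng.standard_normal((F, C, n_mol_chain))

    # dipoles: two-state Markov chain along each chain's z-ordering
    p_stay = (1.0 + spec.target_cos_theta) / 2.0
    if spec.initial_orientation is None:
        s0 = rng.choice([-1.0, 1.0], size=(F, C))
    else:
        s0 = np.full((F, C), float(spec.initial_orientation))
    flips = rng.random((F, C, n_mol_chain - 1)) >= p_stay
    steps = np.where(flips, -1.0, 1.0)
    states = np.concatenate(
        [s0[..., None], s0[..., None] * np.cumprod(steps, axis=2)], axis=2
    )

    phi = 2.0 * math.pi * np.arange(C) / C
    x = spec.chain_radius * np.cos(phi)
    y = spec.chain_radius * np.sin(phi)

    n_mol = C * n_mol_chain
    o = np.empty((F, n_mol, 3))
    o[:, :, 0] = np.repeat(x, n_mol_chain)[None, :]
    o[:, :, 1] = np.repeat(y, n_mol_chain)[None, :]
    o[:, :, 2] = z.reshape(F, n_mol)
    dip = np.zeros((F, n_mol, 3))
    dip[:, :, 2] = states.reshape(F, n_mol)

    # wells fill the channel: the axial interior ends half a spacing past the
    # outermost well (mass drawn beyond it belongs to the reservoirs)
    half_len = (m_side + 0.5) * lam
    return ChannelTrajectory(
        o_positions=o,
        dipoles=dip,
        axial_limits=(-half_len, half_len),
        effective_radius=spec.effective_radius,
        frame_interval_ps=spec.frame_interval_ps,
        perturbation_positions=spec.geometry.perturbation_positions,
    )


# --- umbrella-sampling window generator -------------------------------------


def sample_umbrella_windows(
    z_grid: np.ndarray,
    potential: np.ndarray,
    window_centers: np.ndarray,
    k_spring: float = 5.0,
    n_samples: int = 10_000,
    temperature: float = 300.0,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Draw exact samples from each biased Boltzmann density.

    For window center z0, samples follow
    p(z) ~ exp(-(U(z) + k/2 (z - z0)^2) / k_B T)
    on the tabulated grid, by seeded inverse-CDF sampling.  Windows whose
    biased density carries negligible mass on the grid are flagged and a
    warning is emitted.
    """
    z = np.asarray(z_grid, dtype=float)
    U = np.asarray(potential, dtype=float)
    if z.ndim != 1 or z.shape != U.shape or z.size < 10:
        raise ValueError("z_grid and potential must be matching 1D arrays")
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for usable histograms")
    if k_spring <= 0:
        raise ValueError("k_spring must be positive")
    kT = KB_KCAL_PER_MOL_K * temperature
    rng = np.random.default_rng(seed)
    windows: list[UmbrellaWindow] = []
    for z0 in np.asarray(window_centers, dtype=float):
        bias = 0.5 * k_spring * (z - z0) ** 2
        w = U + bias
        dens = np.exp(-(w - w.min()) / kT)
        mass = np.trapezoid(dens, z)
        flagged = False
        # mass concentrated at the grid edge means the window leaks off-grid
        edge = dens[0] > 1e-3 * dens.max() or dens[-1] > 1e-3 * dens.max()
        if mass <= 0 or edge:
            flagged = True
            warnings.warn(
                f"umbrella window at {z0} has negligible or edge-truncated "
                "probability mass on the tabulated grid",
                RuntimeWarning,
                stacklevel=2,
            )
        cdf = np.concatenate([[0.0], cumulative_trapezoid(dens, z)])
        cdf /= cdf[-1]
        samples = np.interp(rng.random(n_samples), cdf, z)
        windows.append(
            UmbrellaWindow(
                center=float(z0),
                k_spring=float(k_spring),
                samples=samples,
                flagged=flagged,
            )
        )
    return windows
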