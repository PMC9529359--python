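"""Gaussian-comb model of density oscillations in 1D-confined water.

Water confined in a quasi-one-dimensional channel and scattered by a localized
perturbation (a baffle, a wall charge, a neck) develops decaying axial density
oscillations closely analogous to Friedel oscillations around a defect in a
metal.  Each trapped molecule sits in an approximately quadratic potential
well, so its stationary axial distribution (the stationary solution of the
corresponding Fokker-Planck equation) is a normal density

    rho_i(z) = 1/(sigma_i sqrt(2 pi)) exp(-(z - mu_i)^2 / (2 sigma_i^2)),

with wells on a lattice mu_i = i*lambda (lambda = 2.9 A, the oxygen-oxygen
spacing) and no well at the perturbed site i = 0.  The widths grow
geometrically away from the perturbation,

    sigma_i = sigma / g**(|i| - 1),        capped at sigma_i <= sigma_cap,

where sigma (the width of the first well) measures perturbation strength and
g (the decay ratio) measures dipole-network correlation.  The normalized
profile is the lambda-weighted sum of the per-well normals, which has unit
mean over any interior window spanning a whole number of wavelengths.

Both closure relations that remove all free parameters live here:
``sigma_from_h`` (perturbation height -> sigma) and ``g_from_d``
(channel diameter -> g), plus ``g_from_dipole_correlation`` (g = 2<cos theta>).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import norm

# --- physical constants and model defaults -------------------------------

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = 0.0019872

#: Oxygen-oxygen spacing of channel water, in Angstrom.
LAMBDA_ANGSTROM = 2.9

#: Upper limit of any per-well scale parameter, in Angstrom.
SIGMA_CAP_ANGSTROM = 2.0

#: Smallest channel diameter (nm) for which the g(d) closure is trusted.
#: The closure is singular at d = 1 nm and exceeds 1 just above it.
D_MIN_NM = 1.05

#: Graphene lattice constant in nm (used to convert CNT indices to diameters).
GRAPHENE_LATTICE_NM = 0.246

#: Default peak-to-valley contrast threshold for the decay-extent criterion.
DEFAULT_CONTRAST_THRESHOLD = 0.05


class ModelDomainError(ValueError):
    """A closure relation was evaluated outside its physical domain."""


class ValidityError(ModelDomainError):
    """Input is inside the mathematical domain but outside model validity."""


class ResolutionError(ValueError):
    """A z-grid is too coarse to resolve the oscillation wavelength."""


class InsufficientStructureError(ValueError):
    """A profile lacks enough local maxima for the requested statistic."""


class DegenerateInputError(ValueError):
    """An input profile carries no usable oscillation signal."""


# --- domain types ---------------------------------------------------------


@dataclass(frozen=True)
class GeometryParams:
    """Channel geometry.

    Parameters
    ----------
    d : float
        Channel diameter, nondimensionalized by 1 nm (e.g. 1.22 for a (9,9)
        carbon nanotube).
    h : float
        Perturbation (baffle) height, nondimensionalized by 1 nm.
    perturbation_positions : tuple of float
        Axial positions of the perturbation centers, in Angstrom.
    channel_half_length : float
        Axial extent of the channel on each side of the origin, in Angstrom.
    """

    d: float
    h: float
    perturbation_positions: tuple[float, ...] = (0.0,)
    channel_half_length: float = 40.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"channel diameter must be positive, got {self.d}")
        if not self.h > 0:
            raise ValueError(f"perturbation height must be positive, got {self.h}")
        if not self.channel_half_length > 0:
            raise ValueError("channel_half_length must be positive")
        for p in self.perturbation_positions:
            if abs(p) > self.channel_half_length:
                raise ValueError(
                    f"perturbation at {p} A lies outside the channel "
                    f"(half length {self.channel_half_length} A)"
                )


@dataclass(frozen=True)
class OscillationModel:
    """Parameters of the Gaussian-comb density model.

    ``sigma1`` is the scale of the wells adjacent to the perturbation,
    ``decay_ratio`` is g = sigma_|i| / sigma_|i|+1, and wells sit at
    mu_i = i*lambda for i in {-N..-1, 1..N} (the perturbed site i = 0 is
    empty).  The only widths ever used are the capped sequence
    min(sigma1 / g**(|i|-1), sigma_cap).
    """

    sigma1: float
    decay_ratio: float
    n_wells: int
    lambda_spacing: float = LAMBDA_ANGSTROM
    sigma_cap: float = SIGMA_CAP_ANGSTROM

    def __post_init__(self) -> None:
        if not self.sigma1 > 0:
            raise ValueError(f"sigma1 must be positive, got {self.sigma1}")
        if not self.decay_ratio > 0:
            raise ValueError(f"decay_ratio must be positive, got {self.decay_ratio}")
        if not (isinstance(self.n_wells, (int, np.integer)) and self.n_wells >= 1):
            raise ValueError(f"n_wells must be an integer >= 1, got {self.n_wells}")
        if not self.lambda_spacing > 0:
            raise ValueError("lambda_spacing must be positive")
        if not self.sigma_cap > 0:
            raise ValueError("sigma_cap must be positive")

    def sigma_sequence(self) -> np.ndarray:
        return sigma_sequence(self)


@dataclass(frozen=True)
class DensityProfile:
    """A normalized axial density profile on a uniform z-grid.

    ``rho`` is dimensionless (normalized so that the mean density over the
    occupiable space is ~1); ``z_grid`` is in Angstrom with z = 0 at the
    perturbation center.
    """

    z_grid: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_grid, dtype=float)
        r = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "rho", r)
        if z.ndim != 1 or z.size < 2:
            raise ValueError("z_grid must be a 1D array with >= 2 points")
        if r.shape != z.shape:
            raise ValueError("rho and z_grid must have the same shape")
        dz = np.diff(z)
        if not np.all(dz > 0):
            raise ValueError("z_grid must be strictly increasing")
        if not np.allclose(dz, dz[0], rtol=1e-8, atol=1e-10):
            raise ValueError("z_grid must be uniformly spaced")
        if np.any(r < 0):
            raise ValueError("density values must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0])

    def cropped(self, z_min: float, z_max: float) -> "DensityProfile":
        """Restrict the profile to z_min <= z <= z_max."""
        mask = (self.z_grid >= z_min - 1e-12) & (self.z_grid <= z_max + 1e-12)
        return DensityProfile(self.z_grid[mask], self.rho[mask])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"z_angstrom": self.z_grid, "rho_normalized": self.rho}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DensityProfile":
        df = pd.read_csv(path)
        missing = {"z_angstrom", "rho_normalized"} - set(df.columns)
        if missing:
            raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
        return cls(df["z_angstrom"].to_numpy(), df["rho_normalized"].to_numpy())


# --- geometry helper ------------------------------------------------------


def cnt_diameter(n: int, m: int, lattice_nm: float = GRAPHENE_LATTICE_NM) -> float:
    """Diameter (nm) of an (n, m) carbon nanotube from the graphene lattice.

    d = a * sqrt(n^2 + n m + m^2) / pi with a the graphene lattice constant.
    For the (9,9) armchair tube this gives 1.22 nm.
    """
    if n < 0 or m < 0 or (n == 0 and m == 0):
        raise ValueError("chiral indices must be non-negative and not both zero")
    return lattice_nm * math.sqrt(n * n + n * m + m * m) / math.pi


# --- closure relations ----------------------------------------------------


def sigma_from_h(h: float) -> float:
    """First-well scale (Angstrom) from the perturbation height h (nm units).

    sigma = 0.3 - 0.4 log10(h).  Valid only while the result is positive
    (very large obstructions fall outside the calibration).
    """
    if not h > 0:
        raise ModelDomainError(f"perturbation height must be positive, got {h}")
    sigma = 0.3 - 0.4 * math.log10(h)
    if sigma <= 0:
        raise ValidityError(
            f"h = {h} gives sigma = {sigma:.4f} <= 0; the perturbation-strength "
            "closure is not valid for such large h"
        )
    return sigma


def g_from_d(d: float, d_min: float = D_MIN_NM) -> float:
    """Decay ratio g from the channel diameter d (nm units).

    g = 0.52 + 1/(27 ln d).  Singular at d = 1; restricted to d >= d_min
    because just above the singularity the closure exceeds unity and is not
    usable.
    """
    if not d > 0:
        raise ModelDomainError(f"diameter must be positive, got {d}")
    if d == 1.0:
        raise ModelDomainError("g(d) is singular at d = 1 (ln d = 0)")
    if d < d_min:
        raise ValidityError(
            f"d = {d} is below the validity threshold d_min = {d_min}; "
            "the diameter closure is untrustworthy near its singularity"
        )
    return 0.52 + 1.0 / (27.0 * math.log(d))


def g_from_dipole_correlation(mean_cos_theta: float) -> float:
    """Decay ratio from the adjacent-dipole correlation: g = 2 <cos theta>."""
    if not -1.0 <= mean_cos_theta <= 1.0:
        raise ModelDomainError(
            f"<cos theta> must lie in [-1, 1], got {mean_cos_theta}"
        )
    g = 2.0 * mean_cos_theta
    if g <= 0:
        raise ValidityError(
            f"<cos theta> = {mean_cos_theta} implies g = {g} <= 0; the comb "
            "model requires a positive decay ratio"
        )
    return g


# --- model evaluation -----------------------------------------------------


def single_well_density(z, mu_i: float, sigma_i: float):
    """Stationary density of one quadratically trapped molecule (1/Angstrom).

    The normal density with mean ``mu_i`` and scale ``sigma_i``; integrates
    to one over the axis.
    """
    if not sigma_i > 0:
        raise ModelDomainError(f"sigma_i must be positive, got {sigma_i}")
    return norm.pdf(z, loc=mu_i, scale=sigma_i)


def sigma_sequence(model: OscillationModel) -> np.ndarray:
    """Capped per-well scales sigma_i = min(sigma/g**(i-1), cap), i = 1..N.

    By symmetry side -i uses the same value as side +i.
    """
    i = np.arange(1, model.n_wells + 1)
    raw = model.sigma1 / model.decay_ratio ** (i - 1)
    return np.minimum(raw, model.sigma_cap)


def _wells_from_sources(
    sources: Sequence[tuple[float, float]],
    g: float,
    lam: float,
    n_wells: int,
    sigma_cap: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Well centers and scales for one or more perturbation sources.

    Each source spawns a capped cascade of wells at position +- i*lam.  A
    candidate well is kept only if the source that spawned it is (one of) the
    nearest source(s) to the well; wells claimed by several cascades take the
    smallest scale (the stronger localization wins).  No well is placed at a
    source position.
    """
    positions = np.array([p for p, _ in sources], dtype=float)
    mus: list[float] = []
    sigmas: list[float] = []
    idx = np.arange(1, n_wells + 1)
    for k, (p, s) in enumerate(sources):
        if not s > 0:
            raise ModelDomainError(f"source scale must be positive, got {s}")
        casc = np.minimum(s / g ** (idx - 1), sigma_cap)
        for sign in (-1.0, 1.0):
            mu_k = p + sign * idx * lam
            dists = np.abs(mu_k[:, None] - positions[None, :])
            nearest = dists.min(axis=1)
            keep = np.abs(mu_k - p) <= nearest + 1e-9
            # never place a well on top of any source (empty perturbed site)
            on_source = (dists < 1e-9).any(axis=1)
            keep &= ~on_source
            mus.extend(mu_k[keep])
            sigmas.extend(casc[keep])
    mu_arr = np.asarray(mus)
    sg_arr = np.asarray(sigmas)
    # merge coinciding wells: the smaller sigma wins
    order = np.lexsort((sg_arr, np.round(mu_arr, 9)))
    mu_arr, sg_arr = mu_arr[order], sg_arr[order]
    uniq = np.ones(mu_arr.size, dtype=bool)
    uniq[1:] = np.abs(np.diff(mu_arr)) > 1e-9
    return mu_arr[uniq], sg_arr[uniq]


def _comb_density(z: np.ndarray, mus: np.ndarray, sigmas: np.ndarray, lam: float) -> np.ndarray:
    """rho(z) = sum_i lam/(sigma_i sqrt(2 pi)) exp(-(z-mu_i)^2/(2 sigma_i^2))."""
    z = np.asarray(z, dtype=float)
    amp = lam / (sigmas * math.sqrt(2.0 * math.pi))
    return (amp * np.exp(-((z[:, None] - mus) ** 2) / (2.0 * sigmas**2))).sum(axis=1)


def _check_grid(z_grid: np.ndarray, lam: float) -> np.ndarray:
    z = np.asarray(z_grid, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError("z_grid must be a 1D array with >= 2 points")
    dz = np.diff(z)
    if not (np.all(dz > 0) and np.allclose(dz, dz[0], rtol=1e-8, atol=1e-10)):
        raise ValueError("z_grid must be strictly increasing and uniform")
    if dz[0] > lam / 20.0 + 1e-12:
        raise ResolutionError(
            f"grid spacing {dz[0]:.4f} A is coarser than lambda/20 = {lam/20:.4f} A"
        )
    return z


def model_density_profile(model: OscillationModel, z_grid) -> DensityProfile:
    """Evaluate the Gaussian-comb density on a uniform grid.

    The lambda prefactor normalizes each well's integral to lambda, so the
    interior mean of the profile is 1.
    """
    z = _check_grid(z_grid, model.lambda_spacing)
    mus, sigmas = _wells_from_sources(
        [(0.0, model.sigma1)],
        model.decay_ratio,
        model.lambda_spacing,
        model.n_wells,
        model.sigma_cap,
    )
    return DensityProfile(z, _comb_density(z, mus, sigmas, model.lambda_spacing))


def parameter_free_profile(
    geom: GeometryParams,
    z_grid,
    n_wells: int | None = None,
    lambda_spacing: float = LAMBDA_ANGSTROM,
    sigma_cap: float = SIGMA_CAP_ANGSTROM,
) -> DensityProfile:
    """Profile determined by geometry alone: sigma = sigma(h), g = g(d).

    ``n_wells`` defaults to filling the grid (floor(max|z| / lambda)).
    """
    z = np.asarray(z_grid, dtype=float)
    if n_wells is None:
        n_wells = max(1, int(np.floor(np.max(np.abs(z)) / lambda_spacing)))
    model = OscillationModel(
        sigma1=sigma_from_h(geom.h),
        decay_ratio=g_from_d(geom.d),
        n_wells=n_wells,
        lambda_spacing=lambda_spacing,
        sigma_cap=sigma_cap,
    )
    return model_density_profile(model, z)


def superpose_perturbations(
    sources: Sequence[tuple[float, float]],
    g: float,
    lam: float,
    z_grid,
    n_wells: int | None = None,
    sigma_cap: float = SIGMA_CAP_ANGSTROM,
) -> DensityProfile:
    """Density profile for several perturbation sources.

    ``sources`` is a list of (position A, first-well sigma A) pairs.  Wells
    between and around the sources take their scale from the nearest source's
    cascade; where cascades coincide the smaller scale wins.  A single source
    at the origin reduces exactly to :func:`model_density_profile`.
    """
    if len(sources) == 0:
        raise ValueError("at least one perturbation source is required")
    pos = [p for p, _ in sources]
    if len(set(np.round(pos, 9))) != len(pos):
        raise ValueError("perturbation sources must be at distinct positions")
    z = _check_grid(z_grid, lam)
    if n_wells is None:
        span = float(np.max(z) - np.min(z))
        n_wells = max(1, int(np.ceil(span / lam)) + 1)
    mus, sigmas = _wells_from_sources(sources, g, lam, n_wells, sigma_cap)
    return DensityProfile(z, _comb_density(z, mus, sigmas, lam))


# --- profile observables --------------------------------------------------


def _local_maxima_indices(rho: np.ndarray) -> np.ndarray:
    """Strict local maxima; plateaus resolve to their lowest-z grid point."""
    peaks, props = find_peaks(rho, plateau_size=1)
    if peaks.size == 0:
        return peaks
    return props["left_edges"]


def peak_wavelength(profile: DensityProfile) -> float:
    """Mean spacing (Angstrom) of consecutive interior peaks on one side.

    Only interior peaks count: strict local maxima bracketed by a local
    minimum on each side.  A terminal rise where the oscillation has washed
    out into a monotone envelope (no valley before the grid edge) is a
    boundary shoulder, not an oscillation peak, and would bias the spacing.
    Uses the z > 0 side of the perturbation when it carries at least three
    peaks, otherwise the z < 0 side.  Requires >= 3 detectable maxima.
    """
    p_idx = _local_maxima_indices(profile.rho)
    v_idx = _local_maxima_indices(-profile.rho)
    if v_idx.size:
        interior = (p_idx > v_idx.min()) & (p_idx < v_idx.max())
        p_idx = p_idx[interior]
    else:
        p_idx = p_idx[:0]
    z_peaks = profile.z_grid[p_idx]
    for side in (z_peaks[z_peaks > 1e-9], z_peaks[z_peaks < -1e-9]):
        if side.size >= 3:
            return float(np.mean(np.diff(np.sort(side))))
    if z_peaks.size >= 3:
        return float(np.mean(np.diff(np.sort(z_peaks))))
    raise InsufficientStructureError(
        f"need >= 3 local maxima to estimate a wavelength, found {z_peaks.size}"
    )


def decay_extent(
    profile: DensityProfile,
    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
) -> float:
    """Largest |z| (Angstrom) where the oscillation is still 'visible'.

    A peak counts as visible when its local peak-to-valley contrast
    (rho_peak - rho_valley) / (rho_peak + rho_valley), measured against the
    adjacent valley on the side away from the origin (or the inner valley for
    the outermost peak), is at least ``contrast_threshold``.  Returns 0 when
    no peak qualifies.
    """
    if not 0.0 < contrast_threshold < 1.0:
        raise ValueError("contrast_threshold must lie in (0, 1)")
    rho = profile.rho
    z = profile.z_grid
    p_idx = _local_maxima_indices(rho)
    v_idx = _local_maxima_indices(-rho)
    if p_idx.size == 0 or v_idx.size == 0:
        return 0.0
    z_v = z[v_idx]
    extent = 0.0
    for i in p_idx:
        zp, rp = z[i], rho[i]
        outward = z_v > zp if zp >= 0 else z_v < zp
        cand = v_idx[outward]
        if cand.size == 0:
            cand = v_idx  # outermost peak: fall back to nearest valley
        j = cand[np.argmin(np.abs(z[cand] - zp))]
        rv = rho[j]
        denom = rp + rv
        if denom <= 0:
            continue
        contrast = (rp - rv) / denom
        if contrast >= contrast_threshold:
            extent = max(extent, abs(zp))
    return extent


def interior_mean(
    profile: DensityProfile,
    lam: float = LAMBDA_ANGSTROM,
    z_start: float | None = None,
    n_wavelengths: int | None = None,
) -> float:
    """Mean density over a symmetric window spanning whole wavelengths.

    The window is [z_start, z_start + k*lam] plus its mirror image; by default
    it starts at lam/2 (just past the empty perturbed site) and takes the
    largest k that fits the grid.  For a comb of locally constant scale the
    lambda prefactor makes this mean 1 (each well carries integral lambda per
    spacing lambda); where the scale grows with |i| the wider outer wells leak
    more density inward than the inner wells leak outward, so short windows in
    the growth region sit slightly above 1.
    """
    z = profile.z_grid
    lo = lam / 2.0 if z_start is None else float(z_start)
    zmax = float(np.max(np.abs(z)))
    k_max = int(np.floor((zmax - lo) / lam))
    k = k_max if n_wavelengths is None else int(n_wavelengths)
    if k < 1 or k > k_max:
        raise ValueError(
            f"window of {k} wavelengths starting at {lo} A does not fit the grid"
        )
    hi = lo + k * lam
    total = 0.0
    length = 0.0
    for a, b in ((lo, hi), (-hi, -lo)):
        m = (z >= a - 1e-12) & (z <= b + 1e-12)
        # trapezoid average: endpoints half-weighted, exact for whole periods
        total += np.trapezoid(profile.rho[m], z[m])
        length += z[m][-1] - z[m][0]
    return float(total / length)
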