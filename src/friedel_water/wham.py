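"""Potential of mean force from umbrella sampling (WHAM) and from densities.

``wham_solve`` combines harmonically biased window histograms into an
unbiased free-energy profile with the standard weighted-histogram
self-consistency iteration:

    p_j  =  sum_l n_lj  /  sum_l N_l f_l c_lj,      c_lj = exp(-w_l(z_j)/kT),
    1/f_l = sum_j c_lj p_j,

iterated until the per-window free-energy constants -kT ln f_l change by less
than a tolerance.  The PMF is F_j = -kT ln p_j, anchored so its minimum is 0.
Bins with zero combined counts are masked (NaN), never interpolated.

``pmf_from_density`` is the Boltzmann-inversion bridge between the density
and free-energy views of the same channel: F(z) = -kT ln rho(z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .oscillation import KB_KCAL_PER_MOL_K, DensityProfile


class OverlapError(ValueError):
    """Window histograms do not form a connected overlap graph."""


class ConvergenceError(RuntimeError):
    """WHAM iteration did not reach the tolerance within max_iter."""


@dataclass
class UmbrellaWindow:
    """One umbrella-sampling window: harmonic bias and its samples."""

    center: float
    k_spring: float
    samples: np.ndarray
    flagged: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.k_spring < 0:
            raise ValueError("k_spring must be >= 0")
        if self.samples.size < 1:
            raise ValueError("window must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def bias_energy(self, z: np.ndarray) -> np.ndarray:
        return 0.5 * self.k_spring * (np.asarray(z, dtype=float) - self.center) ** 2


def windows_to_csv(windows: list[UmbrellaWindow], path) -> None:
    """Long-format CSV: window_center,k_spring,sample_z."""
    frames = [
        pd.DataFrame(
            {
                "window_center": w.center,
                "k_spring": w.k_spring,
                "sample_z": w.samples,
            }
        )
        for w in windows
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def windows_from_csv(path) -> list[UmbrellaWindow]:
    df = pd.read_csv(path)
    need = {"window_center", "k_spring", "sample_z"}
    if not need <= set(df.columns):
        raise ValueError(f"windows CSV must have columns {sorted(need)}")
    out = []
    for (c, k), grp in df.groupby(["window_center", "k_spring"], sort=True):
        out.append(
            UmbrellaWindow(center=c, k_spring=k, samples=grp["sample_z"].to_numpy())
        )
    return out


@dataclass(frozen=True)
class PMFProfile:
    """Free-energy profile on a uniform z-grid, anchored at min = 0.

    ``free_energy`` is in kcal/mol; masked (zero-count) bins are NaN.
    """

    z_grid: np.ndarray
    free_energy: np.ndarray
    temperature: float
    #: combined histogram counts per bin (WHAM output only; None otherwise)
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z_grid, dtype=float)
        f = np.asarray(self.free_energy, dtype=float)
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "free_energy", f)
        if z.shape != f.shape or z.ndim != 1:
            raise ValueError("z_grid and free_energy must be matching 1D arrays")
        finite = np.isfinite(f)
        if finite.any() and abs(np.nanmin(f)) > 1e-9:
            raise ValueError("PMF must be anchored with min(free_energy) = 0")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"z_angstrom": self.z_grid, "free_energy_kcal_mol": self.free_energy}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, temperature: float = 300.0) -> "PMFProfile":
        df = pd.read_csv(path)
        return cls(
            df["z_angstrom"].to_numpy(),
            df["free_energy_kcal_mol"].to_numpy(),
            temperature,
        )


def _anchored(f: np.ndarray) -> np.ndarray:
    finite = np.isfinite(f)
    if not finite.any():
        raise ValueError("free energy is undefined on every bin")
    return f - np.nanmin(f)


def _check_overlap(occupancy: np.ndarray) -> None:
    """Require the window-overlap graph (shared occupied bins) be connected."""
    n_win = occupancy.shape[0]
    if n_win <= 1:
        return
    adj = (occupancy.astype(bool) @ occupancy.astype(bool).T) > 0
    seen = np.zeros(n_win, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.where(adj[i] & ~seen)[0]:
            seen[j] = True
            stack.append(j)
    if not seen.all():
        raise OverlapError(
            "window histograms are disconnected: groups "
            f"{sorted(np.where(seen)[0])} and {sorted(np.where(~seen)[0])} "
            "share no occupied bins"
        )


def wham_solve(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.1,
    temperature: float = 300.0,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    return_history: bool = False,
):
    """Self-consistent WHAM estimate of the PMF from umbrella windows.

    Convergence is declared when the largest change of any per-window
    free-energy constant (-kT ln f_l) falls below ``tol`` (kcal/mol).  Raises
    :class:`OverlapError` for disconnected windows and
    :class:`ConvergenceError` when ``max_iter`` is exhausted.
    """
    if len(windows) == 0:
        raise ValueError("at least one window is required")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    centers_sorted = sorted(w.center for w in windows)
    if len(windows) > 1:
        spacing = min(np.diff(centers_sorted))
        if spacing > 0 and bin_width > spacing + 1e-12:
            raise ValueError("bin_width must not exceed the window spacing")
    kT = KB_KCAL_PER_MOL_K * temperature

    z_all = np.concatenate([w.samples for w in windows])
    lo, hi = float(z_all.min()), float(z_all.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_lj = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    _check_overlap(n_lj)
    n_j = n_lj.sum(axis=0)
    N_l = n_lj.sum(axis=1).astype(float)
    c_lj = np.exp(-np.stack([w.bias_energy(centers) for w in windows]) / kT)

    f_l = np.ones(len(windows))
    residuals: list[float] = []
    occupied = n_j > 0
    for _ in range(max_iter):
        denom = (N_l[:, None] * f_l[:, None] * c_lj).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_j = np.where(occupied & (denom > 0), n_j / denom, 0.0)
        p_j /= p_j.sum()
        inv_f = (c_lj * p_j).sum(axis=1)
        new_f = 1.0 / inv_f
        # gauge-fix the constants to the first window
        new_f /= new_f[0]
        resid = float(np.max(np.abs(kT * (np.log(new_f) - np.log(f_l)))))
        residuals.append(resid)
        f_l = new_f
        if resid < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {residuals[-1]:.3e} kcal/mol)"
        )

    with np.errstate(divide="ignore"):
        F = np.where(occupied, -kT * np.log(np.where(occupied, p_j, 1.0)), np.nan)
    pmf = PMFProfile(centers, _anchored(F), temperature, counts=n_j)
    if return_history:
        return pmf, np.asarray(residuals)
    return pmf


def pmf_from_density(profile: DensityProfile, temperature: float = 300.0) -> PMFProfile:
    """Boltzmann inversion of a normalized density: F(z) = -kT ln rho(z).

    Zero-density bins are masked with a warning; the result is anchored so
    its minimum is 0.
    """
    kT = KB_KCAL_PER_MOL_K * temperature
    rho = profile.rho
    if np.any(rho <= 0):
        warnings.warn(
            f"{int(np.sum(rho <= 0))} zero-density bins masked in Boltzmann "
            "inversion",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        F = np.where(rho > 0, -kT * np.log(np.where(rho > 0, rho, 1.0)), np.nan)
    return PMFProfile(profile.z_grid, _anchored(F), temperature)


def barrier_height(
    pmf: PMFProfile,
    entrance_region: tuple[float, float],
    baseline_region: tuple[float, float] | None = None,
) -> float:
    """Entrance barrier: max free energy in a region minus an upstream baseline.

    ``baseline_region`` defaults to the anchored zero level (baseline 0);
    when given, the baseline is the mean free energy over that reservoir-side
    interval.
    """
    z = pmf.z_grid
    lo, hi = entrance_region
    mask = (z >= lo) & (z <= hi)
    if not mask.any():
        raise ValueError("entrance_region lies outside the PMF grid")
    peak = np.nanmax(pmf.free_energy[mask])
    baseline = 0.0
    if baseline_region is not None:
        blo, bhi = baseline_region
        bmask = (z >= blo) & (z <= bhi)
        if not bmask.any():
            raise ValueError("baseline_region lies outside the PMF grid")
        baseline = float(np.nanmean(pmf.free_energy[bmask]))
    return float(peak - baseline)
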