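"""Trajectory observables for channel-confined water.

Computes the observables that characterize confined water from a molecular
trajectory: the normalized axial oxygen density, a cylindrical (r, z) density
map, per-molecule dipole +-z states, dipole-chain state statistics
(N_-z / N_+z), the adjacent-dipole correlation <cos theta>, single-molecule
stepped traces, and permeation flux across the channel.

Trajectories are held in :class:`ChannelTrajectory`: per frame, each water's
oxygen position and dipole unit vector (the bisector of the two O-H bonds),
with the channel axis along z and z = 0 at the perturbation center.  XYZ
files (waters as O,H,H triplets) are read with MDAnalysis; oxygen-only
trajectories require a sidecar CSV of dipole vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .oscillation import DensityProfile, LAMBDA_ANGSTROM

# rigid water geometry used when reconstructing hydrogens for XYZ export
OH_BOND_ANGSTROM = 0.9572
HOH_ANGLE_DEG = 104.52


class ChainAssignmentError(RuntimeError):
    """Azimuthal chain assignment failed (e.g. an empty sector)."""


@dataclass
class ChannelTrajectory:
    """Frames of channel water: oxygen positions and dipole unit vectors.

    Attributes
    ----------
    o_positions : ndarray, shape (n_frames, n_molecules, 3)
        Oxygen coordinates in Angstrom; the channel axis is z and z = 0 sits
        at the perturbation center.
    dipoles : ndarray, shape (n_frames, n_molecules, 3)
        Unit dipole vectors (O->H bisector direction).
    axial_limits : (float, float)
        Channel interior along z, Angstrom.
    effective_radius : float
        Radius of the water-occupiable cylinder, Angstrom.
    frame_interval_ps : float
        Time between stored frames, ps.
    perturbation_positions : tuple of float
        Axial perturbation centers, Angstrom.
    """

    o_positions: np.ndarray
    dipoles: np.ndarray
    axial_limits: tuple[float, float]
    effective_radius: float
    frame_interval_ps: float = 2.0
    perturbation_positions: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        self.o_positions = np.asarray(self.o_positions, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        if self.o_positions.ndim != 3 or self.o_positions.shape[2] != 3:
            raise ValueError("o_positions must have shape (frames, molecules, 3)")
        if self.dipoles.shape != self.o_positions.shape:
            raise ValueError("dipoles must match o_positions in shape")
        if self.n_frames < 1:
            raise ValueError("trajectory must contain at least one frame")
        norms = np.linalg.norm(self.dipoles, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("dipole vectors must be unit length to 1e-6")
        lo, hi = self.axial_limits
        if not lo < hi:
            raise ValueError("axial_limits must be ordered (lo < hi)")
        if not self.effective_radius > 0:
            raise ValueError("effective_radius must be positive")
        if not self.frame_interval_ps > 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.o_positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.o_positions.shape[1]

    @property
    def duration_ns(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_ps / 1000.0

    # --- I/O ---------------------------------------------------------------

    def hydrogen_positions(self) -> np.ndarray:
        """Rigid-geometry H positions implied by O positions and dipoles.

        Returns shape (n_frames, n_molecules, 2, 3).  Hydrogens sit at the
        O-H bond length with the H-O-H angle bisected by the dipole; the
        in-plane perpendicular is chosen deterministically.
        """
        d = self.dipoles
        half = math.radians(HOH_ANGLE_DEG / 2.0)
        # deterministic perpendicular: cross with z unless dipole is axial
        ref = np.zeros_like(d)
        axial = np.abs(d[..., 2]) > 0.9
        ref[..., 0] = np.where(axial, 1.0, 0.0)
        ref[..., 2] = np.where(axial, 0.0, 1.0)
        perp = np.cross(d, ref)
        perp /= np.linalg.norm(perp, axis=-1, keepdims=True)
        h1 = self.o_positions + OH_BOND_ANGSTROM * (
            math.cos(half) * d + math.sin(half) * perp
        )
        h2 = self.o_positions + OH_BOND_ANGSTROM * (
            math.cos(half) * d - math.sin(half) * perp
        )
        return np.stack([h1, h2], axis=2)

    def write_xyz(self, path) -> None:
        """Write a multi-frame XYZ file with waters as O,H,H triplets."""
        import MDAnalysis as mda

        n_atoms = 3 * self.n_molecules
        names = np.tile(["O", "H", "H"], self.n_molecules)
        u = mda.Universe.empty(n_atoms, trajectory=True)
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("elements", names)
        h = self.hydrogen_positions()
        coords = np.empty((self.n_frames, n_atoms, 3), dtype=np.float32)
        coords[:, 0::3] = self.o_positions
        coords[:, 1::3] = h[:, :, 0]
        coords[:, 2::3] = h[:, :, 1]
        with mda.Writer(str(path), n_atoms) as w:
            for f in range(self.n_frames):
                u.atoms.positions = coords[f]
                w.write(u.atoms)

    def write_dipole_csv(self, path) -> None:
        """Write the sidecar dipole table: frame,molecule,dipole_x/y/z."""
        f_idx, m_idx = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_molecules), indexing="ij"
        )
        pd.DataFrame(
            {
                "frame": f_idx.ravel(),
                "molecule": m_idx.ravel(),
                "dipole_x": self.dipoles[..., 0].ravel(),
                "dipole_y": self.dipoles[..., 1].ravel(),
                "dipole_z": self.dipoles[..., 2].ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_xyz(
        cls,
        path,
        axial_limits: tuple[float, float],
        effective_radius: float,
        frame_interval_ps: float = 2.0,
        dipole_csv=None,
        perturbation_positions: tuple[float, ...] = (0.0,),
    ) -> "ChannelTrajectory":
        """Read a multi-frame XYZ trajectory (waters as O,H,H triplets).

        When the file contains only oxygens, a ``dipole_csv`` sidecar with
        columns frame,molecule,dipole_x,dipole_y,dipole_z is required.
        """
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        names = np.char.upper(u.atoms.names.astype(str))
        is_o = np.char.startswith(names, "O")
        n_frames = len(u.trajectory)
        if is_o.all():
            o_idx = np.where(is_o)[0]
            n_mol = o_idx.size
            o_pos = np.empty((n_frames, n_mol, 3))
            for f, _ in enumerate(u.trajectory):
                o_pos[f] = u.atoms.positions[o_idx]
            if dipole_csv is None:
                raise ValueError(
                    "oxygen-only trajectory requires a dipole sidecar CSV"
                )
            dip = _read_dipole_csv(dipole_csv, n_frames, n_mol)
        else:
            # O,H,H triplets in fixed order
            if len(names) % 3 != 0 or not all(
                names[i][0] == c
                for i in range(len(names))
                for c in [("O", "H", "H")[i % 3]]
            ):
                raise ValueError("expected waters as O,H,H triplets in fixed order")
            n_mol = len(names) // 3
            o_pos = np.empty((n_frames, n_mol, 3))
            dip = np.empty((n_frames, n_mol, 3))
            for f, _ in enumerate(u.trajectory):
                pos = u.atoms.positions.astype(float)
                o = pos[0::3]
                b1 = pos[1::3] - o
                b2 = pos[2::3] - o
                b1 /= np.linalg.norm(b1, axis=1, keepdims=True)
                b2 /= np.linalg.norm(b2, axis=1, keepdims=True)
                d = b1 + b2
                d /= np.linalg.norm(d, axis=1, keepdims=True)
                o_pos[f] = o
                dip[f] = d
            if dipole_csv is not None:
                dip = _read_dipole_csv(dipole_csv, n_frames, n_mol)
        return cls(
            o_positions=o_pos,
            dipoles=dip,
            axial_limits=axial_limits,
            effective_radius=effective_radius,
            frame_interval_ps=frame_interval_ps,
            perturbation_positions=perturbation_positions,
        )


def _read_dipole_csv(path, n_frames: int, n_mol: int) -> np.ndarray:
    df = pd.read_csv(path)
    need = {"frame", "molecule", "dipole_x", "dipole_y", "dipole_z"}
    if not need <= set(df.columns):
        raise ValueError(f"dipole CSV must have columns {sorted(need)}")
    dip = np.full((n_frames, n_mol, 3), np.nan)
    dip[df["frame"].to_numpy(), df["molecule"].to_numpy()] = df[
        ["dipole_x", "dipole_y", "dipole_z"]
    ].to_numpy()
    if np.isnan(dip).any():
        raise ValueError("dipole CSV does not cover every (frame, molecule)")
    return dip


# --- occupiable region ----------------------------------------------------


def _occupiable_mask(
    centers: np.ndarray,
    axial_limits: tuple[float, float],
    perturbation_positions: tuple[float, ...],
    lam: float,
) -> np.ndarray:
    """Bins inside the channel but outside +-lambda/2 of any perturbation."""
    lo, hi = axial_limits
    mask = (centers >= lo) & (centers <= hi)
    for p in perturbation_positions:
        mask &= np.abs(centers - p) > lam / 2.0
    return mask


# --- densities ------------------------------------------------------------


def axial_density_profile(
    traj: ChannelTrajectory,
    bin_width: float = 0.2,
    lambda_spacing: float = LAMBDA_ANGSTROM,
) -> DensityProfile:
    """Time-averaged axial oxygen density, normalized to unit occupiable mean.

    Oxygen z-coordinates of all frames are histogrammed over the channel
    interior and divided by the mean count per bin over the occupiable region
    (the interior minus +-lambda/2 around each perturbation).
    """
    if bin_width > 0.5:
        raise ValueError("bin_width must be <= 0.5 A to resolve the oscillation")
    lo, hi = traj.axial_limits
    n_bins = max(2, int(round((hi - lo) / bin_width)))
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(traj.o_positions[..., 2].ravel(), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occ = _occupiable_mask(
        centers, traj.axial_limits, traj.perturbation_positions, lambda_spacing
    )
    if not occ.any() or counts[occ].sum() == 0:
        raise ValueError("no oxygen occupancy in the occupiable region")
    return DensityProfile(centers, counts / counts[occ].mean())


@dataclass(frozen=True)
class CylindricalDensityMap:
    """Normalized water density on an (r, z) grid.

    ``values`` are counts per annular volume, normalized by the mean over
    occupiable bins; ``counts`` keeps the raw histogram so the axial marginal
    can be formed without re-binning.
    """

    r_centers: np.ndarray
    z_centers: np.ndarray
    values: np.ndarray  # (n_r, n_z)
    counts: np.ndarray  # (n_r, n_z)
    occupiable_z: np.ndarray  # bool mask over z bins
    axial_limits: tuple[float, float]
    perturbation_positions: tuple[float, ...]

    def axial_marginal(self) -> DensityProfile:
        """z-profile implied by the map: counts summed over r, normalized."""
        counts = self.counts.sum(axis=0)
        occ = self.occupiable_z
        if counts[occ].sum() == 0:
            raise ValueError("no occupancy in the occupiable region")
        return DensityProfile(self.z_centers, counts / counts[occ].mean())

    def to_csv(self, path) -> None:
        r, z = np.meshgrid(self.r_centers, self.z_centers, indexing="ij")
        pd.DataFrame(
            {"r": r.ravel(), "z": z.ravel(), "value": self.values.ravel()}
        ).to_csv(path, index=False)


def cylindrical_density_map(
    traj: ChannelTrajectory,
    dr: float = 0.5,
    dz: float = 0.2,
    lambda_spacing: float = LAMBDA_ANGSTROM,
) -> CylindricalDensityMap:
    """2D density map over (r, z), volume-normalized per annular bin."""
    if dr <= 0 or dz <= 0:
        raise ValueError("dr and dz must be positive")
    lo, hi = traj.axial_limits
    xyz = traj.o_positions.reshape(-1, 3)
    r = np.hypot(xyz[:, 0], xyz[:, 1])
    r_max = max(traj.effective_radius, float(r.max()) + 1e-9)
    n_r = max(1, int(np.ceil(r_max / dr)))
    n_z = max(2, int(round((hi - lo) / dz)))
    r_edges = np.linspace(0.0, n_r * dr, n_r + 1)
    z_edges = np.linspace(lo, hi, n_z + 1)
    counts, _, _ = np.histogram2d(r, xyz[:, 2], bins=[r_edges, z_edges])
    z_centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    # annular bin volumes (independent of frame count; normalization removes it)
    ann = math.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2) * (z_edges[1] - z_edges[0])
    dens = counts / ann[:, None]
    occ_z = _occupiable_mask(
        z_centers, traj.axial_limits, traj.perturbation_positions, lambda_spacing
    )
    occ_2d = np.broadcast_to(occ_z, dens.shape) & (
        r_centers[:, None] <= traj.effective_radius
    )
    mean_occ = dens[occ_2d].mean()
    if counts.sum() == 0 or mean_occ == 0:
        raise ValueError("no occupancy to normalize the density map")
    return CylindricalDensityMap(
        r_centers=r_centers,
        z_centers=z_centers,
        values=dens / mean_occ,
        counts=counts,
        occupiable_z=occ_z,
        axial_limits=traj.axial_limits,
        perturbation_positions=traj.perturbation_positions,
    )


# --- dipole statistics ----------------------------------------------------


class DipoleStates(NamedTuple):
    labels: np.ndarray  # (n_frames, n_molecules), +1 or -1
    n_ties: int  # molecules with exactly zero dipole z-component


def dipole_states(traj: ChannelTrajectory) -> DipoleStates:
    """Classify every molecule per frame as +z or -z by its dipole projection.

    A dipole with exactly zero z-component is labeled +z by convention and
    counted in ``n_ties``.
    """
    dz = traj.dipoles[..., 2]
    labels = np.where(dz < 0, -1, 1).astype(np.int8)
    return DipoleStates(labels=labels, n_ties=int(np.count_nonzero(dz == 0)))


def assign_chains(
    traj: ChannelTrajectory, n_chains: int, seed: int = 0, max_iter: int = 100
) -> np.ndarray:
    """Assign molecules to axial chains by azimuthal clustering.

    A seeded k-means on the unit-circle embedding of first-frame azimuths
    fixes ``n_chains`` anchor angles; every molecule in every frame is then
    assigned to the nearest anchor (fixed azimuthal sectors).  Returns an
    (n_frames, n_molecules) int array of chain indices.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    rng = np.random.default_rng(seed)
    phi0 = np.arctan2(traj.o_positions[0, :, 1], traj.o_positions[0, :, 0])
    pts = np.column_stack([np.cos(phi0), np.sin(phi0)])
    if n_chains > pts.shape[0]:
        raise ChainAssignmentError(
            f"{n_chains} chains requested but only {pts.shape[0]} molecules"
        )
    # greedy farthest-point init: robust when many molecules share an azimuth
    first = int(rng.integers(pts.shape[0]))
    chosen = [first]
    d_min = ((pts - pts[first]) ** 2).sum(axis=1)
    for _ in range(n_chains - 1):
        nxt = int(np.argmax(d_min))
        if d_min[nxt] <= 1e-12:
            raise ChainAssignmentError(
                f"fewer than {n_chains} distinct azimuths on the first frame"
            )
        chosen.append(nxt)
        d_min = np.minimum(d_min, ((pts - pts[nxt]) ** 2).sum(axis=1))
    centers = pts[chosen]
    for _ in range(max_iter):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = d2.argmin(axis=1)
        new = np.empty_like(centers)
        for c in range(n_chains):
            sel = pts[lab == c]
            if sel.size == 0:
                raise ChainAssignmentError(
                    f"azimuthal sector {c} is empty on the first frame; "
                    "check n_chains against the channel occupancy"
                )
            m = sel.mean(axis=0)
            nrm = np.linalg.norm(m)
            new[c] = m / nrm if nrm > 0 else centers[c]
        if np.allclose(new, centers, atol=1e-12):
            centers = new
            break
        centers = new
    anchor = np.arctan2(centers[:, 1], centers[:, 0])
    phi = np.arctan2(traj.o_positions[..., 1], traj.o_positions[..., 0])
    # angular distance to each anchor
    diff = np.abs(
        (phi[..., None] - anchor[None, None, :] + math.pi) % (2 * math.pi) - math.pi
    )
    return diff.argmin(axis=2)


@dataclass(frozen=True)
class ChainStateSeries:
    """Per-frame counts of -z and +z oriented chains."""

    n_minus: np.ndarray
    n_plus: np.ndarray
    n_chains: int

    def __post_init__(self) -> None:
        if np.any(self.n_minus + self.n_plus != self.n_chains):
            raise ValueError("chain counts must partition n_chains every frame")

    def state_probabilities(self) -> dict[str, float]:
        """Time fraction of each 'N_-z/N_+z' state; fractions sum to 1."""
        keys, counts = np.unique(self.n_minus, return_counts=True)
        total = self.n_minus.size
        return {
            f"{int(k)}/{int(self.n_chains - k)}": c / total
            for k, c in zip(keys, counts)
        }


def chain_state_distribution(
    traj: ChannelTrajectory, n_chains: int, seed: int = 0
) -> tuple[ChainStateSeries, dict[str, float]]:
    """Per-frame dipole-chain states and their time-fraction distribution.

    Each chain's orientation in a frame is the majority +-z label of its
    molecules (ties resolved to +z); the returned probabilities are the time
    fractions of each N_-z/N_+z state.
    """
    chains = assign_chains(traj, n_chains, seed=seed)
    labels = dipole_states(traj).labels
    n_frames = traj.n_frames
    n_minus = np.zeros(n_frames, dtype=int)
    for c in range(n_chains):
        sel = chains == c
        if not sel.any(axis=1).all():
            raise ChainAssignmentError(f"chain {c} empty in at least one frame")
        s = np.where(sel, labels, 0).sum(axis=1)
        n_minus += (s < 0).astype(int)
    series = ChainStateSeries(
        n_minus=n_minus, n_plus=n_chains - n_minus, n_chains=n_chains
    )
    return series, series.state_probabilities()


def adjacent_dipole_correlation(
    traj: ChannelTrajectory, n_chains: int | None = None, seed: int = 0
) -> float:
    """Mean cosine between dipoles of axially adjacent waters, <cos theta>.

    Molecules are sorted by z within each chain (``n_chains`` given) or
    globally (``n_chains=None``); consecutive pairs contribute the dot product
    of their unit dipoles.  Averaged over all pairs and frames.
    """
    if traj.n_molecules < 2:
        raise ValueError("need at least two molecules for adjacent pairs")
    if n_chains is None:
        groups = np.zeros((traj.n_frames, traj.n_molecules), dtype=int)
        n_groups = 1
    else:
        groups = assign_chains(traj, n_chains, seed=seed)
        n_groups = n_chains
    total = 0.0
    n_pairs = 0
    z = traj.o_positions[..., 2]
    for f in range(traj.n_frames):
        for c in range(n_groups):
            idx = np.where(groups[f] == c)[0]
            if idx.size < 2:
                continue
            order = idx[np.argsort(z[f, idx], kind="stable")]
            d = traj.dipoles[f, order]
            total += float(np.einsum("ij,ij->i", d[:-1], d[1:]).sum())
            n_pairs += idx.size - 1
    if n_pairs == 0:
        raise ValueError("no adjacent pairs found")
    return total / n_pairs


# --- single-molecule trace and flux ---------------------------------------


class MoleculeTrace(NamedTuple):
    times_ps: np.ndarray
    z: np.ndarray
    step_fraction: float


def molecule_trace(
    traj: ChannelTrajectory,
    molecule_index: int,
    lambda_spacing: float = LAMBDA_ANGSTROM,
) -> MoleculeTrace:
    """z(t) of one molecule plus a stepped-motion metric.

    The step metric is the fraction of frames the molecule spends within
    lambda/4 of the nearest lattice site i*lambda: ~1 for well-trapped
    (stepped) motion, ~0.5 for free diffusion (the lambda/4 neighborhoods
    cover half of each period).
    """
    if not 0 <= molecule_index < traj.n_molecules:
        raise IndexError(
            f"molecule index {molecule_index} out of range [0, {traj.n_molecules})"
        )
    z = traj.o_positions[:, molecule_index, 2]
    t = np.arange(traj.n_frames) * traj.frame_interval_ps
    frac_off = np.abs(z - lambda_spacing * np.round(z / lambda_spacing))
    step_fraction = float(np.mean(frac_off <= lambda_spacing / 4.0))
    return MoleculeTrace(times_ps=t, z=z, step_fraction=step_fraction)


class FluxResult(NamedTuple):
    net: int
    total: int
    net_per_ns: float
    total_per_ns: float


def crossing_flux(
    traj: ChannelTrajectory, z_left: float, z_right: float
) -> FluxResult:
    """Count full channel transits between two axial boundaries.

    A crossing is a molecule entering the region between the boundaries at
    one boundary and exiting at the other without first returning past its
    entry boundary; single-boundary re-crossings do not count.  ``net`` is
    (+z crossings) - (-z crossings); rates are per nanosecond of trajectory.
    """
    lo, hi = traj.axial_limits
    if not z_left < z_right:
        raise ValueError("z_left must be < z_right")
    if z_left < lo or z_right > hi:
        raise ValueError("boundaries must lie within the channel axial limits")
    z = traj.o_positions[..., 2]
    region = np.where(z < z_left, 0, np.where(z > z_right, 2, 1)).astype(np.int8)
    plus = minus = 0
    for m in range(traj.n_molecules):
        seq = region[:, m]
        # compress consecutive duplicates
        comp = seq[np.concatenate([[True], np.diff(seq) != 0])]
        # a transit must be observed inside the channel: left->middle->right;
        # a frame-to-frame jump straight across both boundaries is not counted
        for i in range(2, comp.size):
            if comp[i] == 2 and comp[i - 1] == 1 and comp[i - 2] == 0:
                plus += 1
            elif comp[i] == 0 and comp[i - 1] == 1 and comp[i - 2] == 2:
                minus += 1
    dur = traj.duration_ns
    net = plus - minus
    total = plus + minus
    if dur > 0:
        return FluxResult(net, total, net / dur, total / dur)
    return FluxResult(net, total, float("nan"), float("nan"))
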