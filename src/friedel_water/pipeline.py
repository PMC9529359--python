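"""Configuration-driven orchestration of the simulate/analyze/fit/wham stages.

A run is described by a JSON config validated against :class:`RunConfig`
(keys carry explicit units: ``*_nm``, ``*_angstrom``, ``*_kcal_mol``).  Every
stage writes its outputs under ``out_dir`` together with a ``manifest.json``
recording package and library versions, the seed, all parameters, and SHA-256
digests of every input and output file, so identical configs reproduce
byte-identical results.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .oscillation import (
    DensityProfile,
    GeometryParams,
    OscillationModel,
    g_from_d,
    parameter_free_profile,
    sigma_from_h,
)
from .fitting import closure_consistency, fit_profile
from .synthetic import (
    ChannelWaterSpec,
    LangevinChainSpec,
    generate_channel_water,
    langevin_chain_to_csv,
    sample_umbrella_windows,
    simulate_langevin_chain,
)
from .trajectory import (
    ChannelTrajectory,
    adjacent_dipole_correlation,
    axial_density_profile,
    chain_state_distribution,
    cylindrical_density_map,
)
from .wham import wham_solve, windows_from_csv, windows_to_csv

logger = logging.getLogger("friedel_water")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    subcommand: Literal["predict", "simulate", "analyze", "fit", "wham", "demo"]
    seed: int = 0
    out_dir: str = "."

    # geometry / model
    d_nm: Optional[float] = Field(default=None, gt=0)
    h_nm: Optional[float] = Field(default=None, gt=0)
    lambda_angstrom: float = Field(default=2.9, gt=0)
    sigma_cap: float = Field(default=2.0, gt=0)
    n_wells: Optional[int] = Field(default=None, ge=1)
    zmax_angstrom: float = Field(default=30.0, gt=0)
    dz_angstrom: float = Field(default=0.05, gt=0)
    contrast_threshold: float = Field(default=0.05, gt=0, lt=1)

    # trajectory / analysis
    bin_width_angstrom: float = Field(default=0.2, gt=0)
    n_chains: int = Field(default=4, ge=1)
    target_cos_theta: float = Field(default=0.7, gt=-1, lt=1)
    n_frames: int = Field(default=800, ge=1)
    channel_half_length_angstrom: Optional[float] = Field(default=None, gt=0)
    effective_radius_angstrom: Optional[float] = Field(default=None, gt=0)
    fit_lambda: bool = False
    n_bootstrap: int = Field(default=200, ge=0)

    # simulate
    simulate_kind: Optional[Literal["chain", "channel", "umbrella"]] = None
    n_particles: int = Field(default=20, ge=1)
    k_well_kcal_mol: float = Field(default=1.0, gt=0)
    k_coupling_kcal_mol: float = Field(default=0.0, ge=0)
    dt_ps: float = Field(default=0.001, gt=0)
    n_steps: int = Field(default=20_000, ge=1)
    toy_potential: Literal["harmonic", "double_well", "ramp_bump"] = "harmonic"
    window_spacing_angstrom: float = Field(default=0.5, gt=0)
    k_spring_kcal_mol: float = Field(default=5.0, gt=0)
    n_samples_per_window: int = Field(default=5000, ge=1000)

    # wham
    temperature_k: float = Field(default=300.0, gt=0)
    wham_bin_angstrom: float = Field(default=0.1, gt=0)

    # file inputs
    traj_xyz: Optional[str] = None
    dipole_csv: Optional[str] = None
    profile_csv: Optional[str] = None
    windows_csv: Optional[str] = None

    def required_violations(self) -> list[str]:
        """Subcommand-specific requirement checks (all violations, not the first)."""
        need = {
            "predict": ["d_nm", "h_nm"],
            "demo": ["d_nm", "h_nm"],
            "fit": ["profile_csv"],
            "analyze": ["traj_xyz"],
            "wham": ["windows_csv"],
            "simulate": ["simulate_kind"],
        }[self.subcommand]
        if self.subcommand == "simulate" and self.simulate_kind == "channel":
            need = need + ["d_nm", "h_nm"]
        return [
            f"subcommand '{self.subcommand}' requires key '{k}'"
            for k in need
            if getattr(self, k) is None
        ]


def _suggest(msg: str, bad_key: str) -> str:
    close = difflib.get_close_matches(bad_key, RunConfig.model_fields.keys(), n=1)
    return msg + (f" (did you mean '{close[0]}'?)" if close else "")


def validate_config(path) -> list[str]:
    """Validate a JSON config file; returns [] when ok, else all violations."""
    p = Path(path)
    try:
        raw = json.loads(p.read_text())
    except OSError as exc:
        raise OSError(f"cannot read config {p}: {exc}") from exc
    except json.JSONDecodeError as exc:
        return [f"config is not valid JSON: {exc}"]
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        out = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<root>"
            msg = f"{loc}: {err['msg']}"
            if err["type"] == "extra_forbidden":
                msg = _suggest(f"unknown key '{loc}'", loc)
            out.append(msg)
        return out
    return cfg.required_violations()


def load_config(path) -> RunConfig:
    violations = validate_config(path)
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))
    return RunConfig(**json.loads(Path(path).read_text()))


# --- stage helpers ----------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _z_grid(cfg: RunConfig) -> np.ndarray:
    n = int(round(cfg.zmax_angstrom / cfg.dz_angstrom))
    return np.linspace(-n * cfg.dz_angstrom, n * cfg.dz_angstrom, 2 * n + 1)


def _geometry(cfg: RunConfig) -> GeometryParams:
    return GeometryParams(
        d=cfg.d_nm,
        h=cfg.h_nm,
        channel_half_length=cfg.zmax_angstrom
        if cfg.channel_half_length_angstrom is None
        else cfg.channel_half_length_angstrom,
    )


def _toy_potential(kind: str, z: np.ndarray) -> np.ndarray:
    if kind == "harmonic":
        return 0.5 * 2.0 * z**2
    if kind == "double_well":
        return 0.5 * (z**2 - 9.0) ** 2 / 20.0
    return 0.4 * z + 3.0 * np.exp(-(z**2) / 2.0)  # ramp + bump


def _analyze(traj: ChannelTrajectory, cfg: RunConfig, out: Path) -> dict:
    profile = axial_density_profile(traj, bin_width=cfg.bin_width_angstrom)
    profile.to_csv(out / "profile.csv")
    cmap = cylindrical_density_map(traj, dz=cfg.bin_width_angstrom)
    cmap.to_csv(out / "density_map.csv")
    series, probs = chain_state_distribution(traj, cfg.n_chains, seed=cfg.seed)
    pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "n_minus": series.n_minus,
            "n_plus": series.n_plus,
        }
    ).to_csv(out / "chain_states.csv", index=False)
    cos_theta = adjacent_dipole_correlation(traj, n_chains=cfg.n_chains, seed=cfg.seed)
    summary = {"mean_cos_theta": cos_theta, "chain_state_probabilities": probs}
    (out / "analysis.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage(s); returns and writes the run manifest."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    violations = cfg.required_violations()
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))
    inputs = [
        Path(p)
        for p in (cfg.traj_xyz, cfg.dipole_csv, cfg.profile_csv, cfg.windows_csv)
        if p is not None
    ]
    logger.info("run start: %s (seed=%d, out=%s)", cfg.subcommand, cfg.seed, out)

    if cfg.subcommand == "predict":
        profile = parameter_free_profile(
            _geometry(cfg),
            _z_grid(cfg),
            n_wells=cfg.n_wells,
            lambda_spacing=cfg.lambda_angstrom,
            sigma_cap=cfg.sigma_cap,
        )
        profile.to_csv(out / "profile.csv")

    elif cfg.subcommand == "simulate":
        if cfg.simulate_kind == "chain":
            spec = LangevinChainSpec(
                n_particles=cfg.n_particles,
                k_well=cfg.k_well_kcal_mol,
                k_coupling=cfg.k_coupling_kcal_mol,
                temperature=cfg.temperature_k,
                dt_ps=cfg.dt_ps,
                n_steps=cfg.n_steps,
                lambda_spacing=cfg.lambda_angstrom,
                seed=cfg.seed,
            )
            langevin_chain_to_csv(simulate_langevin_chain(spec), out / "chain.csv")
        elif cfg.simulate_kind == "channel":
            traj = generate_channel_water(_channel_spec(cfg))
            traj.write_xyz(out / "trajectory.xyz")
            traj.write_dipole_csv(out / "dipoles.csv")
        else:  # umbrella
            z = np.linspace(-10.0, 10.0, 4001)
            U = _toy_potential(cfg.toy_potential, z)
            centers = np.arange(-6.0, 6.0 + 1e-9, cfg.window_spacing_angstrom)
            windows = sample_umbrella_windows(
                z,
                U,
                centers,
                k_spring=cfg.k_spring_kcal_mol,
                n_samples=cfg.n_samples_per_window,
                temperature=cfg.temperature_k,
                seed=cfg.seed,
            )
            windows_to_csv(windows, out / "windows.csv")
            pd.DataFrame({"z_angstrom": z, "potential_kcal_mol": U}).to_csv(
                out / "true_potential.csv", index=False
            )

    elif cfg.subcommand == "analyze":
        if cfg.channel_half_length_angstrom is None or cfg.effective_radius_angstrom is None:
            raise ValueError(
                "analyze requires channel_half_length_angstrom and "
                "effective_radius_angstrom"
            )
        traj = ChannelTrajectory.from_xyz(
            cfg.traj_xyz,
            axial_limits=(
                -cfg.channel_half_length_angstrom,
                cfg.channel_half_length_angstrom,
            ),
            effective_radius=cfg.effective_radius_angstrom,
            dipole_csv=cfg.dipole_csv,
        )
        _analyze(traj, cfg, out)

    elif cfg.subcommand == "fit":
        profile = DensityProfile.from_csv(cfg.profile_csv)
        fit = fit_profile(
            profile,
            fit_lambda=cfg.fit_lambda,
            seed=cfg.seed,
            sigma_cap=cfg.sigma_cap,
            lambda_spacing=cfg.lambda_angstrom,
            n_bootstrap=cfg.n_bootstrap,
        )
        fit.to_json(out / "fit.json")

    elif cfg.subcommand == "wham":
        windows = windows_from_csv(cfg.windows_csv)
        pmf = wham_solve(
            windows,
            bin_width=cfg.wham_bin_angstrom,
            temperature=cfg.temperature_k,
        )
        pmf.to_csv(out / "pmf.csv")

    elif cfg.subcommand == "demo":
        _demo(cfg, out)

    for p in inputs:
        if (out / p.name).resolve() == p.resolve() and p.exists():
            raise ValueError(f"output would overwrite input file {p}")

    manifest = {
        "package": "friedel-water",
        "version": __version__,
        "numpy": np.__version__,
        "subcommand": cfg.subcommand,
        "seed": cfg.seed,
        "parameters": json.loads(cfg.model_dump_json()),
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run done: %d output file(s)", len(manifest["outputs"]))
    return manifest


def _channel_spec(cfg: RunConfig) -> ChannelWaterSpec:
    geom = _geometry(cfg)
    n_wells = cfg.n_wells or max(
        1, int(np.floor(cfg.zmax_angstrom / cfg.lambda_angstrom)) - 1
    )
    model = OscillationModel(
        sigma1=sigma_from_h(geom.h),
        decay_ratio=g_from_d(geom.d),
        n_wells=n_wells,
        lambda_spacing=cfg.lambda_angstrom,
        sigma_cap=cfg.sigma_cap,
    )
    return ChannelWaterSpec(
        geometry=geom,
        model=model,
        n_chains=cfg.n_chains,
        target_cos_theta=cfg.target_cos_theta,
        n_frames=cfg.n_frames,
        seed=cfg.seed,
    )


def _demo(cfg: RunConfig, out: Path) -> None:
    """Generate -> analyze -> fit -> closed-form comparison, with a report."""
    spec = _channel_spec(cfg)
    # tie the dipole statistics to the decay ratio via g = 2 <cos theta>
    target = spec.model.decay_ratio / 2.0
    spec = ChannelWaterSpec(
        geometry=spec.geometry,
        model=spec.model,
        n_chains=cfg.n_chains,
        target_cos_theta=target,
        n_frames=cfg.n_frames,
        seed=cfg.seed,
    )
    traj = generate_channel_water(spec)
    traj.write_xyz(out / "trajectory.xyz")
    traj.write_dipole_csv(out / "dipoles.csv")
    summary = _analyze(traj, cfg, out)

    profile = DensityProfile.from_csv(out / "profile.csv")
    m = spec.molecules_per_chain_side
    lam = spec.model.lambda_spacing
    interior = profile.cropped(-(m - 1) * lam, (m - 1) * lam)
    fit = fit_profile(
        interior,
        seed=cfg.seed,
        n_wells=m,
        sigma_cap=cfg.sigma_cap,
        lambda_spacing=lam,
        n_bootstrap=cfg.n_bootstrap,
    )
    fit.to_json(out / "fit.json")

    predicted = parameter_free_profile(
        _geometry(cfg), _z_grid(cfg), n_wells=cfg.n_wells,
        lambda_spacing=lam, sigma_cap=cfg.sigma_cap,
    )
    predicted.to_csv(out / "predicted_profile.csv")

    report = closure_consistency(
        fit, _geometry(cfg), mean_cos_theta=summary["mean_cos_theta"],
        sigma_tolerance=0.1, g_tolerance=0.1,
    )
    (out / "consistency_report.json").write_text(
        json.dumps(
            {
                "fit": {"sigma_hat": fit.sigma_hat, "g_hat": fit.g_hat},
                "closures": {
                    "sigma_from_h": sigma_from_h(cfg.h_nm),
                    "g_from_d": g_from_d(cfg.d_nm),
                    "two_cos_theta": 2.0 * summary["mean_cos_theta"],
                },
                "residuals": {
                    "sigma": report.sigma_residual,
                    "g_geometry": report.g_geometry_residual,
                    "g_dipole": report.g_dipole_residual,
                },
                "all_ok": report.all_ok(),
            },
            indent=2,
        )
    )
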