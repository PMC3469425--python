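"""Configuration files, trajectory and curve I/O, synthetic fixtures.

Trajectories travel as extended XYZ (one block per frame; the comment line
carries the sweep index, box edge and physical time; per-particle columns
are id, state label A/B, position and orientation quaternion) or as an
HDF5 container with identical content.  Configurations are a single YAML
file with ``model``/``sim``/``analysis`` sections; angles are degrees in
the file and radians in memory.  Unknown keys are errors.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clusters import DEFAULT_BOND_CUT, FIBRIL_MIN_SIZE, MassFractionCurve
from .engine import Frame, SimConfig, Trajectory
from .model import (ModelParams, frame_to_quaternion,
                    ideal_oligomer_configuration, quaternion_to_frame)
from .oosawa import analytic_halftime, oosawa_curve

_ANGLE_FIELDS = {"patch_halfwidth_alpha", "patch_halfwidth_beta",
                 "gate_shoulder", "chirality_angle"}


@dataclass
class AnalysisOptions:
    bond_energy_cut: float = DEFAULT_BOND_CUT
    fibril_min_size: int = FIBRIL_MIN_SIZE


@dataclass
class RunConfig:
    """Everything one run needs: model, simulation and analysis settings."""

    model: ModelParams = field(default_factory=ModelParams)
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def to_dict(self) -> dict:
        model = dataclasses.asdict(self.model)
        for k in _ANGLE_FIELDS:
            model[k] = math.degrees(model[k])
        return {"model": model,
                "sim": dataclasses.asdict(self.sim),
                "analysis": dataclasses.asdict(self.analysis)}


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"model", "sim", "analysis"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    model_data = dict(raw.get("model", {}))
    for k in _ANGLE_FIELDS & set(model_data):
        model_data[k] = math.radians(model_data[k])
    return RunConfig(
        model=_build_section(ModelParams, model_data, "model"),
        sim=_build_section(SimConfig, dict(raw.get("sim", {})), "sim"),
        analysis=_build_section(AnalysisOptions,
                                dict(raw.get("analysis", {})), "analysis"))


def echo_config(config: RunConfig, path, seed: int | None = None) -> None:
    """JSON sidecar with the effective configuration and the seed used."""
    data = config.to_dict()
    if seed is not None:
        data["sim"]["seed"] = seed
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# extended XYZ

_STATE_LABELS = {0: "A", 1: "B"}
_LABEL_STATES = {"A": 0, "B": 1}


def write_xyz(traj: Trajectory, path) -> None:
    """Extended-XYZ trajectory writer (quaternion orientation columns)."""
    dt = traj.config.sweep_time_ns
    box = traj.box_edge
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(f"{f.n_particles}\n")
            fh.write(f"sweep={f.sweep} box_nm={box:.9f} "
                     f"time_ns={f.sweep * dt:.9f}\n")
            for i in range(f.n_particles):
                q = frame_to_quaternion(f.axes[i], f.patches[i])
                fh.write(
                    f"{i} {_STATE_LABELS[int(f.states[i])]} "
                    f"{f.positions[i, 0]:.9f} {f.positions[i, 1]:.9f} "
                    f"{f.positions[i, 2]:.9f} "
                    f"{q[0]:.12f} {q[1]:.12f} {q[2]:.12f} {q[3]:.12f}\n")


class TrajectoryParseError(ValueError):
    pass


def read_xyz(path, config: SimConfig | None = None,
             model: ModelParams | None = None) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_xyz`.

    Validates the per-frame header, constant particle count and quaternion
    normalisation; errors name the offending frame.
    """
    lines = Path(path).read_text().splitlines()
    frames = []
    pos_in_file = 0
    n_expected = None
    box = None
    frame_no = 0
    while pos_in_file < len(lines):
        if not lines[pos_in_file].strip():
            pos_in_file += 1
            continue
        try:
            n = int(lines[pos_in_file].strip())
        except ValueError as err:
            raise TrajectoryParseError(
                f"frame {frame_no}: malformed particle-count line "
                f"{lines[pos_in_file]!r}") from err
        if n_expected is not None and n != n_expected:
            raise TrajectoryParseError(
                f"frame {frame_no}: particle count changed "
                f"({n} != {n_expected})")
        n_expected = n
        header = lines[pos_in_file + 1]
        fields = dict(item.split("=", 1) for item in header.split())
        try:
            sweep = int(fields["sweep"])
            box = float(fields["box_nm"])
        except (KeyError, ValueError) as err:
            raise TrajectoryParseError(
                f"frame {frame_no}: malformed header {header!r}") from err
        positions = np.empty((n, 3))
        axes = np.empty((n, 3))
        patches = np.empty((n, 3))
        states = np.empty(n, dtype=np.int64)
        for j in range(n):
            parts = lines[pos_in_file + 2 + j].split()
            if len(parts) != 9:
                raise TrajectoryParseError(
                    f"frame {frame_no}: particle line {j} has "
                    f"{len(parts)} fields, expected 9")
            states[j] = _LABEL_STATES[parts[1]]
            positions[j] = [float(v) for v in parts[2:5]]
            q = np.array([float(v) for v in parts[5:9]])
            if abs(np.linalg.norm(q) - 1.0) > 1e-6:
                raise TrajectoryParseError(
                    f"frame {frame_no}: particle {j} quaternion is not "
                    f"normalised (|q| = {np.linalg.norm(q):.6g})")
            axes[j], patches[j] = quaternion_to_frame(q)
        frames.append(Frame(sweep, positions, axes, patches, states))
        pos_in_file += 2 + n
        frame_no += 1
    if config is None:
        config = SimConfig(n_particles=n_expected or 1,
                           box_edge=box or 100.0,
                           n_sweeps=frames[-1].sweep if frames else 0)
    if model is None:
        model = ModelParams()
    return Trajectory(frames, config, model)


# ---------------------------------------------------------------------------
# HDF5 container (same content, binary)

def write_hdf5(traj: Trajectory, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        nf = len(traj.frames)
        n = traj.frames[0].n_particles
        pos = np.stack([f.positions for f in traj.frames])
        quat = np.empty((nf, n, 4))
        for a, f in enumerate(traj.frames):
            for i in range(n):
                quat[a, i] = frame_to_quaternion(f.axes[i], f.patches[i])
        h5.create_dataset("positions", data=pos)
        h5.create_dataset("quaternions", data=quat)
        h5.create_dataset("states",
                          data=np.stack([f.states for f in traj.frames]))
        h5.create_dataset("sweeps",
                          data=np.array([f.sweep for f in traj.frames]))
        h5.attrs["box_nm"] = traj.box_edge
        h5.attrs["sweep_time_ns"] = traj.config.sweep_time_ns
        h5.attrs["config_json"] = json.dumps(
            dataclasses.asdict(traj.config))


def read_hdf5(path, config: SimConfig | None = None,
              model: ModelParams | None = None) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        pos = h5["positions"][...]
        quat = h5["quaternions"][...]
        states = h5["states"][...]
        sweeps = h5["sweeps"][...]
        if config is None:
            cfg = json.loads(h5.attrs["config_json"])
            cfg["initial_state"] = str(cfg.get("initial_state", "alpha"))
            config = SimConfig(**cfg)
    frames = []
    for a in range(pos.shape[0]):
        n = pos.shape[1]
        axes = np.empty((n, 3))
        patches = np.empty((n, 3))
        for i in range(n):
            axes[i], patches[i] = quaternion_to_frame(quat[a, i])
        frames.append(Frame(int(sweeps[a]), pos[a].copy(), axes, patches,
                            states[a].astype(np.int64)))
    return Trajectory(frames, config, model or ModelParams())


def read_trajectory(path, **kw) -> Trajectory:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_hdf5(path, **kw)
    return read_xyz(path, **kw)


# ---------------------------------------------------------------------------
# mass-fraction curves as CSV

def write_curve(curve: MassFractionCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# m0_mM={curve.m0:.9g}\n")
        fh.write(f"# n_runs_averaged={curve.n_runs_averaged}\n")
        curve.to_frame().to_csv(fh, index=False)


def read_curve(path) -> MassFractionCurve:
    import io as _io

    meta = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, val = line[1:].strip().split("=", 1)
        meta[key] = val
        body_start += 1
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    sd = df["sd"].to_numpy() if "sd" in df and df["sd"].notna().any() else None
    return MassFractionCurve(
        times_ns=df["time_ns"].to_numpy(),
        fibril_mass_fraction=df["fibril_fraction"].to_numpy(),
        monomer_mM=df["monomer_mM"].to_numpy(),
        oligomer_mM=df["oligomer_mM"].to_numpy(),
        fibril_mM=df["fibril_mM"].to_numpy(),
        m0=float(meta["m0_mM"]),
        n_runs_averaged=int(meta.get("n_runs_averaged", 1)),
        sd=sd)


# ---------------------------------------------------------------------------
# synthetic fixtures

def make_synthetic_curves(n: float, k_eff: float, m0_list,
                          noise_sd: float = 0.0, seed: int = 0,
                          n_points: int = 60) -> list:
    """Closed-form growth curves on a log-spaced grid spanning
    0.01-100x the half-time, with multiplicative Gaussian noise."""
    rng = np.random.default_rng(seed)
    curves = []
    for m0 in m0_list:
        th = analytic_halftime(n, k_eff, m0)
        t = np.geomspace(0.01 * th, 100.0 * th, n_points)
        f = oosawa_curve(t, n, k_eff, m0)
        if noise_sd > 0:
            f = np.clip(f * (1.0 + noise_sd * rng.standard_normal(len(f))),
                        0.0, 1.0)
        curves.append(MassFractionCurve(
            times_ns=t, fibril_mass_fraction=f,
            monomer_mM=(1.0 - f) * m0,
            oligomer_mM=np.zeros_like(f),
            fibril_mM=f * m0, m0=float(m0)))
    return curves


def make_ideal_oligomer(size: int, n_beta: int,
                        model: ModelParams) -> Frame:
    """Minimised ideal oligomer as a placeable frame (sweep 0), centred
    at the origin."""
    e, pos, ax, pt, st = ideal_oligomer_configuration(size, n_beta, model)
    pos = pos - pos.mean(axis=0)
    return Frame(0, pos, ax.copy(), pt.copy(), st.copy())
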