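"""Dynamic Monte Carlo propagation.

Small-step rigid-body translations/rotations with Metropolis acceptance,
stochastic internal-state switching, NVT ensemble with cubic periodic
boundaries.  Move amplitudes are calibrated so that a free particle
reproduces the translational/rotational diffusion of an Abeta-scale peptide
over one sweep, which maps one sweep to ``sweep_time_ns`` of physical time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import Avogadro

from . import _kernels
from .model import ModelParams, PeptideState

#: paper-anchored time per sweep is 0.02 ns; the diffusion constants used to
#: derive the move amplitudes are configurable (Abeta-scale defaults).
DEFAULT_SWEEP_TIME_NS = 0.02


def concentration(n_particles: int, box_edge: float) -> float:
    """Molar concentration (mM) of ``n_particles`` in a cube of edge nm."""
    if n_particles < 0 or box_edge <= 0:
        raise ValueError("need n_particles >= 0 and box_edge > 0")
    volume_l = box_edge ** 3 * 1e-24  # nm^3 -> L
    return n_particles / (Avogadro * volume_l) * 1e3


def box_edge_for_concentration(n_particles: int, conc_mM: float) -> float:
    """Cube edge (nm) holding ``n_particles`` at the given concentration."""
    volume_l = n_particles / (Avogadro * conc_mM * 1e-3)
    return (volume_l * 1e24) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``max_displacement`` (nm) and ``max_rotation`` (rad) default to the
    values implied by the diffusion constants and the sweep time: a free
    particle's mean-square displacement per sweep equals ``6 * D_t * dt``
    and its mean-square rotation ``4 * D_r * dt``.
    """

    n_particles: int = 600
    box_edge: float = 100.0
    temperature: float = 1.0        # kBT units; fixed
    max_displacement: float | None = None
    max_rotation: float | None = None
    p_switch: float = 1e-4          # switch-attempt probability per move
    n_sweeps: int = 1000
    sweep_time_ns: float = DEFAULT_SWEEP_TIME_NS
    seed: int = 0
    record_every: int = 100
    diffusion_const: float = 1.5e-10     # m^2/s, translational
    rot_diffusion_const: float = 2.0e7   # 1/s, rotational
    initial_state: str = "alpha"         # or "beta" (fixed-state landscapes)
    verlet_skin: float = 2.0             # nm

    def __post_init__(self):
        if not 0.0 <= self.p_switch <= 1.0:
            raise ValueError("p_switch must be in [0, 1]")
        if self.n_particles <= 0 or self.box_edge <= 0:
            raise ValueError("n_particles and box_edge must be positive")
        if self.initial_state not in ("alpha", "beta"):
            raise ValueError("initial_state must be 'alpha' or 'beta'")
        if self.record_every <= 0:
            raise ValueError("record_every must be positive")

    def derived_max_displacement(self) -> float:
        """Radius (nm) of the uniform displacement ball: <r^2> = 3R^2/5
        must equal 6*D_t*dt."""
        if self.max_displacement is not None:
            return self.max_displacement
        d_nm2_per_ns = self.diffusion_const * 1e9  # m^2/s -> nm^2/ns
        msd = 6.0 * d_nm2_per_ns * self.sweep_time_ns
        return math.sqrt(5.0 * msd / 3.0)

    def derived_max_rotation(self) -> float:
        """Maximum rotation angle (rad): <theta^2> = thmax^2/3 must equal
        4*D_r*dt."""
        if self.max_rotation is not None:
            return self.max_rotation
        dr_per_ns = self.rot_diffusion_const * 1e-9
        ms_ang = 4.0 * dr_per_ns * self.sweep_time_ns
        return math.sqrt(3.0 * ms_ang)

    def concentration_mM(self) -> float:
        return concentration(self.n_particles, self.box_edge)

    def validate_against(self, model: ModelParams) -> None:
        if self.derived_max_displacement() >= 0.5 * model.diameter_sigma:
            raise ValueError(
                "max_displacement must stay below sigma/2 so that no "
                "unphysical moves can occur")
        if self.box_edge <= 2.0 * (model.cylinder_length
                                   + model.diameter_sigma):
            raise ValueError("box edge too small for the minimum-image "
                             "convention with this particle size")


@dataclass
class Frame:
    """One trajectory snapshot (orientations as axis/patch unit vectors)."""

    sweep: int
    positions: np.ndarray   # (N, 3) nm
    axes: np.ndarray        # (N, 3)
    patches: np.ndarray     # (N, 3)
    states: np.ndarray      # (N,) int, 0 = alpha, 1 = beta

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames plus the configuration that produced them."""

    frames: list
    config: SimConfig
    model: ModelParams
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        sweeps = [f.sweep for f in self.frames]
        if any(b <= a for a, b in zip(sweeps, sweeps[1:])):
            raise ValueError("frame sweep indices must strictly increase")
        counts = {f.n_particles for f in self.frames}
        if len(counts) > 1:
            raise ValueError("particle count must be constant across frames")

    @property
    def times_ns(self) -> np.ndarray:
        return np.array([f.sweep for f in self.frames],
                        dtype=float) * self.config.sweep_time_ns

    @property
    def box_edge(self) -> float:
        return self.config.box_edge


class System:
    """Mutable particle system exposing single-move operations.

    This is the unit the Metropolis tests drive directly; :func:`run` uses
    the same njit move kernels inside the compiled sweep loop.
    """

    def __init__(self, positions, axes, patches, states,
                 model: ModelParams, config: SimConfig):
        self.pos = np.ascontiguousarray(positions, dtype=float)
        self.ax = np.ascontiguousarray(axes, dtype=float)
        self.pt = np.ascontiguousarray(patches, dtype=float)
        self.st = np.ascontiguousarray(states, dtype=np.int64)
        self.model = model
        self.config = config
        self._pp = model.as_kernel_params()
        n = self.pos.shape[0]
        self._nbr = np.empty((n, n), dtype=np.int64)
        self._nbr_count = np.empty(n, dtype=np.int64)
        self._refresh_neighbours()

    @classmethod
    def random_initial(cls, config: SimConfig, model: ModelParams,
                       seed: int | None = None,
                       max_insertion_attempts: int | None = None) -> "System":
        """Non-overlapping random insertion of monomers, all in the
        configured initial state."""
        config.validate_against(model)
        seed = config.seed if seed is None else seed
        if max_insertion_attempts is None:
            max_insertion_attempts = 100000 * config.n_particles
        pos, ax, pt, ok = _kernels.random_insertion(
            config.n_particles, config.box_edge,
            0.5 * model.cylinder_length, model.diameter_sigma,
            _derive_seed(seed, 0), max_insertion_attempts)
        if not ok:
            raise RuntimeError("random insertion failed: density too high")
        st = np.full(config.n_particles,
                     0 if config.initial_state == "alpha" else 1,
                     dtype=np.int64)
        return cls(pos, ax, pt, st, model, config)

    def _refresh_neighbours(self):
        r_list = (self.model.cylinder_length + self.model.attraction_cutoff
                  + self.config.verlet_skin)
        _kernels.build_neighbours(self.pos, self.config.box_edge, r_list,
                                  self._nbr, self._nbr_count)

    def local_energy(self, index: int) -> float:
        return float(_kernels.local_energy(
            index, self.pos, self.ax, self.pt, self.st,
            self.config.box_edge, self._pp, self._nbr, self._nbr_count))

    def total_energy(self) -> float:
        return float(_kernels.total_energy_kernel(
            self.pos, self.ax, self.pt, self.st, self.config.box_edge,
            self._pp, 0))

    def move_particle(self, index: int, rng) -> bool:
        """One displacement+rotation Metropolis attempt; the particle is
        restored bit-exactly on rejection."""
        _kernels.seed_rng(_rng_to_seed(rng))
        self._refresh_neighbours()
        acc = _kernels.try_move(index, self.pos, self.ax, self.pt, self.st,
                                self.config.box_edge, self._pp,
                                self.config.derived_max_displacement(),
                                self.config.derived_max_rotation(),
                                self._nbr, self._nbr_count)
        return bool(acc)

    def attempt_state_switch(self, index: int, rng) -> bool:
        """One internal-state flip attempt (the p_switch draw itself is the
        caller's schedule; this is the conditional attempt)."""
        _kernels.seed_rng(_rng_to_seed(rng))
        self._refresh_neighbours()
        acc = _kernels.try_switch(index, self.pos, self.ax, self.pt, self.st,
                                  self.config.box_edge, self._pp,
                                  self.model.dG_internal,
                                  self._nbr, self._nbr_count)
        return bool(acc)

    def snapshot(self, sweep: int = 0) -> Frame:
        return Frame(sweep, self.pos.copy(), self.ax.copy(),
                     self.pt.copy(), self.st.copy())


def _rng_to_seed(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2 ** 31)
    return int(rng.integers(0, 2 ** 31))


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0]
               % (2 ** 31))


def run(config: SimConfig, model: ModelParams,
        rng_seed: int | None = None) -> Trajectory:
    """Run a DMC simulation from a fresh random monomeric configuration.

    Identical (config, model, seed) triples give bit-identical
    trajectories.  Frames are recorded every ``config.record_every`` sweeps,
    frame 0 being the initial configuration.
    """
    seed = config.seed if rng_seed is None else rng_seed
    system = System.random_initial(config, model, seed=seed)
    n = config.n_particles
    n_frames = config.n_sweeps // config.record_every + 1
    fr_pos = np.empty((n_frames, n, 3))
    fr_ax = np.empty((n_frames, n, 3))
    fr_pt = np.empty((n_frames, n, 3))
    fr_st = np.empty((n_frames, n), dtype=np.int64)
    fr_sweep = np.empty(n_frames, dtype=np.int64)
    nf, acc_m, att_m, acc_s, att_s, n_rebuild = _kernels.run_sweeps(
        system.pos, system.ax, system.pt, system.st,
        config.box_edge, model.as_kernel_params(), model.dG_internal,
        config.n_sweeps, config.derived_max_displacement(),
        config.derived_max_rotation(), config.p_switch,
        _derive_seed(seed, 1), config.record_every,
        fr_pos, fr_ax, fr_pt, fr_st, fr_sweep, config.verlet_skin)
    frames = [Frame(int(fr_sweep[i]), fr_pos[i].copy(), fr_ax[i].copy(),
                    fr_pt[i].copy(), fr_st[i].copy()) for i in range(nf)]
    stats = {
        "seed": seed,
        "accepted_moves": int(acc_m),
        "attempted_moves": int(att_m),
        "accepted_switches": int(acc_s),
        "attempted_switches": int(att_s),
        "neighbour_rebuilds": int(n_rebuild),
        "move_acceptance": float(acc_m) / att_m if att_m else float("nan"),
    }
    cfg = config if rng_seed is None else replace(config, seed=seed)
    return Trajectory(frames, cfg, model, stats)
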