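"""Two-state patchy-spherocylinder (PSC) model: parameters, particles and
energy computations.

A peptide is a rigid spherocylinder (cylinder of length ``cylinder_length``
with hemispherical caps, diameter ``diameter_sigma``) carrying an attractive
stripe along its side.  Each particle is in one of two internal states:
``ALPHA`` (soluble random coil: wide patch, shallow well) or ``BETA``
(sheet conformation: narrow patch, deep well).  Converting a monomer from
alpha to beta costs ``dG_internal`` of internal free energy.

The pair interaction acts through the closest approach of the two axis
segments: a hard core below ``diameter_sigma``, and inside the attraction
cutoff a well of depth ``-eps`` modulated by a smooth distance switch, an
angular patch gate on each particle and the axial overlap fraction of the
two segments.  The global minimum over relative poses of two particles in
the same state is exactly ``-eps`` for that state pair.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from . import _kernels


class PeptideState(IntEnum):
    """Internal conformational state of a peptide."""

    ALPHA = 0  # soluble random coil
    BETA = 1   # sheet conformation found in fibrils


@dataclass(frozen=True)
class ModelParams:
    """Geometry and interaction constants of the PSC model.

    Energies are in units of kBT, lengths in nm, angles in radians.
    ``eps_ab`` defaults to the Berthelot (geometric-mean) combination of the
    two like-pair well depths.  ``attraction_cutoff`` defaults to
    ``1.3 * diameter_sigma``.
    """

    diameter_sigma: float = 2.0
    cylinder_length: float = 8.0
    eps_bb: float = 21.0
    eps_aa: float = 8.4
    eps_ab: float | None = None
    patch_halfwidth_alpha: float = math.radians(90.0)
    patch_halfwidth_beta: float = math.radians(45.0)
    gate_shoulder: float = math.radians(10.0)
    chirality_angle: float = math.radians(10.0)
    attraction_cutoff: float | None = None
    dG_internal: float = 15.0

    def __post_init__(self):
        if self.eps_ab is None:
            object.__setattr__(self, "eps_ab",
                               math.sqrt(self.eps_aa * self.eps_bb))
        if self.attraction_cutoff is None:
            object.__setattr__(self, "attraction_cutoff",
                               1.3 * self.diameter_sigma)
        if self.attraction_cutoff <= self.diameter_sigma:
            raise ValueError("attraction_cutoff must exceed diameter_sigma")
        if self.diameter_sigma <= 0 or self.cylinder_length <= 0:
            raise ValueError("dimensions must be positive")
        for name in ("eps_bb", "eps_aa", "eps_ab", "dG_internal"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.eps_bb <= 0 or self.eps_aa <= 0:
            raise ValueError("well depths are positive magnitudes")
        for name in ("patch_halfwidth_alpha", "patch_halfwidth_beta"):
            hw = getattr(self, name)
            if not 0.0 < hw < math.pi:
                raise ValueError(f"{name} must lie in (0, pi)")

    def achiral(self) -> "ModelParams":
        """The same model with the chirality twist removed."""
        return replace(self, chirality_angle=0.0)

    def as_kernel_params(self) -> np.ndarray:
        """Pack into the float64 vector consumed by the numba kernels."""
        return np.array([
            0.5 * self.cylinder_length,
            self.diameter_sigma,
            self.attraction_cutoff,
            self.eps_aa,
            self.eps_ab,
            self.eps_bb,
            self.patch_halfwidth_alpha,
            self.patch_halfwidth_beta,
            self.gate_shoulder,
            self.chirality_angle,
        ])

    def fingerprint(self) -> tuple:
        return tuple(np.round(self.as_kernel_params(), 12))


# ---------------------------------------------------------------------------
# orientation helpers: body frame is (patch, axis x patch, axis)

def frame_to_quaternion(axis: np.ndarray, patch: np.ndarray) -> np.ndarray:
    """Quaternion (w, x, y, z) rotating the body frame (ex -> patch,
    ez -> axis) into the lab frame."""
    axis = np.asarray(axis, dtype=float)
    patch = np.asarray(patch, dtype=float)
    m = np.column_stack([patch, np.cross(axis, patch), axis])
    q = Rotation.from_matrix(m).as_quat()  # (x, y, z, w)
    return np.array([q[3], q[0], q[1], q[2]])


def quaternion_to_frame(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`frame_to_quaternion`: returns (axis, patch)."""
    q = np.asarray(q, dtype=float)
    rot = Rotation.from_quat([q[1], q[2], q[3], q[0]])
    m = rot.as_matrix()
    return m[:, 2].copy(), m[:, 0].copy()


@dataclass
class Particle:
    """Rigid spherocylinder pose plus internal state.

    ``orientation`` is a unit quaternion (w, x, y, z); the cylinder axis is
    the rotated body z axis and the patch direction the rotated body x axis
    (orthogonal to the axis before any chirality twist).
    """

    position: np.ndarray
    orientation: np.ndarray
    state: PeptideState = PeptideState.ALPHA

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")
        norm = np.linalg.norm(self.orientation)
        if self.orientation.shape != (4,) or abs(norm - 1.0) > 1e-9:
            raise ValueError("orientation must be a unit quaternion (1e-9)")
        self.state = PeptideState(self.state)

    @classmethod
    def from_axis_patch(cls, position, axis, patch,
                        state=PeptideState.ALPHA) -> "Particle":
        return cls(np.asarray(position, dtype=float),
                   frame_to_quaternion(axis, patch), state)

    @property
    def axis(self) -> np.ndarray:
        return quaternion_to_frame(self.orientation)[0]

    @property
    def patch_direction(self) -> np.ndarray:
        return quaternion_to_frame(self.orientation)[1]


def particles_to_arrays(particles) -> tuple[np.ndarray, ...]:
    """(positions, axes, patches, states) arrays from Particle records."""
    n = len(particles)
    pos = np.empty((n, 3))
    ax = np.empty((n, 3))
    pt = np.empty((n, 3))
    st = np.empty(n, dtype=np.int64)
    for i, p in enumerate(particles):
        pos[i] = p.position
        ax[i], pt[i] = quaternion_to_frame(p.orientation)
        st[i] = int(p.state)
    return pos, ax, pt, st


# ---------------------------------------------------------------------------
# operations

def segment_min_distance(pose_a: Particle, pose_b: Particle,
                         length: float, box: float = 0.0):
    """Minimum distance between the two finite axis segments.

    Returns (distance, t_a, t_b) with closest-point parameters in
    [-length/2, length/2].  ``box > 0`` applies the minimum-image convention
    to the center separation.
    """
    if length <= 0:
        raise ValueError("degenerate segment: length must be positive")
    for p in (pose_a, pose_b):
        if not (np.all(np.isfinite(p.position)) and
                np.all(np.isfinite(p.orientation))):
            raise ValueError("non-finite pose")
    r = pose_b.position - pose_a.position
    if box > 0.0:
        r -= box * np.rint(r / box)
    ua = pose_a.axis
    ub = pose_b.axis
    return _kernels.seg_seg_closest(r[0], r[1], r[2],
                                    ua[0], ua[1], ua[2],
                                    ub[0], ub[1], ub[2], 0.5 * length)


def pair_energy(a: Particle, b: Particle, params: ModelParams,
                box: float = 0.0) -> float:
    """Pair interaction energy in kBT; +inf for hard-core overlap."""
    for p in (a, b):
        if not (np.all(np.isfinite(p.position)) and
                np.all(np.isfinite(p.orientation))):
            raise ValueError("non-finite pose")
    r = b.position - a.position
    if box > 0.0:
        r -= box * np.rint(r / box)
    ua, pa = quaternion_to_frame(a.orientation)
    ub, pb = quaternion_to_frame(b.orientation)
    return _kernels.pair_energy_s(r[0], r[1], r[2],
                                  ua[0], ua[1], ua[2], pa[0], pa[1], pa[2],
                                  ub[0], ub[1], ub[2], pb[0], pb[1], pb[2],
                                  int(a.state), int(b.state),
                                  params.as_kernel_params(), 0)


def total_energy(particles, params: ModelParams, box: float = 0.0) -> float:
    """Sum of pair energies over unique pairs (minimum image); +inf and a
    flag-worthy result if any pair overlaps."""
    pos, ax, pt, st = particles_to_arrays(particles)
    return float(_kernels.total_energy_kernel(pos, ax, pt, st, float(box),
                                              params.as_kernel_params(), 0))


# ---------------------------------------------------------------------------
# pose optimisation: pair minimum and ideal oligomers

def _orientation_from_angles(theta, phi, psi):
    """Axis from spherical angles plus patch twist psi about the axis."""
    u = np.array([math.sin(theta) * math.cos(phi),
                  math.sin(theta) * math.sin(phi),
                  math.cos(theta)])
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p0 = ref - np.dot(ref, u) * u
    p0 /= np.linalg.norm(p0)
    c, s = math.cos(psi), math.sin(psi)
    p = p0 * c + np.cross(u, p0) * s
    return u, p


def minimize_pair_energy(params: ModelParams,
                         state_a: PeptideState,
                         state_b: PeptideState,
                         n_starts: int = 32,
                         seed: int = 0):
    """Global minimum of the pair energy over relative poses.

    Multi-start Nelder-Mead on (position of b, axis angles, patch twist)
    with particle a pinned at the origin (axis z, patch x), using a
    soft-core penalty so the optimizer can cross the contact boundary.
    Returns (energy_kBT, pose_vector)."""
    pp = params.as_kernel_params()
    sa, sb = int(state_a), int(state_b)

    def objective(x):
        u, p = _orientation_from_angles(x[3], x[4], x[5])
        return _kernels.pair_energy_s(x[0], x[1], x[2],
                                      0.0, 0.0, 1.0, 1.0, 0.0, 0.0,
                                      u[0], u[1], u[2], p[0], p[1], p[2],
                                      sa, sb, pp, 1)

    rng = np.random.default_rng(seed)
    reach = params.cylinder_length + params.attraction_cutoff
    starts = [
        # ideal side-by-side antiparallel-patch contact
        np.array([params.diameter_sigma, 0.0, 0.0, 0.0, 0.0, math.pi]),
        np.array([params.diameter_sigma, 0.0, 0.0, math.pi, 0.0, math.pi]),
    ]
    for _ in range(n_starts):
        starts.append(np.concatenate([
            rng.uniform(-reach, reach, 3),
            [rng.uniform(0, math.pi), rng.uniform(-math.pi, math.pi),
             rng.uniform(-math.pi, math.pi)],
        ]))
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10,
                                "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return float(best.fun), best.x


def _seed_positions(size: int, spacing: float):
    """Candidate 2D center arrangements (units of the contact distance)."""
    s = spacing
    h = s * math.sqrt(3.0) / 2.0
    chain = [(i * s, 0.0) for i in range(size)]
    seeds = [chain]
    if size >= 3:
        seeds.append([(0.0, 0.0), (s, 0.0), (0.5 * s, h)][:size] +
                     chain[3:size])
    if size == 4:
        seeds.append([(0.0, 0.0), (s, 0.0), (0.0, s), (s, s)])          # square
        seeds.append([(0.0, 0.0), (s, 0.0), (0.5 * s, h), (0.5 * s, -h)])  # rhombus
    if size == 5:
        seeds.append([(0.0, 0.0), (s, 0.0), (0.0, s), (s, s),
                      (0.5 * s, s + h)])                                 # house
        seeds.append([(0.0, 0.0), (s, 0.0), (2 * s, 0.0),
                      (0.5 * s, h), (1.5 * s, h)])                       # brick rows
        seeds.append([(0.0, 0.0), (s, 0.0), (0.0, s), (s, s),
                      (2 * s, 0.0)])                                     # square+tail
        seeds.append([(0.0, 0.0), (s, 0.0), (0.5 * s, h),
                      (0.5 * s, -h), (1.5 * s, h)])                      # fused triangles
    return seeds


def _refine_patch_angles(x0, size, pos, cutoff, objective, n_grid=48,
                         n_sweeps=2):
    """Coordinate descent over per-particle patch angles at fixed centers.

    The patch gates make the energy highly multimodal in the angles; a grid
    scan per particle reliably escapes dead-gate initialisations before the
    simplex polish."""
    x = x0.copy()
    angles = np.linspace(-math.pi, math.pi, n_grid, endpoint=False)
    coarse = np.linspace(-math.pi, math.pi, 16, endpoint=False)
    idx = [0] + [3 * i for i in range(1, size)]
    for _ in range(n_sweeps):
        # joint pair scan first: a bond only pays off when both gates open,
        # so single-angle descent deadlocks on closed pairs
        for a_i in range(size):
            for b_i in range(a_i + 1, size):
                if np.linalg.norm(pos[a_i] - pos[b_i]) >= cutoff:
                    continue
                ja, jb = idx[a_i], idx[b_i]
                best = (x[ja], x[jb], objective(x))
                for aa in coarse:
                    x[ja] = aa
                    for ab in coarse:
                        x[jb] = ab
                        e = objective(x)
                        if e < best[2]:
                            best = (aa, ab, e)
                x[ja], x[jb] = best[0], best[1]
        for j in idx:
            best_a, best_e = x[j], objective(x)
            for a in angles:
                x[j] = a
                e = objective(x)
                if e < best_e:
                    best_a, best_e = a, e
            x[j] = best_a
    return x


_oligomer_cache: dict = {}


def ideal_oligomer_configuration(size: int, n_beta: int, params: ModelParams):
    """Minimum-energy ideal configuration of a small oligomer.

    Returns (energy_kBT, positions, axes, patches, states).  The search runs
    multi-start Nelder-Mead over in-plane arrangements of parallel particles
    (the stripe runs length-wise, so the optimum keeps axes aligned) for
    every assignment of the beta states, followed by a full rigid-body
    polish in 3D.  Requires the achiral model, where the ideal contact
    geometry is planar.
    """
    if not 1 <= size <= 5:
        raise ValueError("oligomer sizes 1-5 are supported "
                         "(the landscape stops at the tetramer; the pentamer "
                         "only terminates the path)")
    if not 0 <= n_beta <= size:
        raise ValueError("n_beta must be between 0 and size")
    if params.chirality_angle != 0.0:
        raise ValueError("ideal oligomer enthalpies are defined for the "
                         "achiral model (chirality_angle = 0)")
    key = (size, n_beta, params.fingerprint())
    if key in _oligomer_cache:
        return _oligomer_cache[key]

    pp = params.as_kernel_params()
    sigma = params.diameter_sigma
    ez = np.array([0.0, 0.0, 1.0])

    if size == 1:
        out = (0.0, np.zeros((1, 3)), ez[None, :].copy(),
               np.array([[1.0, 0.0, 0.0]]),
               np.array([n_beta], dtype=np.int64))
        _oligomer_cache[key] = out
        return out

    def unpack2d(x):
        pos = np.zeros((size, 3))
        ax = np.tile(ez, (size, 1))
        pt = np.empty((size, 3))
        pt[0] = [math.cos(x[0]), math.sin(x[0]), 0.0]
        for i in range(1, size):
            px, py, phi = x[3 * i - 2:3 * i + 1]
            pos[i] = [px, py, 0.0]
            pt[i] = [math.cos(phi), math.sin(phi), 0.0]
        return pos, ax, pt

    best = (np.inf, None, None)  # energy, x, states
    rng = np.random.default_rng(1234 + size * 17 + n_beta)
    for combo in itertools.combinations(range(size), n_beta):
        st = np.zeros(size, dtype=np.int64)
        st[list(combo)] = 1

        def objective(x, st=st):
            pos, ax, pt = unpack2d(x)
            return _kernels.total_energy_kernel(pos, ax, pt, st, 0.0, pp, 1)

        starts = []
        for seed_xy in _seed_positions(size, sigma):
            x0 = np.empty(3 * size - 2)
            centroid = np.mean(seed_xy, axis=0)
            for i, (px, py) in enumerate(seed_xy):
                phi = math.atan2(centroid[1] - py, centroid[0] - px)
                if i == 0:
                    x0[0] = phi
                else:
                    x0[3 * i - 2:3 * i + 1] = (px, py, phi)
            starts.append(x0)
        for _ in range(4):
            x0 = np.empty(3 * size - 2)
            x0[0] = rng.uniform(-math.pi, math.pi)
            for i in range(1, size):
                x0[3 * i - 2:3 * i] = rng.uniform(-1.5, 1.5, 2) * sigma
                x0[3 * i] = rng.uniform(-math.pi, math.pi)
            starts.append(x0)
        for x0 in starts:
            x0 = _refine_patch_angles(x0, size, unpack2d(x0)[0],
                                      params.attraction_cutoff, objective)
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"maxiter": 3000 * size,
                                    "xatol": 1e-9, "fatol": 1e-11})
            if res.fun < best[0]:
                best = (res.fun, res.x, st.copy())

    # full rigid-body polish in 3D from the best planar arrangement
    e2d, x2d, st = best
    pos, ax, pt = unpack2d(x2d)

    def pack3d():
        x = [x2d[0]]
        for i in range(1, size):
            x.extend([pos[i, 0], pos[i, 1], 0.0, 0.0, 0.0,
                      x2d[3 * i]])
        return np.array(x)

    def unpack3d(x):
        p3 = np.zeros((size, 3))
        a3 = np.empty((size, 3))
        t3 = np.empty((size, 3))
        a3[0] = ez
        t3[0] = [math.cos(x[0]), math.sin(x[0]), 0.0]
        for i in range(1, size):
            px, py, pz, th, ph, psi = x[6 * i - 5:6 * i + 1]
            p3[i] = [px, py, pz]
            a3[i], t3[i] = _orientation_from_angles(th, ph, psi)
        return p3, a3, t3

    def objective3d(x):
        p3, a3, t3 = unpack3d(x)
        return _kernels.total_energy_kernel(p3, a3, t3, st, 0.0, pp, 1)

    res = minimize(objective3d, pack3d(), method="Nelder-Mead",
                   options={"maxiter": 4000 * size, "xatol": 1e-9,
                            "fatol": 1e-11})
    if res.fun <= e2d:
        pos, ax, pt = unpack3d(res.x)
        energy = res.fun
    else:
        energy = e2d
    # evaluate with the true hard core
    e_hard = float(_kernels.total_energy_kernel(pos, ax, pt, st, 0.0, pp, 0))
    if not math.isfinite(e_hard):
        e_hard = float(energy)  # soft value; contact resolved within switch
    out = (e_hard, pos, ax, pt, st)
    _oligomer_cache[key] = out
    return out


def ideal_oligomer_enthalpy(size: int, n_beta: int,
                            params: ModelParams) -> float:
    """Global minimum interaction energy (kBT) of an ideal i-mer with
    ``n_beta`` converted monomers; the enthalpic node of the free-energy
    landscape."""
    return ideal_oligomer_configuration(size, n_beta, params)[0]
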