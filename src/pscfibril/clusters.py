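"""Trajectory observables: cluster decomposition, oligomer mass
distributions, fibril mass-fraction curves, half-times, commitment
probabilities and residual monomer concentrations.

Two particles are bonded when their pair energy falls below an energy
cutoff (default -1 kBT); clusters are connected components of the bond
graph under the minimum-image convention.  Every oligomer of at least
``fibril_min_size`` (default 4) monomers counts as a fibril; dimers and
trimers together form the "oligomer" mass channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import _kernels
from .engine import Frame, Trajectory, concentration
from .model import ModelParams

DEFAULT_BOND_CUT = -1.0
FIBRIL_MIN_SIZE = 4


@dataclass
class Cluster:
    members: np.ndarray      # particle ids
    n_beta: int
    n_edges: int

    @property
    def size(self) -> int:
        return self.members.size

    @property
    def is_cyclic(self) -> bool:
        """True when the bond graph of this cluster is not a tree (a fibril
        bent into a closed ring registers here)."""
        return self.n_edges >= self.size


@dataclass
class ClusterDecomposition:
    """Partition of one frame into bonded clusters."""

    labels: np.ndarray       # per-particle cluster label
    clusters: list           # list[Cluster]
    sweep: int = 0

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters], dtype=int)

    def size_counts(self, max_size: int) -> np.ndarray:
        """counts[i] = number of i-mers, i = 1..max_size (index 0 unused)."""
        counts = np.zeros(max_size + 1, dtype=float)
        for c in self.clusters:
            if c.size <= max_size:
                counts[c.size] += 1
        return counts


def find_clusters(frame: Frame, model: ModelParams, box: float,
                  bond_energy_cut: float = DEFAULT_BOND_CUT,
                  sweep: int | None = None) -> ClusterDecomposition:
    """Connected components of the bond graph of one frame."""
    n = frame.n_particles
    edges = _kernels.bond_edges_kernel(frame.positions, frame.axes,
                                       frame.patches, frame.states,
                                       box, model.as_kernel_params(),
                                       bond_energy_cut)
    if len(edges):
        data = np.ones(len(edges))
        adj = coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    clusters = []
    edge_labels = labels[edges[:, 0]] if len(edges) else np.empty(0, int)
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        clusters.append(Cluster(
            members=members,
            n_beta=int(frame.states[members].sum()),
            n_edges=int(np.count_nonzero(edge_labels == lab)),
        ))
    return ClusterDecomposition(labels, clusters,
                                frame.sweep if sweep is None else sweep)


def decompose_trajectory(traj: Trajectory,
                         bond_energy_cut: float = DEFAULT_BOND_CUT) -> list:
    return [find_clusters(f, traj.model, traj.box_edge, bond_energy_cut)
            for f in traj.frames]


@dataclass
class MassFractionCurve:
    """Relative fibril mass vs time plus the per-channel concentrations.

    Mass is conserved: monomer + oligomer + fibril concentrations add up to
    the initial monomer concentration ``m0`` at every frame.
    """

    times_ns: np.ndarray
    fibril_mass_fraction: np.ndarray
    monomer_mM: np.ndarray
    oligomer_mM: np.ndarray
    fibril_mM: np.ndarray
    m0: float
    n_runs_averaged: int = 1
    sd: np.ndarray | None = None

    def __post_init__(self):
        f = np.asarray(self.fibril_mass_fraction, dtype=float)
        if np.any((f < -1e-12) | (f > 1 + 1e-12)):
            raise ValueError("mass fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_ns": self.times_ns,
            "monomer_mM": self.monomer_mM,
            "oligomer_mM": self.oligomer_mM,
            "fibril_mM": self.fibril_mM,
            "fibril_fraction": self.fibril_mass_fraction,
        })
        df["sd"] = self.sd if self.sd is not None else np.nan
        return df


def mass_fraction_series(traj: Trajectory,
                         fibril_min_size: int = FIBRIL_MIN_SIZE,
                         bond_energy_cut: float = DEFAULT_BOND_CUT,
                         decompositions: list | None = None
                         ) -> MassFractionCurve:
    """Per-frame mass split into monomers, oligomers (dimers+trimers) and
    fibrils (clusters of at least ``fibril_min_size``)."""
    decs = decompositions or decompose_trajectory(traj, bond_energy_cut)
    n = traj.frames[0].n_particles
    m0 = concentration(n, traj.box_edge)
    mono = np.empty(len(decs))
    olig = np.empty(len(decs))
    fib = np.empty(len(decs))
    for k, dec in enumerate(decs):
        sizes = dec.sizes
        n_mono = int(sizes[sizes == 1].sum())
        n_fib = int(sizes[sizes >= fibril_min_size].sum())
        n_olig = n - n_mono - n_fib
        mono[k] = n_mono / n * m0
        olig[k] = n_olig / n * m0
        fib[k] = n_fib / n * m0
    return MassFractionCurve(
        times_ns=traj.times_ns,
        fibril_mass_fraction=fib / m0,
        monomer_mM=mono, oligomer_mM=olig, fibril_mM=fib, m0=m0)


def average_curves(curves: list) -> MassFractionCurve:
    """Pointwise mean and standard deviation over replicate runs.

    Curves on different time grids are linearly resampled onto the grid of
    the first curve."""
    if not curves:
        raise ValueError("no curves to average")
    t = curves[0].times_ns
    stacks = {"f": [], "mono": [], "olig": [], "fib": []}
    for c in curves:
        if np.array_equal(c.times_ns, t):
            f, mo, ol, fi = (c.fibril_mass_fraction, c.monomer_mM,
                             c.oligomer_mM, c.fibril_mM)
        else:
            f = np.interp(t, c.times_ns, c.fibril_mass_fraction)
            mo = np.interp(t, c.times_ns, c.monomer_mM)
            ol = np.interp(t, c.times_ns, c.oligomer_mM)
            fi = np.interp(t, c.times_ns, c.fibril_mM)
        stacks["f"].append(f)
        stacks["mono"].append(mo)
        stacks["olig"].append(ol)
        stacks["fib"].append(fi)
    f = np.mean(stacks["f"], axis=0)
    return MassFractionCurve(
        times_ns=t,
        fibril_mass_fraction=f,
        monomer_mM=np.mean(stacks["mono"], axis=0),
        oligomer_mM=np.mean(stacks["olig"], axis=0),
        fibril_mM=np.mean(stacks["fib"], axis=0),
        m0=float(np.mean([c.m0 for c in curves])),
        n_runs_averaged=int(sum(c.n_runs_averaged for c in curves)),
        sd=np.std(stacks["f"], axis=0, ddof=0),
    )


def halftime(curve: MassFractionCurve,
             plateau_fraction: float = 0.1) -> float:
    """First crossing time (ns) of half the plateau value.

    The plateau is the mean of the final ``plateau_fraction`` of points;
    the crossing is located by linear interpolation."""
    f = np.asarray(curve.fibril_mass_fraction, dtype=float)
    t = np.asarray(curve.times_ns, dtype=float)
    n_tail = max(1, int(math.ceil(plateau_fraction * len(f))))
    plateau = float(np.mean(f[-n_tail:]))
    target = 0.5 * plateau
    if plateau <= 0 or f.max() < target:
        raise ValueError(
            f"curve never reaches half its plateau (plateau={plateau:.4g}, "
            f"max={f.max():.4g}); growth has not progressed far enough")
    above = np.flatnonzero(f >= target)
    k = above[0]
    if k == 0:
        return float(t[0])
    t0, t1 = t[k - 1], t[k]
    f0, f1 = f[k - 1], f[k]
    if f1 == f0:
        return float(t1)
    return float(t0 + (target - f0) * (t1 - t0) / (f1 - f0))


@dataclass
class CommitmentResult:
    size: int
    probability: float | None
    n_events: int
    n_committed: int
    n_unresolved: int


def commitment_probability(decompositions: list, size: int,
                           fibril_min_size: int = FIBRIL_MIN_SIZE
                           ) -> CommitmentResult:
    """Fraction of first-appearance clusters of ``size`` that grow to
    fibril scale before dissolving back to monomers.

    Clusters are tracked across frames by particle overlap (>50% of the
    smaller set).  A cluster of size s commits when it reaches
    ``max(fibril_min_size, 2*s)``; it dissolves when its tracked successor
    disappears.  Clusters still unresolved at the end of the trajectory are
    excluded from the denominator.
    """
    # sub-fibril oligomers commit by reaching fibril scale; a cluster already
    # at fibril scale commits by doubling (growing into a full fibre)
    target = fibril_min_size if size < fibril_min_size else 2 * size
    n_events = n_committed = n_unresolved = 0
    seen: set = set()  # frozensets of members already counted as events
    for start, dec in enumerate(decompositions):
        for c in dec.clusters:
            if c.size != size:
                continue
            key = frozenset(c.members.tolist())
            if key in seen:
                continue
            seen.add(key)
            n_events += 1
            fate = _track_fate(decompositions, start, c, target)
            if fate == "committed":
                n_committed += 1
            elif fate == "unresolved":
                n_unresolved += 1
    resolved = n_events - n_unresolved
    prob = n_committed / resolved if resolved else None
    return CommitmentResult(size, prob, n_events, n_committed, n_unresolved)


def _track_fate(decompositions, start, cluster, target) -> str:
    members = set(cluster.members.tolist())
    for dec in decompositions[start + 1:]:
        best, overlap = None, 0
        for c in dec.clusters:
            if c.size < 2:
                continue
            ov = len(members & set(c.members.tolist()))
            if ov > overlap:
                best, overlap = c, ov
        if best is None or overlap < 0.5 * min(len(members), best.size):
            return "dissolved"
        if best.size >= target:
            return "committed"
        members = set(best.members.tolist())
    return "unresolved"


@dataclass
class ResidualMonomer:
    concentration_mM: float
    stderr_mM: float
    plateau_reached: bool


def residual_monomer(curve: MassFractionCurve,
                     plateau_fraction: float = 0.1) -> ResidualMonomer:
    """Late-time equilibrium monomer concentration: mean over the final
    10% of frames, with a flag when the trace is still drifting."""
    mono = np.asarray(curve.monomer_mM, dtype=float)
    n_tail = max(2, int(math.ceil(plateau_fraction * len(mono))))
    tail = mono[-n_tail:]
    prev = mono[-2 * n_tail:-n_tail] if len(mono) >= 2 * n_tail else tail
    value = float(tail.mean())
    se = float(tail.std(ddof=1) / math.sqrt(len(tail))) if len(tail) > 1 else 0.0
    drift = abs(float(prev.mean()) - value)
    plateau = drift <= max(3.0 * se, 0.02 * curve.m0)
    return ResidualMonomer(value, se, plateau)


def cluster_event_log(decompositions: list,
                      fibril_min_size: int = FIBRIL_MIN_SIZE,
                      sweep_time_ns: float = 1.0) -> pd.DataFrame:
    """Birth/death ledger of every tracked cluster (id, birth/death sweep,
    maximum size, fate)."""
    rows = []
    active: dict = {}   # id -> (members, birth, max_size)
    next_id = 0
    for dec in decompositions:
        cur = [c for c in dec.clusters if c.size >= 2]
        matched = set()
        new_active = {}
        for c in cur:
            mem = set(c.members.tolist())
            best_id, overlap = None, 0
            for cid, (pmem, birth, mx) in active.items():
                ov = len(mem & pmem)
                if ov > overlap:
                    best_id, overlap = cid, ov
            if best_id is not None and best_id not in matched and \
                    overlap > 0.5 * min(len(mem), len(active[best_id][0])):
                _, birth, mx = active[best_id]
                new_active[best_id] = (mem, birth, max(mx, c.size))
                matched.add(best_id)
            else:
                new_active[next_id] = (mem, dec.sweep, c.size)
                next_id += 1
        for cid, (mem, birth, mx) in active.items():
            if cid not in new_active:
                rows.append((cid, birth, dec.sweep, mx,
                             "fibril" if mx >= fibril_min_size
                             else "dissolved"))
        active = new_active
    last_sweep = decompositions[-1].sweep if decompositions else 0
    for cid, (mem, birth, mx) in active.items():
        rows.append((cid, birth, -1, mx,
                     "fibril" if mx >= fibril_min_size else "open"))
    df = pd.DataFrame(rows, columns=["cluster_id", "birth_sweep",
                                     "death_sweep", "max_size", "fate"])
    return df.sort_values("cluster_id").reset_index(drop=True)
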