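"""Free-energy landscape of small oligomers.

The free energy of a mixed i-mer with k converted (beta) monomers is
decomposed into three additive parts,

    F(i, k) = dH(i, k) + k * dG_internal - T * [ (i-k) s_alpha(i)
                                                 + k s_beta(i) ],

referenced to the free monomer in the alpha state, F(1, 0) = 0.  The
enthalpy dH is the minimum interaction energy of the ideal i-mer; the
internal term charges the conformational conversion penalty once per
converted monomer; the entropic term uses per-monomer entropies extracted
from the cluster-size populations of fixed-state (pure alpha / pure beta)
achiral simulations:

    F_i = -kBT ln( <N_i> / <N_1> ),      -T s(i) = (F_i - dH_i) / i .

A single particle's translational/rotational entropy is taken to be
state-independent, so s_alpha(1) = s_beta(1) = 0 and the monomer
conversion cost is exactly dG_internal.  The minimum-free-energy path from
the free monomer to the first fully converted tetramer (monomer addition
in alpha, single conversions) identifies the critical nucleus as the
highest-F species along the path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import DEFAULT_BOND_CUT, decompose_trajectory
from .engine import Trajectory
from .model import ModelParams, ideal_oligomer_enthalpy


@dataclass
class PopulationTable:
    """Mean cluster-size populations of a fixed-state simulation."""

    mean_counts: np.ndarray        # index i = 1..max_size; [0] unused
    state: str                     # "alpha" or "beta"
    concentration_mM: float
    n_frames: int
    per_frame_counts: np.ndarray | None = None  # (n_frames, max_size+1)

    def __post_init__(self):
        if np.any(self.mean_counts < 0):
            raise ValueError("populations must be non-negative")
        if self.state not in ("alpha", "beta"):
            raise ValueError("state must be 'alpha' or 'beta'")


def population_table_from_trajectory(traj: Trajectory, state: str,
                                     max_size: int = 5,
                                     bond_energy_cut: float = DEFAULT_BOND_CUT,
                                     equilibration_fraction: float = 0.2
                                     ) -> PopulationTable:
    """Count i-mers per frame (after discarding the equilibration window)
    and average."""
    decs = decompose_trajectory(traj, bond_energy_cut)
    start = int(math.floor(equilibration_fraction * len(decs)))
    decs = decs[start:] or decs
    counts = np.array([d.size_counts(max_size) for d in decs])
    return PopulationTable(
        mean_counts=counts.mean(axis=0), state=state,
        concentration_mM=traj.config.concentration_mM(),
        n_frames=len(decs), per_frame_counts=counts)


@dataclass
class FreeEnergyEstimate:
    values: np.ndarray             # F_i, kBT, index i
    stderr: np.ndarray
    lower_bound: np.ndarray        # True where N_i = 0 -> F_i = +inf


def population_free_energies(pop: PopulationTable,
                             n_blocks: int = 5) -> FreeEnergyEstimate:
    """F_i = -ln(<N_i>/<N_1>) in kBT relative to the monomer, with block
    averaging for the statistical error."""
    counts = pop.mean_counts
    if counts[1] <= 0:
        raise ValueError("no monomers observed; F_i is referenced to <N_1>")
    max_size = len(counts) - 1
    values = np.full(max_size + 1, np.nan)
    stderr = np.zeros(max_size + 1)
    lower = np.zeros(max_size + 1, dtype=bool)
    for i in range(1, max_size + 1):
        if counts[i] > 0:
            values[i] = -math.log(counts[i] / counts[1])
        else:
            values[i] = math.inf
            lower[i] = True
    if pop.per_frame_counts is not None and len(pop.per_frame_counts) >= n_blocks:
        blocks = np.array_split(pop.per_frame_counts, n_blocks)
        for i in range(2, max_size + 1):
            fs = []
            for b in blocks:
                m = b.mean(axis=0)
                if m[i] > 0 and m[1] > 0:
                    fs.append(-math.log(m[i] / m[1]))
            if len(fs) >= 2:
                stderr[i] = float(np.std(fs, ddof=1) / math.sqrt(len(fs)))
    return FreeEnergyEstimate(values, stderr, lower)


def entropy_per_monomer(F_i: float, H_i: float, i: int) -> float:
    """-T*s contribution per monomer of a pure i-mer: (F_i - H_i)/i.

    Fixed-state simulations never pay the internal conversion term, so it
    is excluded here by construction."""
    if not math.isfinite(F_i):
        raise ValueError("F_i must be finite to extract an entropy")
    return (F_i - H_i) / i


def entropy_table(pop: PopulationTable, model: ModelParams,
                  max_size: int = 4) -> np.ndarray:
    """Per-monomer -T*s for i = 1..max_size from one pure-state run."""
    fe = population_free_energies(pop)
    state_beta = pop.state == "beta"
    s = np.full(max_size + 1, np.nan)
    s[1] = 0.0  # reference: a lone particle's entropy is state-independent
    for i in range(2, max_size + 1):
        h = ideal_oligomer_enthalpy(i, i if state_beta else 0,
                                    model.achiral())
        s[i] = entropy_per_monomer(fe.values[i], h, i)
    return s


@dataclass
class FELandscape:
    """Free energy F(i, k) with its additive decomposition.

    Arrays are indexed [i, k] with i = 0..max_size (row 0 unused) and
    k <= i; inaccessible nodes hold NaN.
    """

    F: np.ndarray
    enthalpy: np.ndarray           # dH(i, k)
    internal: np.ndarray           # k * dG_internal
    entropic: np.ndarray           # -T * [(i-k) s_a(i) + k s_b(i)]
    concentration_mM: float
    dG_internal: float
    max_size: int

    def node(self, i: int, k: int) -> float:
        if not (1 <= i <= self.max_size and 0 <= k <= i):
            raise KeyError(f"node (i={i}, k={k}) outside the landscape")
        return float(self.F[i, k])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(1, self.max_size + 1):
            for k in range(i + 1):
                rows.append((i, k, self.enthalpy[i, k], self.internal[i, k],
                             self.entropic[i, k], self.F[i, k]))
        return pd.DataFrame(rows, columns=[
            "size_i", "n_beta_k", "enthalpy_kBT", "internal_kBT",
            "entropy_term_kBT", "free_energy_kBT"])

    def render(self) -> str:
        """Plain-text grid, sizes across, conversion count down."""
        lines = ["F(i, k) / kBT at %.3g mM" % self.concentration_mM]
        header = "k\\i " + "".join(f"{i:>9d}" for i in
                                   range(1, self.max_size + 1))
        lines.append(header)
        for k in range(self.max_size + 1):
            cells = []
            for i in range(1, self.max_size + 1):
                cells.append(f"{self.F[i, k]:>9.2f}" if k <= i
                             else " " * 9)
            lines.append(f"{k:>3d} " + "".join(cells))
        return "\n".join(lines)


def build_landscape(s_alpha, s_beta, model: ModelParams,
                    concentration_mM: float,
                    max_size: int = 4) -> FELandscape:
    """Assemble F(i, k) from the two pure-state entropy tables and the
    ideal enthalpies; s tables give -T*s per monomer for i = 1..max_size."""
    s_alpha = np.asarray(s_alpha, dtype=float)
    s_beta = np.asarray(s_beta, dtype=float)
    for name, s in (("alpha", s_alpha), ("beta", s_beta)):
        if len(s) < max_size + 1 or np.any(~np.isfinite(s[1:max_size + 1])):
            bad = [i for i in range(1, max_size + 1)
                   if len(s) <= i or not math.isfinite(s[i])]
            raise ValueError(
                f"missing {name}-state entropy for i-mer sizes {bad}")
    shape = (max_size + 1, max_size + 1)
    F = np.full(shape, np.nan)
    H = np.full(shape, np.nan)
    G = np.full(shape, np.nan)
    S = np.full(shape, np.nan)
    achiral = model.achiral()
    for i in range(1, max_size + 1):
        for k in range(i + 1):
            H[i, k] = ideal_oligomer_enthalpy(i, k, achiral)
            G[i, k] = k * model.dG_internal
            S[i, k] = (i - k) * s_alpha[i] + k * s_beta[i]
            F[i, k] = H[i, k] + G[i, k] + S[i, k]
    return FELandscape(F, H, G, S, concentration_mM,
                       model.dG_internal, max_size)


@dataclass
class NucleationPath:
    nodes: list                    # [(i, k), ...] from (1, 0)
    free_energies: list            # F at each node
    step_dF: list
    barrier_node: tuple
    barrier_F: float

    @property
    def nucleus_size(self) -> int:
        return self.barrier_node[0]

    def summary(self) -> str:
        steps = " -> ".join(f"({i},{k})" for i, k in self.nodes)
        return (f"path: {steps}\n"
                f"critical nucleus: (i={self.barrier_node[0]}, "
                f"k={self.barrier_node[1]}) at {self.barrier_F:.2f} kBT")


def enumerate_paths(max_size: int):
    """All monotone paths (1,0) -> (max_size, max_size) using monomer
    addition in alpha, (i,k)->(i+1,k), and single conversion,
    (i,k)->(i,k+1)."""
    paths = []

    def extend(path):
        i, k = path[-1]
        if (i, k) == (max_size, max_size):
            paths.append(list(path))
            return
        if i < max_size:
            extend(path + [(i + 1, k)])
        if k < i:
            extend(path + [(i, k + 1)])

    extend([(1, 0)])
    return paths


def min_free_energy_path(landscape: FELandscape) -> NucleationPath:
    """Lowest-barrier monotone path from the free alpha monomer to the
    first fully converted fibril-competent species.

    The node graph is tiny, so the path is found by exhaustive enumeration:
    among all monotone paths the one minimising the ordered list of its
    free energies (highest first) is selected -- the minimax path with
    deterministic tie-breaking."""
    best_key, best = None, None
    for p in enumerate_paths(landscape.max_size):
        fs = [landscape.F[i, k] for i, k in p]
        key = tuple(sorted(fs, reverse=True))
        if best_key is None or key < best_key:
            best_key, best = key, p
    fs = [float(landscape.F[i, k]) for i, k in best]
    barrier_idx = int(np.argmax(fs))
    return NucleationPath(
        nodes=best, free_energies=fs,
        step_dF=[b - a for a, b in zip(fs, fs[1:])],
        barrier_node=best[barrier_idx], barrier_F=fs[barrier_idx])
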