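"""Shared fixtures: model parameters, ideal configurations, and the
session-scoped scaled-down simulation campaign used by the acceptance
suite."""

from __future__ import annotations

import numpy as np
import pytest

from pscfibril.clusters import (average_curves, decompose_trajectory,
                                mass_fraction_series)
from pscfibril.engine import SimConfig, box_edge_for_concentration, run
from pscfibril.model import (ModelParams, Particle, PeptideState,
                             ideal_oligomer_enthalpy)

CAMPAIGN_CONCENTRATIONS = (2.0, 4.0, 8.0)   # mM
CAMPAIGN_N = 150
CAMPAIGN_SWEEPS = 60_000
CAMPAIGN_SEEDS = (21, 22, 23)


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def achiral_params() -> ModelParams:
    return ModelParams().achiral()


def ideal_dimer(state_a=PeptideState.BETA, state_b=PeptideState.BETA,
                sigma=2.0):
    """Side-by-side parallel contact pair with patches facing: the global
    pair-energy minimum geometry."""
    a = Particle.from_axis_patch([0.0, 0.0, 0.0], [0, 0, 1], [1, 0, 0],
                                 state_a)
    b = Particle.from_axis_patch([sigma, 0.0, 0.0], [0, 0, 1], [-1, 0, 0],
                                 state_b)
    return a, b


@pytest.fixture(scope="session")
def enthalpy_table(achiral_params):
    """Minimised ideal-oligomer interaction energies H(i, k), i <= 4."""
    return {(i, k): ideal_oligomer_enthalpy(i, k, achiral_params)
            for i in range(1, 5) for k in range(i + 1)}


@pytest.fixture(scope="session")
def campaign(default_params):
    """Scaled-down growth campaign: 150 particles at 2/4/8 mM, three
    seeds per concentration averaged as in the full protocol.

    Returns dict with per-concentration averaged curves, the raw curves,
    and the cluster decompositions of the fastest run (for commitment
    analysis, where events must resolve within the trajectory)."""
    averaged = {}
    raw = {}
    decs_fast = None
    for conc in CAMPAIGN_CONCENTRATIONS:
        box = box_edge_for_concentration(CAMPAIGN_N, conc)
        curves = []
        for seed in CAMPAIGN_SEEDS:
            cfg = SimConfig(n_particles=CAMPAIGN_N, box_edge=box,
                            n_sweeps=CAMPAIGN_SWEEPS, record_every=250,
                            seed=seed)
            traj = run(cfg, default_params)
            if conc == CAMPAIGN_CONCENTRATIONS[-1] \
                    and seed == CAMPAIGN_SEEDS[0]:
                decs_fast = decompose_trajectory(traj)
            curves.append(mass_fraction_series(traj))
        raw[conc] = curves
        averaged[conc] = average_curves(curves)
    return {"averaged": averaged, "raw": raw, "decs_fast": decs_fast}


@pytest.fixture(scope="session")
def free_gas_fractions():
    """Equilibrium beta fractions of a non-interacting two-state gas at
    several internal penalties, with block-averaged standard errors."""
    out = {}
    for dg in (0.0, 1.0, 2.0, 3.0):
        params = ModelParams(eps_bb=1e-9, eps_aa=1e-9, dG_internal=dg)
        cfg = SimConfig(n_particles=128, box_edge=60.0, n_sweeps=600,
                        record_every=2, p_switch=0.5, seed=5)
        traj = run(cfg, params)
        fr = np.array([f.states.mean() for f in traj.frames[75:]])
        blocks = np.array_split(fr, 10)
        means = [b.mean() for b in blocks]
        out[dg] = (float(fr.mean()),
                   float(np.std(means, ddof=1) / np.sqrt(len(means))))
    return out
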