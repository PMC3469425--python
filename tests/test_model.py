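"""Geometry and energy of the two-state patchy spherocylinder."""

import math

import numpy as np
import pytest

from pscfibril.model import (ModelParams, Particle, PeptideState,
                             ideal_oligomer_enthalpy, minimize_pair_energy,
                             pair_energy, segment_min_distance, total_energy)
from conftest import ideal_dimer

EPS_AB = math.sqrt(8.4 * 21.0)


def random_particle(rng, span=10.0, state=PeptideState.BETA):
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    v = rng.standard_normal(3)
    patch = v - v.dot(axis) * axis
    patch /= np.linalg.norm(patch)
    return Particle.from_axis_patch(rng.uniform(0, span, 3), axis, patch,
                                    state)


class TestSegmentDistance:
    def test_parallel_offset(self):
        a = Particle.from_axis_patch([0, 0, 0], [0, 0, 1], [1, 0, 0])
        b = Particle.from_axis_patch([3.0, 0, 0], [0, 0, 1], [1, 0, 0])
        d, ta, tb = segment_min_distance(a, b, 8.0)
        assert d == pytest.approx(3.0, abs=1e-12)
        assert ta == pytest.approx(tb, abs=1e-12)

    def test_perpendicular_crossing(self):
        a = Particle.from_axis_patch([0, 0, 0], [0, 0, 1], [1, 0, 0])
        b = Particle.from_axis_patch([2.5, 0, 0], [0, 1, 0], [1, 0, 0])
        d, ta, tb = segment_min_distance(a, b, 8.0)
        assert d == pytest.approx(2.5, abs=1e-12)
        assert ta == pytest.approx(0.0, abs=1e-12)
        assert tb == pytest.approx(0.0, abs=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = random_particle(rng)
            b = random_particle(rng)
            d1, _, _ = segment_min_distance(a, b, 8.0)
            d2, _, _ = segment_min_distance(b, a, 8.0)
            assert d1 == pytest.approx(d2, abs=1e-10)

    def test_against_brute_force_grid(self):
        """Exact closest approach vs dense sampling of both segments."""
        rng = np.random.default_rng(1)
        hl = 4.0
        t = np.linspace(-hl, hl, 1500)
        for _ in range(50):
            a = random_particle(rng, span=6.0)
            b = random_particle(rng, span=6.0)
            d, _, _ = segment_min_distance(a, b, 2 * hl)
            pa = a.position[None, :] + t[:, None] * a.axis[None, :]
            pb = b.position[None, :] + t[:, None] * b.axis[None, :]
            diff = pa[:, None, :] - pb[None, :, :]
            d_grid = np.sqrt((diff ** 2).sum(-1)).min()
            assert d <= d_grid + 1e-9
            assert d_grid - d <= 1e-3

    def test_zero_length_rejected(self):
        a, b = ideal_dimer()
        with pytest.raises(ValueError):
            segment_min_distance(a, b, 0.0)


class TestPairEnergy:
    def test_printed_well_depths(self, default_params):
        """Ideal side-by-side contacts hit the configured well depths."""
        cases = [
            (PeptideState.BETA, PeptideState.BETA, -21.0),
            (PeptideState.ALPHA, PeptideState.ALPHA, -8.4),
            (PeptideState.ALPHA, PeptideState.BETA, -EPS_AB),
        ]
        for sa, sb, expected in cases:
            a, b = ideal_dimer(sa, sb)
            assert pair_energy(a, b, default_params) == \
                pytest.approx(expected, abs=1e-9)

    def test_zero_beyond_cutoff(self, default_params):
        a, b = ideal_dimer()
        b.position[0] = default_params.attraction_cutoff + 1e-9
        assert pair_energy(a, b, default_params) == 0.0

    def test_overlap_is_infinite(self, default_params):
        a, b = ideal_dimer()
        b.position[0] = 1.5
        assert pair_energy(a, b, default_params) == math.inf

    def test_symmetry(self, default_params):
        rng = np.random.default_rng(2)
        states = [PeptideState.ALPHA, PeptideState.BETA]
        for k in range(1000):
            a = random_particle(rng, span=5.0, state=states[k % 2])
            b = random_particle(rng, span=5.0, state=states[(k // 2) % 2])
            assert pair_energy(a, b, default_params) == \
                pytest.approx(pair_energy(b, a, default_params), abs=1e-12)

    def test_attraction_never_deeper_than_well(self, default_params):
        rng = np.random.default_rng(3)
        for _ in range(500):
            a = random_particle(rng, span=4.0)
            b = random_particle(rng, span=4.0)
            e = pair_energy(a, b, default_params)
            assert e >= -default_params.eps_bb - 1e-12

    def test_global_minimum_normalisation(self, default_params):
        """Multi-start minimisation over relative poses recovers the
        configured well depth for each state pair within 1%."""
        for sa, sb, eps in [
            (PeptideState.BETA, PeptideState.BETA, 21.0),
            (PeptideState.ALPHA, PeptideState.ALPHA, 8.4),
            (PeptideState.ALPHA, PeptideState.BETA, EPS_AB),
        ]:
            e, _ = minimize_pair_energy(default_params, sa, sb,
                                        n_starts=16, seed=7)
            assert e == pytest.approx(-eps, rel=0.01)

    def test_non_finite_pose_rejected(self, default_params):
        a, b = ideal_dimer()
        b.position[0] = math.nan
        with pytest.raises(ValueError):
            pair_energy(a, b, default_params)


class TestTotalEnergy:
    def test_single_particle(self, default_params):
        a, _ = ideal_dimer()
        assert total_energy([a], default_params, box=50.0) == 0.0

    def test_two_isolated_dimers(self, default_params):
        a, b = ideal_dimer()
        c, d = ideal_dimer()
        for p in (c, d):
            p.position = p.position + np.array([0.0, 20.0, 0.0])
        assert total_energy([a, b, c, d], default_params, box=50.0) == \
            pytest.approx(-42.0, abs=1e-9)

    def test_matches_pairwise_double_loop(self, default_params):
        rng = np.random.default_rng(4)
        parts = [random_particle(rng, span=12.0,
                                 state=PeptideState(int(rng.integers(2))))
                 for _ in range(20)]
        box = 40.0
        expected = 0.0
        for i in range(20):
            for j in range(i + 1, 20):
                expected += pair_energy(parts[i], parts[j],
                                        default_params, box=box)
        assert total_energy(parts, default_params, box=box) == \
            pytest.approx(expected, abs=1e-9)

    def test_pbc_lattice_translation_invariance(self, default_params):
        rng = np.random.default_rng(5)
        parts = [random_particle(rng, span=12.0) for _ in range(12)]
        box = 40.0
        e0 = total_energy(parts, default_params, box=box)
        shifted = [Particle(p.position + np.array([box, -2 * box, box]),
                            p.orientation, p.state) for p in parts]
        assert total_energy(shifted, default_params, box=box) == \
            pytest.approx(e0, abs=1e-9)


class TestModelParams:
    def test_berthelot_closure(self):
        p = ModelParams(eps_aa=5.0, eps_bb=30.0)
        assert p.eps_ab ** 2 == pytest.approx(5.0 * 30.0, rel=1e-14)

    def test_defaults_match_reference_values(self):
        p = ModelParams()
        assert (p.eps_bb, p.eps_aa, p.dG_internal) == (21.0, 8.4, 15.0)

    def test_achiral_reduction(self, default_params):
        assert default_params.achiral() == ModelParams(chirality_angle=0.0)
        # chirality only twists the gate away from the axial midplane, so
        # the centred ideal contact is unchanged
        a, b = ideal_dimer()
        assert pair_energy(a, b, default_params) == \
            pytest.approx(pair_energy(a, b, default_params.achiral()),
                          abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParams(attraction_cutoff=1.0)
        with pytest.raises(ValueError):
            ModelParams(patch_halfwidth_beta=4.0)
        with pytest.raises(ValueError):
            ModelParams(eps_aa=-1.0)


class TestIdealOligomers:
    def test_monomer_is_zero(self, achiral_params):
        assert ideal_oligomer_enthalpy(1, 0, achiral_params) == 0.0
        assert ideal_oligomer_enthalpy(1, 1, achiral_params) == 0.0

    def test_dimer_minima(self, enthalpy_table):
        assert enthalpy_table[(2, 0)] == pytest.approx(-8.4, abs=1e-3)
        assert enthalpy_table[(2, 1)] == pytest.approx(-EPS_AB, abs=1e-3)
        assert enthalpy_table[(2, 2)] == pytest.approx(-21.0, abs=1e-3)

    def test_trimer_tetramer_bond_accounting(self, enthalpy_table):
        """Frozen optimizer values, cross-checked against the bond-count
        decomposition of the optimal planar arrangements (triangle for
        trimers; rhombus/square for tetramers, where the narrow sheet patch
        can keep only four of five contacts alive)."""
        expected = {
            (3, 0): -3 * 8.4,
            (3, 1): -(8.4 + 2 * EPS_AB),
            (3, 2): -(21.0 + 2 * EPS_AB),
            (3, 3): -3 * 21.0,
            (4, 0): -5 * 8.4,
            (4, 1): -(3 * 8.4 + 2 * EPS_AB),
            (4, 2): -(8.4 + 4 * EPS_AB),
            (4, 3): -(2 * 21.0 + 2 * EPS_AB),
            (4, 4): -4 * 21.0,
        }
        for key, val in expected.items():
            assert enthalpy_table[key] == pytest.approx(val, abs=1e-2), key

    def test_monotone_in_size(self, enthalpy_table):
        for k_frac, seq in ((0, [(i, 0) for i in range(1, 5)]),
                            (1, [(i, i) for i in range(1, 5)])):
            vals = [enthalpy_table.get(node, 0.0) for node in seq]
            assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_unsupported_sizes_and_chirality(self, default_params,
                                             achiral_params):
        with pytest.raises(ValueError):
            ideal_oligomer_enthalpy(6, 0, achiral_params)
        with pytest.raises(ValueError):
            ideal_oligomer_enthalpy(2, 3, achiral_params)
        with pytest.raises(ValueError):
            ideal_oligomer_enthalpy(2, 0, default_params)  # chiral
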