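"""Cluster decomposition and the kinetic observables built on it."""

import math

import numpy as np
import pytest

from pscfibril.clusters import (ClusterDecomposition, Cluster,
                                MassFractionCurve, average_curves,
                                cluster_event_log, commitment_probability,
                                decompose_trajectory, find_clusters,
                                halftime, mass_fraction_series,
                                residual_monomer)
from pscfibril.engine import Frame, SimConfig, concentration, run
from pscfibril.io import make_ideal_oligomer
from pscfibril.model import ModelParams
from pscfibril.oosawa import analytic_halftime, oosawa_curve


def monomer_grid_frame(n, box, spacing=11.1):
    """n isolated monomers on a cubic grid (no pair within reach)."""
    per_side = int(math.ceil(n ** (1 / 3)))
    pos = []
    for i in range(n):
        a, b, c = (i % per_side, (i // per_side) % per_side,
                   i // per_side ** 2)
        pos.append([0.5 + a * spacing, 0.5 + b * spacing,
                    0.5 + c * spacing])
    pos = np.array(pos)
    assert pos.max() < box
    ez = np.tile([0.0, 0.0, 1.0], (n, 1))
    ex = np.tile([1.0, 0.0, 0.0], (n, 1))
    return Frame(0, pos, ez, ex, np.zeros(n, dtype=np.int64))


def place(frame_src, offset):
    f = frame_src
    return (f.positions + np.asarray(offset), f.axes, f.patches, f.states)


class TestFindClusters:
    def test_all_monomers(self, achiral_params):
        frame = monomer_grid_frame(27, box=40.0)
        dec = find_clusters(frame, achiral_params, box=40.0)
        assert len(dec.clusters) == 27
        assert np.all(dec.sizes == 1)

    def test_ideal_tetramer_is_one_cluster(self, achiral_params):
        tet = make_ideal_oligomer(4, 4, achiral_params)
        frame = Frame(0, tet.positions + 20.0, tet.axes, tet.patches,
                      tet.states)
        dec = find_clusters(frame, achiral_params, box=40.0)
        assert len(dec.clusters) == 1
        assert dec.clusters[0].size == 4
        assert dec.clusters[0].n_beta == 4

    def test_chain_transitivity(self, achiral_params):
        """a-b-c with only consecutive contacts is one cluster of three."""
        s = achiral_params.diameter_sigma
        pos = np.array([[10.0, 10, 10], [10 + s, 10, 10], [10 + 2 * s, 10, 10]])
        ez = np.tile([0.0, 0.0, 1.0], (3, 1))
        patches = np.tile([0.0, 1.0, 0.0], (3, 1))  # covers both neighbours
        frame = Frame(0, pos, ez, patches, np.zeros(3, dtype=np.int64))
        dec = find_clusters(frame, achiral_params, box=40.0)
        assert [c.size for c in dec.clusters] == [3]
        assert dec.clusters[0].n_edges == 2
        assert not dec.clusters[0].is_cyclic

    def test_ring_is_flagged_cyclic(self, achiral_params):
        """A closed loop of bonded coils registers as a cyclic cluster."""
        m = 10
        s = achiral_params.diameter_sigma
        r = 1.001 * s / (2 * math.sin(math.pi / m))  # just off the hard core
        theta = 2 * math.pi * np.arange(m) / m
        pos = np.column_stack([20 + r * np.cos(theta),
                               20 + r * np.sin(theta),
                               np.full(m, 20.0)])
        ez = np.tile([0.0, 0.0, 1.0], (m, 1))
        patches = np.column_stack([-np.cos(theta), -np.sin(theta),
                                   np.zeros(m)])  # radially inward
        frame = Frame(0, pos, ez, patches, np.zeros(m, dtype=np.int64))
        dec = find_clusters(frame, achiral_params, box=40.0)
        assert [c.size for c in dec.clusters] == [m]
        assert dec.clusters[0].n_edges == m
        assert dec.clusters[0].is_cyclic

    def test_invariance_under_translation_and_relabel(self, achiral_params):
        tet = make_ideal_oligomer(4, 2, achiral_params)
        n = 12
        pos = np.vstack([tet.positions + 10.0,
                         monomer_grid_frame(8, 40.0).positions + 1.0])
        ax = np.vstack([tet.axes, np.tile([0.0, 0, 1], (8, 1))])
        pt = np.vstack([tet.patches, np.tile([1.0, 0, 0], (8, 1))])
        st = np.concatenate([tet.states, np.zeros(8, dtype=np.int64)])
        base = find_clusters(Frame(0, pos, ax, pt, st), achiral_params, 40.0)
        # whole-box translation across the periodic boundary
        shifted = find_clusters(Frame(0, (pos + 33.0) % 40.0, ax, pt, st),
                                achiral_params, 40.0)
        perm = np.random.default_rng(0).permutation(n)
        relabeled = find_clusters(Frame(0, pos[perm], ax[perm], pt[perm],
                                        st[perm]), achiral_params, 40.0)
        for other in (shifted, relabeled):
            assert sorted(c.size for c in base.clusters) == \
                sorted(c.size for c in other.clusters)


class TestMassFraction:
    def test_counting_two_tetramers(self, achiral_params):
        """2 tetramers + 592 monomers of 600: fibril fraction 8/600."""
        box = 110.0
        singles = monomer_grid_frame(592, box)
        tet = make_ideal_oligomer(4, 4, achiral_params)
        pos = np.vstack([tet.positions + [3.0, 3.0, 104.0],
                         tet.positions + [30.0, 3.0, 104.0],
                         singles.positions])
        ax = np.vstack([tet.axes, tet.axes, singles.axes])
        pt = np.vstack([tet.patches, tet.patches, singles.patches])
        st = np.concatenate([tet.states, tet.states, singles.states])
        frame = Frame(0, pos, ax, pt, st)
        cfg = SimConfig(n_particles=600, box_edge=box, n_sweeps=0)
        from pscfibril.engine import Trajectory
        traj = Trajectory([frame], cfg, achiral_params)
        curve = mass_fraction_series(traj)
        assert curve.fibril_mass_fraction[0] == pytest.approx(8 / 600)
        assert curve.monomer_mM[0] == pytest.approx(592 / 600 * curve.m0)
        assert curve.oligomer_mM[0] == 0.0

    def test_mass_conservation_on_simulation(self, default_params):
        cfg = SimConfig(n_particles=60, box_edge=30.0, n_sweeps=400,
                        record_every=100, seed=2)
        curve = mass_fraction_series(run(cfg, default_params))
        total = curve.monomer_mM + curve.oligomer_mM + curve.fibril_mM
        assert np.allclose(total, curve.m0, rtol=1e-12)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            MassFractionCurve(np.arange(3.0), np.array([0.0, 0.5, 1.2]),
                              np.zeros(3), np.zeros(3), np.zeros(3), 1.0)


class TestAverageCurves:
    @staticmethod
    def curve(f, m0=1.0, t=None):
        f = np.asarray(f, dtype=float)
        t = np.arange(len(f), dtype=float) if t is None else t
        return MassFractionCurve(t, f, (1 - f) * m0, np.zeros_like(f),
                                 f * m0, m0)

    def test_identical_curves(self):
        c = self.curve([0.0, 0.4, 0.8])
        avg = average_curves([c, c, c])
        assert np.allclose(avg.fibril_mass_fraction, c.fibril_mass_fraction)
        assert np.allclose(avg.sd, 0.0)
        assert avg.n_runs_averaged == 3

    def test_mirror_noise_cancels(self):
        base = np.array([0.0, 0.5, 0.9])
        noise = np.array([0.0, 0.1, -0.05])
        avg = average_curves([self.curve(base + noise),
                              self.curve(base - noise)])
        assert np.allclose(avg.fibril_mass_fraction, base)

    def test_sd_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        curves = [self.curve(np.clip(rng.random(5), 0, 1))
                  for _ in range(5)]
        avg = average_curves(curves)
        stack = np.array([c.fibril_mass_fraction for c in curves])
        assert np.allclose(avg.sd, stack.std(axis=0, ddof=0))

    def test_resampling_distinct_grids(self):
        c1 = self.curve([0.0, 0.5, 1.0], t=np.array([0.0, 1.0, 2.0]))
        c2 = self.curve([0.0, 0.25, 0.75, 1.0],
                        t=np.array([0.0, 0.5, 1.5, 2.0]))
        avg = average_curves([c1, c2])
        assert np.array_equal(avg.times_ns, c1.times_ns)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_curves([])


class TestHalftime:
    def test_closed_form_matches_analytic(self):
        n, k, m0 = 3.8, 0.02, 0.51
        th = analytic_halftime(n, k, m0)
        t = np.linspace(0, 8 * th, 4000)
        f = oosawa_curve(t, n, k, m0)
        curve = TestAverageCurves.curve(f, m0=m0, t=t)
        assert halftime(curve) == pytest.approx(th, rel=1e-3)

    def test_step_function(self):
        f = np.array([0.0] * 5 + [1.0] * 5)
        t = np.arange(10.0)
        curve = TestAverageCurves.curve(f, t=t)
        # crossing interpolated onto the jump interval [4, 5]
        assert 4.0 < halftime(curve) <= 5.0

    def test_time_scaling_covariance(self):
        f = oosawa_curve(np.linspace(0, 100, 500), 3.0, 0.05, 1.0)
        t = np.linspace(0, 100, 500)
        c1 = TestAverageCurves.curve(f, t=t)
        c2 = TestAverageCurves.curve(f, t=2 * t)
        assert halftime(c2) == pytest.approx(2 * halftime(c1), rel=1e-12)

    def test_never_reaching_half_plateau(self):
        f = np.concatenate([np.linspace(0, 0.5, 50), [0.01] * 5])
        with pytest.raises(ValueError, match="plateau"):
            halftime(TestAverageCurves.curve(np.zeros(20)))


def toy_decompositions():
    """Four trimers; two grow to fibril size, two dissolve."""
    def dec(clusters, sweep, n=20):
        labels = np.zeros(n, dtype=int)
        cl = []
        used = set()
        for j, mem in enumerate(clusters):
            cl.append(Cluster(np.array(mem), 0, max(0, len(mem) - 1)))
            used.update(mem)
        singles = [i for i in range(n) if i not in used]
        for j, i in enumerate(singles):
            cl.append(Cluster(np.array([i]), 0, 0))
        return ClusterDecomposition(labels, cl, sweep)

    frames = [
        dec([[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11]], 0),
        dec([[0, 1, 2, 12], [3, 4, 5], [6, 7], [9, 10]], 1),
        dec([[0, 1, 2, 12, 13], [3, 4, 5, 14], [9]], 2),
    ]
    return frames


class TestCommitment:
    def test_toy_half_commit(self):
        res = commitment_probability(toy_decompositions(), size=3)
        assert res.probability == pytest.approx(0.5)
        assert res.n_events == 4
        assert res.n_committed == 2

    def test_no_clusters_reported_undefined(self):
        res = commitment_probability(toy_decompositions(), size=6)
        assert res.probability is None
        assert res.n_events == 0


class TestResidualMonomer:
    def test_fully_depleted(self):
        f = np.concatenate([np.linspace(0, 1, 50), np.ones(50)])
        res = residual_monomer(TestAverageCurves.curve(f, m0=2.0))
        assert res.concentration_mM == pytest.approx(0.0, abs=1e-12)
        assert res.plateau_reached

    def test_no_aggregation_returns_m0(self):
        f = np.zeros(100)
        res = residual_monomer(TestAverageCurves.curve(f, m0=2.0))
        assert res.concentration_mM == pytest.approx(2.0)

    def test_still_growing_flagged(self):
        f = np.linspace(0, 0.6, 100)
        res = residual_monomer(TestAverageCurves.curve(f, m0=2.0))
        assert not res.plateau_reached


class TestEventLog:
    def test_birth_death_ledger(self):
        df = cluster_event_log(toy_decompositions())
        assert set(df.columns) == {"cluster_id", "birth_sweep",
                                   "death_sweep", "max_size", "fate"}
        fates = df["fate"].tolist()
        assert fates.count("fibril") + fates.count("open") + \
            fates.count("dissolved") == len(df)
        assert (df["max_size"] >= 2).all()
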