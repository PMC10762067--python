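"""Observables: Rg with unwrapping, binding classification, bridge span,
cluster detection (vs a networkx oracle), and trajectory aggregation."""

import math

import networkx as nx
import numpy as np
import pytest

from nucleohns.analysis import (
    BrokenRingError,
    aggregate,
    binding_fractions,
    bridge_span,
    classify_binding,
    detect_clusters,
    radius_of_gyration,
    unwrap_ring,
    BindingRecord,
)
from nucleohns.builder import MONOMER, ParticleConfiguration
from nucleohns.dynamics import Frame, Trajectory
from nucleohns.fixtures import make_fixture


def ring_config(points, box=100.0):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return ParticleConfiguration(
        positions=points,
        species=np.full(n, MONOMER, dtype=np.int64),
        molecule_id=np.zeros(n, dtype=np.int64),
        box=box,
        fene_bonds=np.stack([np.arange(n), (np.arange(n) + 1) % n], axis=1).astype(
            np.int64
        ),
    )


class TestRadiusOfGyration:
    def test_two_points(self):
        cfg = ring_config([[0, 0, 0], [3.0, 0, 0]])
        assert radius_of_gyration(cfg) == pytest.approx(1.5)

    def test_cube_corners(self):
        corners = [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 1, 1], [1, 1, 1], [1, 0, 1], [0, 0, 1],
        ]
        cfg = ring_config(corners)
        assert radius_of_gyration(cfg) == pytest.approx(math.sqrt(3) / 2, rel=1e-12)

    def test_lattice_translation_invariance(self):
        fx = make_fixture("known_rg", seed=1)
        cfg = fx.config
        rg0 = radius_of_gyration(cfg)
        shifted = cfg.copy()
        shifted.positions = (cfg.positions + cfg.box * np.array([2.0, -1.0, 1.0]))
        assert radius_of_gyration(shifted) == pytest.approx(rg0, rel=1e-12)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        pts = np.random.default_rng(3).normal(size=(12, 3))
        cfg = ring_config(pts, box=1e6)  # effectively non-periodic
        rg0 = radius_of_gyration(cfg)
        rot = Rotation.random(random_state=5).as_matrix()
        cfg2 = ring_config(pts @ rot.T, box=1e6)
        assert radius_of_gyration(cfg2) == pytest.approx(rg0, rel=1e-9)

    def test_unwrap_start_independence(self):
        fx = make_fixture("known_rg", seed=2)
        cfg = fx.config
        u0 = unwrap_ring(cfg, start=0)
        for start in (1, 17, 63):
            us = unwrap_ring(cfg, start=start)
            rel0 = u0 - u0.mean(axis=0)
            rels = us - us.mean(axis=0)
            assert np.max(np.abs(np.sort(np.linalg.norm(rel0, axis=1))
                                 - np.sort(np.linalg.norm(rels, axis=1)))) < 1e-9

    def test_wrapped_circle_recovers_radius(self):
        fx = make_fixture("known_rg", seed=4)
        assert radius_of_gyration(fx.config) == pytest.approx(10.0, rel=1e-9)

    def test_broken_ring_raises(self):
        pts = np.zeros((4, 3))
        pts[:, 0] = [0.0, 1.0, 2.0, 26.0]  # bond of ~24 > box/2
        cfg = ring_config(pts, box=40.0)
        with pytest.raises(BrokenRingError):
            radius_of_gyration(cfg)


class TestBinding:
    def test_mixed_binding_fixture(self):
        fx = make_fixture("mixed_binding", seed=0)
        records = classify_binding(fx.config)
        theta, fd, fb = binding_fractions(records)
        assert theta == fx.truth["theta"] == 0.5
        assert fd == fx.truth["frac_dangling"] == 0.3
        assert fb == fx.truth["frac_bridging"] == 0.2
        assert theta == fd + fb  # exact count arithmetic

    def test_all_far_is_unbound(self):
        fx = make_fixture("mixed_binding", seed=0, n_dangling=0, n_bridging=0,
                          n_free=4)
        records = classify_binding(fx.config)
        assert all(r.mode == "unbound" for r in records)
        assert binding_fractions(records)[0] == 0.0

    def test_no_hns_is_an_error(self):
        fx = make_fixture("known_rg", seed=0)
        with pytest.raises(ValueError):
            classify_binding(fx.config)

    @pytest.mark.parametrize(
        "a,b,n,span,label",
        [
            ([5], [9], 200, 4, "trans"),
            ([1], [199], 200, 2, "cis"),
            ([7], [7], 200, 0, "cis"),
        ],
    )
    def test_bridge_span_ring_arithmetic(self, a, b, n, span, label):
        rec = BindingRecord(
            contacts_patch_a=np.array(a), contacts_patch_b=np.array(b),
            mode="bridging",
        )
        assert bridge_span(rec, n) == (span, label)

    def test_bridge_span_requires_bridging(self):
        rec = BindingRecord(
            contacts_patch_a=np.array([1]), contacts_patch_b=np.array([]),
            mode="dangling",
        )
        with pytest.raises(ValueError):
            bridge_span(rec, 100)


def cores_config(positions, box=60.0):
    """Bare H-NS cores with patches folded onto the core (cluster tests
    only need core coordinates)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    pos = np.repeat(positions, 3, axis=0)
    pos[1::3] += [0.0, 0.0, 0.4]
    pos[2::3] -= [0.0, 0.0, 0.4]
    species = np.tile([3, 2, 2], n).astype(np.int64)
    harm = []
    angles = []
    for k in range(n):
        harm += [[3 * k, 3 * k + 1], [3 * k, 3 * k + 2]]
        angles.append([3 * k + 1, 3 * k, 3 * k + 2])
    return ParticleConfiguration(
        positions=pos,
        species=species,
        molecule_id=np.repeat(np.arange(n), 3).astype(np.int64),
        box=box,
        harm_bonds=np.array(harm, dtype=np.int64),
        harm_k=np.full(2 * n, 120.0),
        harm_r0=np.full(2 * n, 0.4),
        harm_kind=np.zeros(2 * n, dtype=np.int64),
        angles=np.array(angles, dtype=np.int64),
    )


class TestClusters:
    def test_chain_of_three(self):
        cfg = cores_config([[10, 10, 10], [12.9, 10, 10], [15.8, 10, 10]])
        rep = detect_clusters(cfg)
        assert rep.histogram == {3: 1}
        assert rep.mean_size == 3.0

    def test_three_singletons(self):
        cfg = cores_config([[10, 10, 10], [13.1, 10, 10], [16.2, 10, 10]])
        rep = detect_clusters(cfg)
        assert rep.histogram == {1: 3}

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        cfg = cores_config(rng.uniform(0, 30, size=(40, 3)), box=30.0)
        rep = detect_clusters(cfg)
        assert rep.sizes.sum() == 40
        assert len(rep.labels) == 40

    def test_matches_networkx_oracle(self):
        """Partition equals brute-force adjacency + graph components
        (minimum image), on dense random core sets."""
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 25, size=(50, 3))
            cfg = cores_config(pts, box=25.0)
            rep = detect_clusters(cfg)
            g = nx.Graph()
            g.add_nodes_from(range(50))
            for i in range(50):
                for j in range(i + 1, 50):
                    d = pts[i] - pts[j]
                    d -= 25.0 * np.rint(d / 25.0)
                    if (d**2).sum() <= 9.0:
                        g.add_edge(i, j)
            oracle = {frozenset(c) for c in nx.connected_components(g)}
            ours = {
                frozenset(np.flatnonzero(rep.labels == lab))
                for lab in np.unique(rep.labels)
            }
            assert ours == oracle

    def test_clustered_fixture(self):
        fx = make_fixture("clustered", seed=0, sizes=[24, 3, 2, 1])
        rep = detect_clusters(fx.config)
        assert rep.histogram == {1: 1, 2: 1, 3: 1, 24: 1}
        assert rep.mean_size == 7.5


class TestAggregate:
    def _traj_from(self, cfgs, times=None):
        topo = cfgs[0]
        frames = [
            Frame(
                time=(times[i] if times else float(i)),
                positions=c.positions % topo.box,
                images=np.floor(c.positions / topo.box).astype(np.int64),
            )
            for i, c in enumerate(cfgs)
        ]
        return Trajectory(topology=topo.copy(), frames=frames)

    def test_single_frame_summary_equals_frame(self):
        fx = make_fixture("mixed_binding", seed=1)
        traj = self._traj_from([fx.config])
        df, summary = aggregate(traj)
        assert summary["n_frames"] == 1
        assert summary["theta_mean"] == fx.truth["theta"]
        assert summary["rg_mean"] == pytest.approx(df["rg"].iloc[0])

    def test_identical_frames_zero_error(self):
        fx = make_fixture("mixed_binding", seed=1)
        traj = self._traj_from([fx.config] * 6)
        _, summary = aggregate(traj)
        assert summary["rg_se"] == 0.0
        assert summary["theta_se"] == 0.0

    def test_pooled_cluster_histogram(self):
        """Frames with cluster multisets {3,1} and {2,2} pool to histogram
        {1:1, 2:2, 3:1} and mean size 2.0."""
        base = [[10.0, 10, 10], [12.5, 10, 10], [15.0, 10, 10], [30.0, 10, 10]]
        frame2 = [[10.0, 10, 10], [12.5, 10, 10], [30.0, 10, 10], [32.5, 10, 10]]
        ring = make_fixture("known_rg", seed=0, radius=3.0, n=12, box=60.0).config
        cfgs = []
        for cores in (base, frame2):
            cores_cfg = cores_config(cores, box=60.0)
            merged = ParticleConfiguration(
                positions=np.vstack([ring.positions, cores_cfg.positions]),
                species=np.concatenate([ring.species, cores_cfg.species]),
                molecule_id=np.concatenate(
                    [ring.molecule_id, cores_cfg.molecule_id + 1]
                ),
                box=60.0,
                fene_bonds=ring.fene_bonds,
                harm_bonds=cores_cfg.harm_bonds + ring.n_particles,
                harm_k=cores_cfg.harm_k,
                harm_r0=cores_cfg.harm_r0,
                harm_kind=cores_cfg.harm_kind,
                angles=cores_cfg.angles + ring.n_particles,
            )
            cfgs.append(merged)
        df, summary = aggregate(self._traj_from(cfgs))
        assert summary["cluster_histogram"] == {1: 1, 2: 2, 3: 1}
        assert summary["mean_cluster_size"] == 2.0

    def test_empty_trajectory_rejected(self):
        fx = make_fixture("known_rg", seed=0)
        with pytest.raises(ValueError):
            aggregate(Trajectory(topology=fx.config, frames=[]))


class TestSimulationScaling:
    def test_ideal_ring_rg_scales_linearly(self, phantom_ring_rgs):
        """Gaussian ring law: <Rg^2> proportional to N (within 10%)."""
        r = phantom_ring_rgs
        assert r[100] / r[50] == pytest.approx(2.0, rel=0.10)
        assert r[200] / r[100] == pytest.approx(2.0, rel=0.10)

    def test_crowding_monotonicity(self, synergy_sweep):
        """Compaction deepens and bridging/clustering grow with phi_c
        (desk-scale reflection of the crowding-synergy trend)."""
        df = synergy_sweep.sort_values("phi_c")
        rg = df["rg"].to_numpy()
        se = df["rg_se"].to_numpy()
        for i in range(len(rg) - 1):
            assert rg[i + 1] <= rg[i] + (se[i] + se[i + 1])
        assert rg[-1] < rg[0]
        fb = df["frac_bridging"].to_numpy()
        cs = df["mean_cluster_size"].to_numpy()
        assert fb[-1] > fb[0]
        assert cs[-1] >= cs[0]
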