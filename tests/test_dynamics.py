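"""Engine correctness: forces vs finite differences, NVE conservation,
equipartition, minimum-image invariance, cell-list vs all-pairs oracle,
and seed determinism."""

import numpy as np
import pytest

from nucleohns.builder import ParticleConfiguration, SystemSpec, assemble_system
from nucleohns.dynamics import (
    FeneOverstretchError,
    IntegratorSettings,
    RunSchedule,
    compute_forces,
    compute_forces_allpairs,
    initialize_state,
    run,
    step,
    _advance,
)
from nucleohns.interactions import BondedParams, InteractionTable


def small_mixed_config(seed=0, n_mono=20, n_hns=5, phi=0.05, box=12.0):
    spec = SystemSpec(
        n_monomers=n_mono, box_side=box, phi_c=phi, n_hns=n_hns, seed=seed
    )
    return assemble_system(spec), spec.interaction_table()


def relaxed(config, table, seed=0, steps=3000):
    """Short thermostatted warmup so configurations are thermal-like."""
    st = initialize_state(config, seed=seed)
    _advance(st, IntegratorSettings(seed=seed), table, BondedParams(), steps,
             dmax=0.05, seed=seed)
    return st


class TestForces:
    def test_wca_minimum_zero_force(self, table):
        cfg = ParticleConfiguration(
            positions=np.array([[5.0, 5.0, 5.0], [5.0 + 2 ** (1 / 6), 5.0, 5.0]]),
            species=np.array([1, 1], dtype=np.int64),
            molecule_id=np.zeros(2, dtype=np.int64),
            box=20.0,
            fene_bonds=np.zeros((0, 2), dtype=np.int64),
        )
        f, pe = compute_forces(cfg, table)
        assert np.abs(f).max() < 1e-10
        assert pe == pytest.approx(0.0, abs=1e-12)

    def test_rest_triplex_zero_force(self, table):
        from nucleohns.builder import build_hns_triplex

        pos, species, harm, angle = build_hns_triplex(np.full(3, 10.0), [0, 0, 1.0])
        bp = BondedParams()
        cfg = ParticleConfiguration(
            positions=pos,
            species=species,
            molecule_id=np.zeros(3, dtype=np.int64),
            box=20.0,
            harm_bonds=harm,
            harm_k=np.full(2, bp.hns_K),
            harm_r0=np.full(2, bp.hns_r0),
            harm_kind=np.zeros(2, dtype=np.int64),
            angles=angle,
        )
        f, pe = compute_forces(cfg, table)
        assert np.abs(f).max() < 1e-9
        assert pe == pytest.approx(0.0, abs=1e-12)

    def test_forces_match_finite_differences(self, table):
        """Central differences of the total energy on a thermal 20-monomer
        mixed system (ring + triplexes + crowders)."""
        cfg, tab = small_mixed_config(seed=1)
        st = relaxed(cfg, tab, seed=1)
        cfg = st.configuration
        f, pe = compute_forces(cfg, tab)
        rng = np.random.default_rng(0)
        picks = rng.choice(cfg.n_particles, size=12, replace=False)
        h = 1e-6
        for i in picks:
            for d in range(3):
                for sgn, store in ((+1, "up"), (-1, "dn")):
                    cfg.positions[i, d] += sgn * h
                    if sgn == 1:
                        _, e_up = compute_forces(cfg, tab)
                        cfg.positions[i, d] -= h
                    else:
                        _, e_dn = compute_forces(cfg, tab)
                        cfg.positions[i, d] += h
                fd = -(e_up - e_dn) / (2 * h)
                denom = max(1.0, abs(f[i, d]))
                assert abs(f[i, d] - fd) / denom < 1e-5

    def test_minimum_image_lattice_invariance(self, table):
        cfg, tab = small_mixed_config(seed=2)
        f0, e0 = compute_forces(cfg, tab)
        shifted = cfg.copy()
        shifted.positions = cfg.positions + cfg.box * np.array([3.0, -2.0, 5.0])
        f1, e1 = compute_forces(shifted, tab)
        assert e1 == pytest.approx(e0, rel=1e-12)
        assert np.allclose(f0, f1, atol=1e-9)

    def test_cell_list_matches_all_pairs(self):
        """Neighbor-list forces equal the O(N^2) oracle on thermalized
        ~100-particle systems."""
        for seed in (3, 4):
            cfg, tab = small_mixed_config(seed=seed, n_mono=30, n_hns=6, phi=0.08)
            st = relaxed(cfg, tab, seed=seed)
            f_cell, e_cell = compute_forces(st.configuration, tab)
            f_ref, e_ref = compute_forces_allpairs(st.configuration, tab)
            assert e_cell == pytest.approx(e_ref, rel=1e-10, abs=1e-10)
            assert np.max(np.abs(f_cell - f_ref)) < 1e-10 * max(
                1.0, np.max(np.abs(f_ref))
            )

    def test_fene_domain_violation_reported(self, table):
        cfg = ParticleConfiguration(
            positions=np.array([[1.0, 1.0, 1.0], [2.6, 1.0, 1.0]]),
            species=np.array([1, 1], dtype=np.int64),
            molecule_id=np.zeros(2, dtype=np.int64),
            box=20.0,
            fene_bonds=np.array([[0, 1]], dtype=np.int64),
        )
        with pytest.raises(FeneOverstretchError):
            compute_forces(cfg, table)


class TestIntegrator:
    def test_free_particle_drift(self, table):
        """Zero forces, no thermostat: uniform motion x += v dt."""
        cfg = ParticleConfiguration(
            positions=np.array([[5.0, 5.0, 5.0]]),
            species=np.array([4], dtype=np.int64),
            molecule_id=np.zeros(1, dtype=np.int64),
            box=20.0,
        )
        st = initialize_state(cfg, seed=0)
        st.velocities = np.array([[0.3, -0.2, 0.1]])
        v0 = st.velocities.copy()
        settings = IntegratorSettings(dt=0.005, thermostat_on=False)
        _advance(st, settings, table, BondedParams(), 1000, seed=0)
        assert np.allclose(
            st.configuration.positions[0], [5.0, 5.0, 5.0] + v0[0] * 5.0, atol=1e-10
        )

    def test_harmonic_dimer_energy_drift(self, table):
        """Symplectic VV on a stiff harmonic dimer: the block-averaged
        total energy drifts by < 1e-6 epsilon over 1e4 steps."""
        bp = BondedParams()
        cfg = ParticleConfiguration(
            positions=np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.45]]),
            species=np.array([3, 2], dtype=np.int64),   # core-patch pair: no LJ
            molecule_id=np.zeros(2, dtype=np.int64),
            box=20.0,
            harm_bonds=np.array([[0, 1]], dtype=np.int64),
            harm_k=np.array([bp.hns_K]),
            harm_r0=np.array([bp.hns_r0]),
            harm_kind=np.zeros(1, dtype=np.int64),
        )
        st = SimulationStateFactory(cfg)
        settings = IntegratorSettings(dt=0.001, thermostat_on=False)
        pos_s, vel_s, pe, ke, _ = _advance(
            st, settings, table, bp, 10_000, sample_every=1, seed=0
        )
        e = pe + ke
        first, last = e[:1000].mean(), e[-1000:].mean()
        assert abs(last - first) < 1e-6

    def test_nve_drift_mixed_system(self):
        """|dE|/|E| < 1e-4 over 1e4 NVE steps at dt = 0.001 on a thermal
        ~50-particle mixed system."""
        cfg, tab = small_mixed_config(seed=5, n_mono=20, n_hns=4, phi=0.03)
        st = relaxed(cfg, tab, seed=5)
        settings = IntegratorSettings(dt=0.001, thermostat_on=False)
        pos_s, vel_s, pe, ke, _ = _advance(
            st, settings, tab, BondedParams(), 10_000, sample_every=100, seed=0
        )
        e = pe + ke
        assert abs(e[-1] - e[0]) / abs(e[0]) < 1e-4

    def test_equipartition(self, table):
        """<v_a^2> = kT/m per Cartesian component within 2%."""
        cfg, tab = small_mixed_config(seed=6, n_mono=30, n_hns=5, phi=0.05)
        st = relaxed(cfg, tab, seed=6)
        settings = IntegratorSettings(thermostat_on=True, seed=6)
        pos_s, vel_s, pe, ke, mean_t = _advance(
            st, settings, tab, BondedParams(), 40_000, sample_every=20, seed=7
        )
        # 2000 samples x ~100 particles per component
        per_component = (vel_s**2).mean(axis=(0, 1))
        assert np.all(np.abs(per_component - 1.0) < 0.02)
        assert mean_t == pytest.approx(1.0, abs=0.02)

    def test_schedule_frame_arithmetic(self):
        spec = SystemSpec(n_monomers=20, box_side=15.0, phi_c=0.0, n_hns=0, seed=1)
        traj, log = run(
            spec,
            schedule=RunSchedule(equilibration_steps=0, production_steps=100,
                                 sample_interval=10),
            warmup_steps=100,
        )
        assert traj.n_frames == 10
        times = [f.time for f in traj.frames]
        assert np.allclose(np.diff(times), 10 * 0.005)

    def test_seed_determinism(self):
        spec = SystemSpec(n_monomers=20, box_side=15.0, phi_c=0.05, n_hns=3, seed=11)
        sch = RunSchedule(equilibration_steps=1000, production_steps=2000,
                          sample_interval=500)
        t1, _ = run(spec, schedule=sch)
        t2, _ = run(spec, schedule=sch)
        for a, b in zip(t1.frames, t2.frames):
            assert np.array_equal(a.positions, b.positions)

    def test_step_advances_time(self, table):
        cfg, tab = small_mixed_config(seed=12, n_mono=10, n_hns=2, phi=0.0)
        st = relaxed(cfg, tab, seed=12)
        t0 = st.time
        step(st, IntegratorSettings(seed=1), tab)
        assert st.time == pytest.approx(t0 + 0.005)


def SimulationStateFactory(cfg):
    from nucleohns.dynamics import SimulationState

    return SimulationState(
        configuration=cfg.copy(),
        velocities=np.zeros((cfg.n_particles, 3)),
    )
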