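"""Langevin dynamics engine: velocity-Verlet + Langevin thermostat with
cell-list neighbor search under periodic boundary conditions.

The system is kept at T = 1 epsilon/k_B by an impulse-style Langevin
thermostat (friction -m v / damping_time plus Gaussian noise entering the
force term of velocity-Verlet).  With the thermostat off the integrator is
plain symplectic NVE velocity-Verlet, which is what the energy-conservation
checks exercise.

Positions are integrated unwrapped; emitted frames carry wrapped positions
plus per-particle image counters so trajectories can be unwrapped exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .builder import ParticleConfiguration, SystemSpec, assemble_system
from .interactions import BondedParams, InteractionTable

__all__ = [
    "IntegratorSettings",
    "RunSchedule",
    "SimulationState",
    "Frame",
    "Trajectory",
    "FeneOverstretchError",
    "SimulationBlowupError",
    "compute_forces",
    "initialize_state",
    "step",
    "run",
]

NEIGHBOR_SKIN = 0.4  # sigma; Verlet-list margin, rebuilt at half-skin travel


@dataclass(frozen=True)
class IntegratorSettings:
    dt: float = 0.005           # tau
    temperature: float = 1.0    # epsilon / k_B
    damping_time: float = 1.0   # tau
    thermostat_on: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.damping_time <= 0:
            raise ValueError("dt and damping_time must be positive")


@dataclass(frozen=True)
class RunSchedule:
    equilibration_steps: int = 200_000
    production_steps: int = 1_000_000
    sample_interval: int = 5_000

    def __post_init__(self) -> None:
        if min(self.equilibration_steps, self.production_steps, self.sample_interval) < 0:
            raise ValueError("schedule counts must be non-negative")
        if self.production_steps and self.sample_interval:
            if self.production_steps % self.sample_interval:
                raise ValueError("sample_interval must divide production_steps")

    @property
    def n_frames(self) -> int:
        if self.sample_interval == 0:
            return 0
        return self.production_steps // self.sample_interval


class FeneOverstretchError(RuntimeError):
    """A FENE bond left its domain (r >= r0): integrator instability."""


class SimulationBlowupError(RuntimeError):
    """Non-finite coordinate/energy encountered during integration."""


@dataclass
class Frame:
    time: float                 # tau
    positions: np.ndarray       # wrapped into [0, box)
    images: np.ndarray          # periodic image counters (int)
    potential_energy: float = np.nan
    kinetic_energy: float = np.nan

    def unwrapped(self, box: float) -> np.ndarray:
        return self.positions + self.images * box


@dataclass
class Trajectory:
    """Ordered production frames plus the static topology they refer to."""

    topology: ParticleConfiguration
    frames: list = field(default_factory=list)

    @property
    def box(self) -> float:
        return self.topology.box

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def frame_config(self, i: int) -> ParticleConfiguration:
        """Topology with positions replaced by frame i's wrapped positions."""
        c = self.topology.copy()
        c.positions = self.frames[i].positions.copy()
        return c


@dataclass
class SimulationState:
    configuration: ParticleConfiguration   # positions held unwrapped
    velocities: np.ndarray
    time: float = 0.0
    step_count: int = 0
    seed: int = 0

    def wrapped_positions(self) -> np.ndarray:
        box = self.configuration.box
        return self.configuration.positions - box * np.floor(
            self.configuration.positions / box
        )

    def images(self) -> np.ndarray:
        box = self.configuration.box
        return np.floor(self.configuration.positions / box).astype(np.int64)


def _present_max_cutoff(config: ParticleConfiguration, table: InteractionTable) -> float:
    """Largest active cutoff among species pairs actually present."""
    present = np.unique(config.species)
    rc = 0.0
    for i in present:
        for j in present:
            pp = table.params(int(i), int(j))
            if pp.active:
                rc = max(rc, pp.r_cut)
    return rc


def _kernel_args(config: ParticleConfiguration, table: InteractionTable, bp: BondedParams):
    eps, sig2, rc2, shift, act = table.as_arrays()
    # drop rows/cols of absent species so the list radius (and the skin
    # derived from rc2.max() inside the kernel) stays tight
    absent = np.setdiff1d(np.arange(1, 5), np.unique(config.species)) - 1
    for a in absent:
        act[a, :] = act[:, a] = False
        rc2[a, :] = rc2[:, a] = 0.0
    return dict(
        species=(config.species - 1).astype(np.int64),
        mass=np.ones(config.n_particles),
        L=float(config.box),
        eps=eps, sig2=sig2, rc2=rc2, shift=shift, act=act,
        fene_bonds=np.ascontiguousarray(config.fene_bonds),
        fene_k0=bp.fene_k0, fene_r0=bp.fene_r0,
        harm_bonds=np.ascontiguousarray(config.harm_bonds),
        harm_k=np.ascontiguousarray(config.harm_k),
        harm_r0=np.ascontiguousarray(config.harm_r0),
        angles=np.ascontiguousarray(config.angles),
        angle_k=bp.hns_kb,
        rlist=_present_max_cutoff(config, table) + NEIGHBOR_SKIN,
    )


def compute_forces(
    config: ParticleConfiguration,
    table: InteractionTable | None = None,
    bp: BondedParams = BondedParams(),
):
    """Per-particle force vectors and total potential energy.

    All nonbonded pairs use the minimum-image convention; inactive pairs
    are skipped; bonded terms (FENE ring, H-NS radial + angle, anchors)
    are included.
    """
    table = table if table is not None else InteractionTable.paper_n200()
    ka = _kernel_args(config, table, bp)
    n = config.n_particles
    pos = np.ascontiguousarray(config.positions, dtype=float)
    f = np.zeros((n, 3))
    cap = 96
    while True:
        neigh_idx = np.zeros((n, cap), dtype=np.int32)
        neigh_cnt = np.zeros(n, dtype=np.int32)
        if ka["rlist"] > NEIGHBOR_SKIN:
            st = _kernels._build_neighbors(pos, ka["L"], ka["rlist"], neigh_idx, neigh_cnt)
            if st == _kernels.STATUS_NEIGH_OVERFLOW:
                cap *= 2
                continue
        break
    pe, st, bad = _kernels._forces(
        pos, ka["species"], ka["L"],
        ka["eps"], ka["sig2"], ka["rc2"], ka["shift"], ka["act"],
        ka["fene_bonds"], ka["fene_k0"], ka["fene_r0"],
        ka["harm_bonds"], ka["harm_k"], ka["harm_r0"],
        ka["angles"], ka["angle_k"],
        neigh_idx, neigh_cnt, f,
    )
    if st == _kernels.STATUS_FENE:
        i, j = config.fene_bonds[bad]
        raise FeneOverstretchError(
            f"FENE bond {bad} ({i}-{j}) at or beyond r0 = {bp.fene_r0}"
        )
    return f, float(pe)


def compute_forces_allpairs(
    config: ParticleConfiguration,
    table: InteractionTable | None = None,
    bp: BondedParams = BondedParams(),
):
    """Reference O(N^2) force evaluation (no neighbor list); used as the
    oracle the cell-list path must match."""
    table = table if table is not None else InteractionTable.paper_n200()
    ka = _kernel_args(config, table, bp)
    n = config.n_particles
    pos = np.ascontiguousarray(config.positions, dtype=float)
    neigh_idx = np.zeros((n, max(n, 1)), dtype=np.int32)
    neigh_cnt = np.zeros(n, dtype=np.int32)
    for i in range(n):
        neigh_idx[i, : n - i - 1] = np.arange(i + 1, n)
        neigh_cnt[i] = n - i - 1
    f = np.zeros((n, 3))
    pe, st, bad = _kernels._forces(
        pos, ka["species"], ka["L"],
        ka["eps"], ka["sig2"], ka["rc2"], ka["shift"], ka["act"],
        ka["fene_bonds"], ka["fene_k0"], ka["fene_r0"],
        ka["harm_bonds"], ka["harm_k"], ka["harm_r0"],
        ka["angles"], ka["angle_k"],
        neigh_idx, neigh_cnt, f,
    )
    if st == _kernels.STATUS_FENE:
        raise FeneOverstretchError(f"FENE bond {bad} out of domain")
    return f, float(pe)


def initialize_state(
    config: ParticleConfiguration, seed: int = 0, temperature: float = 1.0
) -> SimulationState:
    """Draw Maxwell-Boltzmann velocities (zero total momentum) at T."""
    rng = np.random.default_rng(seed)
    v = rng.normal(scale=np.sqrt(temperature), size=(config.n_particles, 3))
    v -= v.mean(axis=0)
    return SimulationState(
        configuration=config.copy(), velocities=v, seed=seed
    )


def _advance(
    state: SimulationState,
    settings: IntegratorSettings,
    table: InteractionTable,
    bp: BondedParams,
    n_steps: int,
    sample_every: int = 0,
    dmax: float = 0.0,
    seed: int | None = None,
):
    """Drive the jitted integrator for n_steps, mutating ``state``.

    Returns (sampled positions, velocities, pe, ke, mean_T).
    """
    config = state.configuration
    ka = _kernel_args(config, table, bp)
    n = config.n_particles
    nf = n_steps // sample_every if sample_every else 0
    out_pos = np.zeros((max(nf, 1), n, 3))
    out_vel = np.zeros((max(nf, 1), n, 3))
    out_pe = np.zeros(max(nf, 1))
    out_ke = np.zeros(max(nf, 1))
    pos = np.ascontiguousarray(config.positions, dtype=float)
    vel = np.ascontiguousarray(state.velocities, dtype=float)
    st, nsamp, mean_t, bad = _kernels.integrate(
        pos, vel, ka["species"], ka["mass"], ka["L"],
        ka["eps"], ka["sig2"], ka["rc2"], ka["shift"], ka["act"],
        ka["fene_bonds"], ka["fene_k0"], ka["fene_r0"],
        ka["harm_bonds"], ka["harm_k"], ka["harm_r0"],
        ka["angles"], ka["angle_k"],
        settings.dt, 1.0 / settings.damping_time, settings.temperature,
        settings.thermostat_on,
        (seed if seed is not None else settings.seed) & 0x7FFFFFFF,
        n_steps, sample_every, dmax,
        ka["rlist"], out_pos, out_vel, out_pe, out_ke,
    )
    if st == _kernels.STATUS_FENE:
        i, j = config.fene_bonds[bad]
        raise FeneOverstretchError(
            f"FENE bond {bad} ({i}-{j}) overstretched at t={state.time:.2f} tau"
        )
    if st == _kernels.STATUS_NONFINITE:
        fmax = float(np.abs(compute_forces(config, table, bp)[0]).max()) if np.all(
            np.isfinite(pos)
        ) else float("nan")
        raise SimulationBlowupError(
            f"non-finite coordinate/energy at t={state.time:.2f} tau "
            f"(max |F| = {fmax:.3g})"
        )
    config.positions = pos
    state.velocities = vel
    state.time += n_steps * settings.dt
    state.step_count += n_steps
    return out_pos[:nsamp], out_vel[:nsamp], out_pe[:nsamp], out_ke[:nsamp], mean_t


def step(state: SimulationState, settings: IntegratorSettings,
         table: InteractionTable | None = None,
         bp: BondedParams = BondedParams()) -> SimulationState:
    """Advance one time step (thin wrapper over the jitted loop).

    Deterministic: the thermostat noise stream is seeded from
    (settings.seed, state.step_count).
    """
    table = table if table is not None else InteractionTable.paper_n200()
    _advance(
        state, settings, table, bp, n_steps=1,
        seed=(settings.seed * 1_000_003 + state.step_count) & 0x7FFFFFFF,
    )
    return state


def _spec_hash(*objs) -> str:
    blob = json.dumps([asdict(o) for o in objs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(
    spec: SystemSpec,
    settings: IntegratorSettings | None = None,
    schedule: RunSchedule | None = None,
    table: InteractionTable | None = None,
    bp: BondedParams = BondedParams(),
    warmup_steps: int = 2_000,
    config: ParticleConfiguration | None = None,
):
    """Assemble, warm up, equilibrate and sample one system.

    Warmup runs with per-step displacements capped at 0.05 sigma to relax
    the residual soft overlaps left by random insertion; equilibration
    frames are discarded; production emits a frame every
    ``sample_interval`` steps.  Returns (Trajectory, log dict).
    """
    settings = settings or IntegratorSettings(seed=spec.seed)
    schedule = schedule or RunSchedule()
    eff_table = spec.interaction_table(table)

    ss = np.random.SeedSequence([spec.seed, settings.seed])
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(4)]

    if config is None:
        config = assemble_system(spec, table=table, bp=bp)
    state = initialize_state(config, seed=seeds[0], temperature=settings.temperature)

    if warmup_steps:
        _advance(state, settings, eff_table, bp, warmup_steps,
                 dmax=0.05, seed=seeds[1])
    if schedule.equilibration_steps:
        _advance(state, settings, eff_table, bp, schedule.equilibration_steps,
                 seed=seeds[2])

    traj = Trajectory(topology=config.copy())
    mean_t = np.nan
    if schedule.production_steps:
        t0 = state.time
        pos_s, vel_s, pe_s, ke_s, mean_t = _advance(
            state, settings, eff_table, bp, schedule.production_steps,
            sample_every=schedule.sample_interval, seed=seeds[3],
        )
        box = config.box
        for k in range(len(pos_s)):
            img = np.floor(pos_s[k] / box).astype(np.int64)
            traj.frames.append(
                Frame(
                    time=t0 + (k + 1) * schedule.sample_interval * settings.dt,
                    positions=pos_s[k] - img * box,
                    images=img,
                    potential_energy=float(pe_s[k]),
                    kinetic_energy=float(ke_s[k]),
                )
            )
    log = {
        "seed": spec.seed,
        "spec_hash": _spec_hash(spec, settings, schedule),
        "mean_temperature": float(mean_t),
        "n_frames": traj.n_frames,
        "n_particles": config.n_particles,
        "final_time": state.time,
    }
    return traj, log
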