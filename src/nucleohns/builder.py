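"""Assembly of simulation-ready systems.

A system is a chromosome-like ring polymer (species 1), a set of H-NS
triplexes (core, species 3, with two antipodal patches, species 2), and
spherical crowders (species 4) packed to a target volume fraction inside a
periodic cube.  Assembly is deterministic given the spec's seed and
guarantees a mild overlap-free start (no active nonbonded pair closer than
0.85 sigma_ij), which the integrator's capped-displacement warmup then
relaxes fully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .interactions import BondedParams, InteractionTable

__all__ = [
    "SystemSpec",
    "ParticleConfiguration",
    "crowder_count",
    "build_ring_polymer",
    "build_hns_triplex",
    "assemble_system",
    "anchor_hns",
]

MONOMER, PATCH, CORE, CROWDER = 1, 2, 3, 4

#: bond-kind labels for harmonic bonds
KIND_HNS_RADIAL = 0
KIND_ANCHOR = 1

ANCHOR_K = 120.0   # epsilon/sigma^2, stiff tether used for the anchored control
ANCHOR_R0 = 0.6    # sigma, rest length ~ the patch-monomer binding distance


@dataclass(frozen=True)
class SystemSpec:
    """Declarative description of one simulated system."""

    n_monomers: int = 200
    box_side: float = 50.0
    phi_c: float = 0.0
    n_hns: int = 0
    crowder_diameter: float = 2.0
    hns_permeable_to_crowders: bool = False  # control: switch off core-crowder LJ
    n_anchored: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi_c < 0.5):
            raise ValueError("phi_c must lie in [0, 0.5)")
        if self.n_anchored > self.n_hns:
            raise ValueError("cannot anchor more H-NS than present")
        if self.n_monomers < 3:
            raise ValueError("ring needs at least 3 monomers")
        if self.box_side <= 2.0:
            raise ValueError("box too small")

    def interaction_table(self, table: InteractionTable | None = None) -> InteractionTable:
        """Effective pair table for this spec (applies the permeable-H-NS
        control, which deactivates core-crowder only)."""
        t = table if table is not None else InteractionTable.paper_n200()
        if self.hns_permeable_to_crowders:
            t = t.deactivate(CORE, CROWDER)
        return t


@dataclass
class ParticleConfiguration:
    """Positions + species + topology of one system (or one frame)."""

    positions: np.ndarray          # (n, 3), sigma units
    species: np.ndarray            # (n,), values in {1, 2, 3, 4}
    molecule_id: np.ndarray        # (n,)
    box: float
    fene_bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    harm_bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    harm_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    harm_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    harm_kind: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def monomer_indices(self) -> np.ndarray:
        return np.flatnonzero(self.species == MONOMER)

    @property
    def patch_indices(self) -> np.ndarray:
        return np.flatnonzero(self.species == PATCH)

    @property
    def core_indices(self) -> np.ndarray:
        return np.flatnonzero(self.species == CORE)

    @property
    def crowder_indices(self) -> np.ndarray:
        return np.flatnonzero(self.species == CROWDER)

    @property
    def n_hns(self) -> int:
        return len(self.core_indices)

    def hns_triplets(self) -> np.ndarray:
        """(n_hns, 3) array of (core, patch_a, patch_b) indices, derived
        from the angle topology."""
        if len(self.angles) == 0:
            return np.zeros((0, 3), dtype=np.int64)
        return np.stack(
            [self.angles[:, 1], self.angles[:, 0], self.angles[:, 2]], axis=1
        )

    def copy(self) -> "ParticleConfiguration":
        return ParticleConfiguration(
            positions=self.positions.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            box=self.box,
            fene_bonds=self.fene_bonds.copy(),
            harm_bonds=self.harm_bonds.copy(),
            harm_k=self.harm_k.copy(),
            harm_r0=self.harm_r0.copy(),
            harm_kind=self.harm_kind.copy(),
            angles=self.angles.copy(),
        )


def crowder_count(phi_c: float, box_side: float, sigma_c: float) -> int:
    """Number of crowders realizing volume fraction phi_c in a cube,
    rounded half-up (unbiased phi_c realization)."""
    if phi_c == 0:
        return 0
    if phi_c < 0 or box_side <= 0 or sigma_c <= 0:
        raise ValueError("inputs must be positive (or phi_c = 0)")
    v_crowder = math.pi / 6.0 * sigma_c**3
    return int(math.floor(phi_c * box_side**3 / v_crowder + 0.5))


# ---------------------------------------------------------------------------
# ring polymer
# ---------------------------------------------------------------------------

def _resample_closed_curve(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a finely sampled closed curve at n equal-arclength points."""
    d = np.linalg.norm(np.diff(np.vstack([points, points[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    idx = np.searchsorted(s, targets, side="right") - 1
    idx = np.clip(idx, 0, len(points) - 1)
    frac = (targets - s[idx]) / np.maximum(d[idx], 1e-300)
    nxt = (idx + 1) % len(points)
    return points[idx] + frac[:, None] * (points[nxt] - points[idx])


def _torus_coil(N: int, box: float, bond_length: float) -> np.ndarray:
    """Closed, unknotted initial curve for rings too long for a planar circle.

    The ring is laid on a (1, q) winding of a torus: it goes once around a
    main circle of radius R while winding q times around the tube.  Such a
    curve is an unknot, is injective, and can pack an arbitrarily long
    contour in the box for suitable (q, tube radius).  q is chosen as the
    smallest winding number whose resampled polygon keeps all
    non-consecutive beads at least 0.9 sigma apart.
    """
    target_len = N * bond_length
    ell = target_len / (2.0 * math.pi)
    R = min(0.3 * box, 0.9 * ell)
    aq = math.sqrt(max(ell**2 - R**2, 1e-12))
    fine = max(40 * N, 4000)
    t = np.linspace(0.0, 2.0 * math.pi, fine, endpoint=False)
    for q in range(2, 600):
        a = aq / q
        if R + a > 0.46 * box:
            continue
        if a < 1.1:  # tube too thin -> curvature radius below bead size
            break
        curve = np.stack(
            [
                (R + a * np.cos(q * t)) * np.cos(t),
                (R + a * np.cos(q * t)) * np.sin(t),
                a * np.sin(q * t),
            ],
            axis=1,
        )
        # rescale so the contour length matches N * bond_length exactly
        d = np.linalg.norm(np.diff(np.vstack([curve, curve[:1]]), axis=0), axis=1)
        scale = target_len / d.sum()
        if not 0.8 < scale < 1.2 or scale * (R + a) > 0.47 * box:
            continue
        pts = _resample_closed_curve(curve * scale, N)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(0.9, output_type="ndarray")
        if len(pairs) == 0:
            return pts
        ring_sep = np.minimum(
            np.abs(pairs[:, 0] - pairs[:, 1]),
            N - np.abs(pairs[:, 0] - pairs[:, 1]),
        )
        if np.all(ring_sep <= 1):
            return pts
    raise ValueError(
        f"cannot embed a ring of {N} beads (contour {target_len:.0f} sigma) "
        f"in a box of side {box} sigma"
    )


def build_ring_polymer(
    N: int, box: float, seed: int = 0, bond_length: float = 0.97
) -> ParticleConfiguration:
    """Closed, non-self-intersecting starting conformation for the ring.

    A planar circle (exact chord length = ``bond_length``) is used whenever
    its diameter fits the box; longer rings are embedded as a toroidal coil
    (see :func:`_torus_coil`).  Both starts are unknotted; equilibration
    erases the memory of the shape.  The ring topology closes monomer N-1
    onto monomer 0.
    """
    if N < 3:
        raise ValueError("ring needs at least 3 monomers")
    R_circle = bond_length / (2.0 * math.sin(math.pi / N))
    rng = np.random.default_rng(seed)
    if 2.0 * R_circle <= 0.92 * box:
        ang = 2.0 * math.pi * np.arange(N) / N
        pts = np.stack(
            [R_circle * np.cos(ang), R_circle * np.sin(ang), np.zeros(N)], axis=1
        )
    else:
        pts = _torus_coil(N, box, bond_length)
    # random rigid rotation + centering in the box, seed-reproducible
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    pts = pts @ rot.T + box / 2.0
    bonds = np.stack([np.arange(N), (np.arange(N) + 1) % N], axis=1).astype(np.int64)
    return ParticleConfiguration(
        positions=pts,
        species=np.full(N, MONOMER, dtype=np.int64),
        molecule_id=np.zeros(N, dtype=np.int64),
        box=float(box),
        fene_bonds=bonds,
    )


def build_hns_triplex(center, axis, bp: BondedParams = BondedParams()):
    """One H-NS triplex at rest: core at ``center``, patches at
    center +- r0 * axis (axis must be a unit vector).

    Returns (positions (3,3) ordered core/patch/patch, species, local
    harmonic-bond and angle topology with 0-based indices into the triple).
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-8:
        raise ValueError("axis must be a unit vector")
    center = np.asarray(center, dtype=float)
    pos = np.stack(
        [center, center + bp.hns_r0 * axis, center - bp.hns_r0 * axis]
    )
    species = np.array([CORE, PATCH, PATCH], dtype=np.int64)
    harm = np.array([[0, 1], [0, 2]], dtype=np.int64)
    angle = np.array([[1, 0, 2]], dtype=np.int64)
    return pos, species, harm, angle


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

def _min_image_dists(p, others, L):
    d = others - p
    d -= L * np.rint(d / L)
    return np.linalg.norm(d, axis=1)


def _pair_sigma_vector(table, s_new, species_existing):
    """Per-existing-particle sigma_ij against a new particle of species
    s_new (0 where the pair is inactive)."""
    out = np.zeros(len(species_existing))
    for s in np.unique(species_existing):
        pp = table.params(int(s), s_new)
        out[species_existing == s] = pp.sigma if pp.active else 0.0
    return out


def assemble_system(
    spec: SystemSpec,
    table: InteractionTable | None = None,
    bp: BondedParams = BondedParams(),
    overlap_factor: float = 0.9,
    max_retries: int = 40,
) -> ParticleConfiguration:
    """Build the full system described by ``spec`` (deterministic per seed).

    Order: ring monomers, then H-NS triplexes (random positions/orientations
    with rejection), then crowders (random sequential insertion through a
    jitted cell-grid kernel).  Every active nonbonded pair ends at least
    ``overlap_factor * sigma_ij`` apart; residual soft overlaps are relaxed
    by the integrator's capped-displacement warmup.
    """
    eff_table = spec.interaction_table(table)
    L = spec.box_side
    rng = np.random.default_rng(spec.seed)

    config = build_ring_polymer(
        spec.n_monomers, L, seed=int(rng.integers(2**31 - 1))
    )
    positions = [config.positions]
    species = [config.species]
    mol = [config.molecule_id]
    harm_bonds, harm_k, harm_r0, harm_kind, angles = [], [], [], [], []

    # --- H-NS triplexes ---
    placed_pos = config.positions
    placed_sp = config.species
    for h in range(spec.n_hns):
        ok = False
        for _ in range(20000):
            center = rng.random(3) * L
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            tri_pos, tri_sp, tri_harm, tri_ang = build_hns_triplex(center, axis, bp)
            ok = True
            for p, s in zip(tri_pos, tri_sp):
                sig = _pair_sigma_vector(eff_table, int(s), placed_sp)
                d = _min_image_dists(p, placed_pos, L)
                if np.any(d < overlap_factor * sig):
                    ok = False
                    break
            if ok:
                break
        if not ok:
            raise RuntimeError(f"failed to place H-NS triplex {h} after bounded retries")
        base = sum(len(p) for p in positions)
        positions.append(tri_pos)
        species.append(tri_sp)
        mol.append(np.full(3, h + 1, dtype=np.int64))
        harm_bonds.append(tri_harm + base)
        harm_k.extend([bp.hns_K, bp.hns_K])
        harm_r0.extend([bp.hns_r0, bp.hns_r0])
        harm_kind.extend([KIND_HNS_RADIAL, KIND_HNS_RADIAL])
        angles.append(tri_ang + base)
        placed_pos = np.vstack([placed_pos, tri_pos])
        placed_sp = np.concatenate([placed_sp, tri_sp])

    # --- crowders ---
    n_crowd = crowder_count(spec.phi_c, L, spec.crowder_diameter)
    if n_crowd > 0:
        sig_exist = _pair_sigma_vector(eff_table, CROWDER, placed_sp)
        pp44 = eff_table.params(CROWDER, CROWDER)
        for attempt in range(max_retries):
            pts, n_placed = _kernels.insert_spheres(
                n_crowd,
                L,
                placed_pos,
                overlap_factor * sig_exist,
                overlap_factor * (pp44.sigma if pp44.active else 0.0),
                int(rng.integers(2**31 - 1)),
                1000 * n_crowd,
            )
            if n_placed == n_crowd:
                break
        else:
            achieved = (
                n_placed * math.pi / 6.0 * spec.crowder_diameter**3 / L**3
            )
            raise RuntimeError(
                f"crowder packing failed: placed {n_placed}/{n_crowd} "
                f"(phi_c achieved {achieved:.3f} of {spec.phi_c})"
            )
        base = sum(len(p) for p in positions)
        positions.append(pts)
        species.append(np.full(n_crowd, CROWDER, dtype=np.int64))
        mol.append(np.arange(spec.n_hns + 1, spec.n_hns + 1 + n_crowd, dtype=np.int64))

    config = ParticleConfiguration(
        positions=np.vstack(positions),
        species=np.concatenate(species),
        molecule_id=np.concatenate(mol),
        box=L,
        fene_bonds=config.fene_bonds,
        harm_bonds=(
            np.vstack(harm_bonds).astype(np.int64)
            if harm_bonds
            else np.zeros((0, 2), dtype=np.int64)
        ),
        harm_k=np.array(harm_k),
        harm_r0=np.array(harm_r0),
        harm_kind=np.array(harm_kind, dtype=np.int64),
        angles=(
            np.vstack(angles).astype(np.int64)
            if angles
            else np.zeros((0, 3), dtype=np.int64)
        ),
    )
    if spec.n_anchored:
        config = anchor_hns(config, spec.n_anchored, seed=int(rng.integers(2**31 - 1)))
    _validate(config, spec)
    return config


def anchor_hns(
    config: ParticleConfiguration, n_anchor: int, seed: int = 0
) -> ParticleConfiguration:
    """Tether one patch of ``n_anchor`` H-NS dimers to distinct,
    uniformly chosen monomers via stiff harmonic bonds.

    The anchored dimers keep their other patch free, so they can still
    bridge; the tether fixes *which* dimers are bound, mimicking a
    fixed-number-bound control.  Site choice is seed-reproducible.
    """
    if n_anchor == 0:
        return config
    triplets = config.hns_triplets()
    if n_anchor > len(triplets):
        raise ValueError(f"cannot anchor {n_anchor} H-NS; only {len(triplets)} present")
    rng = np.random.default_rng(seed)
    monomers = config.monomer_indices
    sites = rng.choice(monomers, size=n_anchor, replace=False)
    new = config.copy()
    add_bonds = np.stack(
        [triplets[:n_anchor, 1], sites], axis=1
    ).astype(np.int64)
    new.harm_bonds = np.vstack([new.harm_bonds, add_bonds])
    new.harm_k = np.concatenate([new.harm_k, np.full(n_anchor, ANCHOR_K)])
    new.harm_r0 = np.concatenate([new.harm_r0, np.full(n_anchor, ANCHOR_R0)])
    new.harm_kind = np.concatenate(
        [new.harm_kind, np.full(n_anchor, KIND_ANCHOR, dtype=np.int64)]
    )
    return new


def _validate(config: ParticleConfiguration, spec: SystemSpec) -> None:
    n_crowd = crowder_count(spec.phi_c, spec.box_side, spec.crowder_diameter)
    expected = spec.n_monomers + 3 * spec.n_hns + n_crowd
    if config.n_particles != expected:
        raise AssertionError(
            f"particle count mismatch: {config.n_particles} != {expected}"
        )
    assert len(config.fene_bonds) == spec.n_monomers
    assert config.n_hns == spec.n_hns
    assert len(config.angles) == spec.n_hns
    n_radial = int(np.sum(config.harm_kind == KIND_HNS_RADIAL))
    assert n_radial == 2 * spec.n_hns
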