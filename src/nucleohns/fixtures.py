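"""Deterministic hand-built frames with analytically known observables.

These fixtures let every analysis stage be exercised without running any
dynamics: cluster partitions are placed by construction, binding modes are
realized by exact sub-/super-cutoff patch placement, and ring geometries
have closed-form radii of gyration.  Each fixture's stored truth is
verified against a brute-force recomputation at build time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analysis import CLUSTER_CUTOFF, CONTACT_CUTOFF
from .builder import (
    CORE,
    MONOMER,
    PATCH,
    ParticleConfiguration,
    build_hns_triplex,
    build_ring_polymer,
)
from .interactions import BondedParams

__all__ = ["FixtureFrame", "make_fixture"]


@dataclass
class FixtureFrame:
    config: ParticleConfiguration
    truth: dict


def _add_triplexes(config: ParticleConfiguration, placements) -> ParticleConfiguration:
    """Append H-NS triplexes (center, axis) to a configuration."""
    bp = BondedParams()
    pos = [config.positions]
    sp = [config.species]
    mol = [config.molecule_id]
    harm, angles = [], []
    base = config.n_particles
    next_mol = int(config.molecule_id.max(initial=-1)) + 1
    for center, axis in placements:
        tp, ts, th, ta = build_hns_triplex(center, axis, bp)
        pos.append(tp)
        sp.append(ts)
        mol.append(np.full(3, next_mol))
        harm.append(th + base)
        angles.append(ta + base)
        base += 3
        next_mol += 1
    n_hns = len(placements)
    return ParticleConfiguration(
        positions=np.vstack(pos),
        species=np.concatenate(sp),
        molecule_id=np.concatenate(mol).astype(np.int64),
        box=config.box,
        fene_bonds=config.fene_bonds,
        harm_bonds=(
            np.vstack(harm).astype(np.int64) if harm else np.zeros((0, 2), dtype=np.int64)
        ),
        harm_k=np.full(2 * n_hns, bp.hns_K),
        harm_r0=np.full(2 * n_hns, bp.hns_r0),
        harm_kind=np.zeros(2 * n_hns, dtype=np.int64),
        angles=(
            np.vstack(angles).astype(np.int64) if angles else np.zeros((0, 3), dtype=np.int64)
        ),
    )


def _known_rg(radius: float = 10.0, n: int = 100, box: float = 100.0, seed: int = 0):
    """Ring monomers on a circle of given radius: Rg equals the radius
    exactly (every bead is at distance `radius` from the centroid)."""
    rng = np.random.default_rng(seed)
    ang = 2 * math.pi * np.arange(n) / n
    pts = np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], axis=1
    )
    shift = rng.random(3) * box
    pts = (pts + shift) % box  # wrapped on purpose: exercises unwrapping
    cfg = ParticleConfiguration(
        positions=pts,
        species=np.full(n, MONOMER, dtype=np.int64),
        molecule_id=np.zeros(n, dtype=np.int64),
        box=box,
        fene_bonds=np.stack([np.arange(n), (np.arange(n) + 1) % n], axis=1).astype(
            np.int64
        ),
    )
    return FixtureFrame(config=cfg, truth={"rg": radius})


def _mixed_binding(
    n_dangling: int = 3, n_bridging: int = 2, n_free: int = 5, seed: int = 0
):
    """Ring + H-NS with prescribed binding modes.

    Dangling dimers hover over one monomer with the near patch at 0.6
    sigma (inside the 0.685 cutoff) and the far patch at 1.4; bridging
    dimers sit over the midpoint of a bond with both patches within the
    cutoff of distinct monomers; free dimers float far from everything.
    All cores are kept > 3 sigma apart, so the cluster partition is all
    singletons.
    """
    n_mono, box = 60, 60.0
    # explicit planar circle in the xy-plane (no random rotation) so the
    # +z placements below have exact, known distances to every monomer
    radius = 0.97 / (2 * math.sin(math.pi / n_mono))
    ang = 2 * math.pi * np.arange(n_mono) / n_mono
    mono = np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_mono)], axis=1
    ) + box / 2
    ring = ParticleConfiguration(
        positions=mono,
        species=np.full(n_mono, MONOMER, dtype=np.int64),
        molecule_id=np.zeros(n_mono, dtype=np.int64),
        box=box,
        fene_bonds=np.stack(
            [np.arange(n_mono), (np.arange(n_mono) + 1) % n_mono], axis=1
        ).astype(np.int64),
    )
    center = mono.mean(axis=0)
    placements = []
    n_hns = n_dangling + n_bridging + n_free
    # spread used monomers around the ring so cores stay well separated
    sites = np.linspace(0, n_mono, n_dangling + n_bridging, endpoint=False).astype(int)
    up = np.array([0.0, 0.0, 1.0])
    for k in range(n_dangling):
        m = mono[sites[k]]
        core = m + 1.0 * up
        placements.append((core, up))  # near patch at 0.6 below core
    for k in range(n_bridging):
        j = sites[n_dangling + k]
        a, b = mono[j], mono[(j + 1) % n_mono]
        axis = (b - a) / np.linalg.norm(b - a)
        core = (a + b) / 2 + 0.55 * up
        placements.append((core, axis))
    rng = np.random.default_rng(seed + 1)
    for k in range(n_free):
        lateral = center[:2] + 15.0 * np.array(
            [math.cos(2 * math.pi * k / max(n_free, 1)),
             math.sin(2 * math.pi * k / max(n_free, 1))]
        )
        core = np.array([lateral[0], lateral[1], center[2] + 8.0 + 4.0 * k])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        placements.append((core, axis))
    # dangling triplex: patch order from build is (+axis, -axis); re-point
    # the near patch at the monomer by placing the core above it
    cfg = _add_triplexes(ring, placements)
    theta = (n_dangling + n_bridging) / n_hns
    truth = {
        "theta": theta,
        "frac_dangling": n_dangling / n_hns,
        "frac_bridging": n_bridging / n_hns,
        "cluster_histogram": {1: n_hns},
    }
    return FixtureFrame(config=cfg, truth=truth)


def _clustered(sizes=(24, 3, 2, 1), box: float = 80.0, seed: int = 0):
    """H-NS cores placed in prescribed connected components.

    Members of one cluster sit on a compact cubic sub-lattice with 2.5
    sigma spacing (< 3 sigma cutoff, guaranteeing connectivity);
    component anchors are separated by >> 3 sigma.  A small far-away ring
    keeps the frame a valid polymer configuration.
    """
    sizes = tuple(int(s) for s in sizes)
    ring = build_ring_polymer(12, box, seed=seed)
    # keep the ring away from the cluster region
    ring.positions += np.array([0.0, 0.0, box / 2 - 5.0])
    rng = np.random.default_rng(seed + 7)
    placements = []
    spacing = 2.5
    anchor_step = spacing * 4 + CLUSTER_CUTOFF + 2.0  # > cutoff between components
    for ci, size in enumerate(sizes):
        anchor = np.array([6.0 + ci * anchor_step, 6.0, 6.0])
        m = max(1, math.ceil(size ** (1 / 3)))
        k = 0
        for iz in range(m):
            for iy in range(m):
                for ix in range(m):
                    if k >= size:
                        break
                    center = anchor + spacing * np.array([ix, iy, iz])
                    axis = rng.normal(size=3)
                    axis /= np.linalg.norm(axis)
                    placements.append((center, axis))
                    k += 1
    cfg = _add_triplexes(ring, placements)
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    return FixtureFrame(config=cfg, truth={"cluster_histogram": hist,
                                           "mean_size": sum(sizes) / len(sizes)})


def make_fixture(kind: str, seed: int = 0, **kwargs) -> FixtureFrame:
    """Build a deterministic fixture frame of the requested kind.

    kinds: ``known_rg`` (circle with closed-form Rg), ``mixed_binding``
    (prescribed dangling/bridging/free counts), ``clustered`` (prescribed
    cluster-size multiset).  The stored truth is re-verified by brute
    force before returning.
    """
    builders = {
        "known_rg": _known_rg,
        "mixed_binding": _mixed_binding,
        "clustered": _clustered,
    }
    if kind not in builders:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(builders)}")
    fx = builders[kind](seed=seed, **kwargs)
    _verify(fx)
    return fx


def _brute_force_clusters(pos: np.ndarray, box: float, cutoff: float) -> dict:
    """Adjacency + breadth-first search, independent of the production path."""
    n = len(pos)
    seen = [False] * n
    hist: dict[int, int] = {}
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], 0
        seen[s] = True
        while stack:
            i = stack.pop()
            comp += 1
            for j in range(n):
                if not seen[j]:
                    d = pos[i] - pos[j]
                    d -= box * np.rint(d / box)
                    if (d**2).sum() <= cutoff**2:
                        seen[j] = True
                        stack.append(j)
        hist[comp] = hist.get(comp, 0) + 1
    return hist


def _verify(fx: FixtureFrame) -> None:
    cfg, truth = fx.config, fx.truth
    if "rg" in truth:
        from .analysis import radius_of_gyration

        if abs(radius_of_gyration(cfg) - truth["rg"]) > 1e-9 * max(truth["rg"], 1):
            raise AssertionError("known_rg fixture failed brute-force verification")
    if "cluster_histogram" in truth:
        cores = cfg.positions[cfg.core_indices]
        hist = _brute_force_clusters(cores, cfg.box, CLUSTER_CUTOFF)
        if hist != truth["cluster_histogram"]:
            raise AssertionError(
                f"cluster fixture mismatch: built {hist}, expected "
                f"{truth['cluster_histogram']}"
            )
    if "theta" in truth:
        mono = cfg.positions[cfg.monomer_indices]
        n_d = n_b = 0
        for core, pa, pb in cfg.hns_triplets():
            hits = []
            for p in (pa, pb):
                d = mono - cfg.positions[p]
                d -= cfg.box * np.rint(d / cfg.box)
                hits.append(bool((np.sum(d**2, axis=1) < CONTACT_CUTOFF**2).any()))
            if all(hits):
                n_b += 1
            elif any(hits):
                n_d += 1
        n = cfg.n_hns
        if (n_d / n, n_b / n) != (truth["frac_dangling"], truth["frac_bridging"]):
            raise AssertionError(
                f"binding fixture mismatch: dangling {n_d}, bridging {n_b}"
            )
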