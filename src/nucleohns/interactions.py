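"""Closed-form energies and forces of the coarse-grained Hamiltonian.

Four species make up the model: DNA monomers (1), H-NS patches (2), H-NS
cores (3), and crowders (4).  All nonbonded pairs interact through a
truncated-shifted Lennard-Jones potential; the ring polymer is held together
by FENE springs; each H-NS dimer is a rigid-ish triplex (core + two antipodal
patches) held by stiff radial springs and a harmonic angle centred at 180°.

Units are reduced throughout: lengths in the monomer diameter ``sigma``,
energies in ``epsilon = k_B T``, times in ``tau = sigma * sqrt(m / epsilon)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PairParams",
    "InteractionTable",
    "BondedParams",
    "SPECIES_NAMES",
    "pair_energy",
    "pair_force",
    "fene_energy",
    "fene_force",
    "hns_internal_energy",
    "potential_minimum",
]

#: species labels in the published numbering, indexed 1..4
SPECIES_NAMES = {1: "monomer", 2: "patch", 3: "core", 4: "crowder"}

_RMIN_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class PairParams:
    """LJ parameters for one species pair.

    ``active=False`` encodes pairs that do not interact at all (patch-core
    and patch-crowder); such pairs contribute exactly zero energy and force.
    """

    epsilon: float
    sigma: float
    r_cut: float
    active: bool = True

    def __post_init__(self) -> None:
        if self.active:
            if self.epsilon <= 0 or self.sigma <= 0 or self.r_cut <= 0:
                raise ValueError(
                    "active pair requires positive epsilon, sigma, r_cut; got "
                    f"({self.epsilon}, {self.sigma}, {self.r_cut})"
                )

    @property
    def is_purely_repulsive(self) -> bool:
        """True when the cutoff sits at the LJ minimum (WCA convention).

        Compared with 1% relative tolerance: the published table rounds
        sigma to 3 decimals, so r_cut = 2^{1/6} sigma holds only
        approximately (e.g. the patch-patch pair, 0.2 vs 0.19981)."""
        return self.active and abs(self.r_cut - _RMIN_FACTOR * self.sigma) < 0.01 * self.r_cut


INACTIVE = PairParams(epsilon=0.0, sigma=0.0, r_cut=0.0, active=False)


def _wca(sigma: float, epsilon: float = 1.0) -> PairParams:
    return PairParams(epsilon=epsilon, sigma=sigma, r_cut=_RMIN_FACTOR * sigma)


@dataclass(frozen=True)
class BondedParams:
    """Bonded interaction constants (ring FENE + H-NS internal potential)."""

    fene_k0: float = 30.0     # epsilon / sigma^2
    fene_r0: float = 1.5      # sigma, maximum FENE extension
    hns_K: float = 120.0      # epsilon / sigma^2, core-patch radial spring
    hns_r0: float = 0.4       # sigma, core-patch rest distance
    hns_kb: float = 50.0      # epsilon, patch-core-patch angle stiffness

    def __post_init__(self) -> None:
        vals = (self.fene_k0, self.fene_r0, self.hns_K, self.hns_r0, self.hns_kb)
        if any(v <= 0 for v in vals):
            raise ValueError("all bonded constants must be positive")
        if self.fene_r0 <= 1.0:
            raise ValueError("fene_r0 must exceed the typical bond length (~1 sigma)")


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric 4x4 map of species pair -> :class:`PairParams`.

    Keys are unordered pairs (i, j) with species indices 1..4.  The default
    construction reproduces the published parameter table for the N=200
    system; :meth:`paper_n2000` gives the long-chain variant with larger
    crowders.
    """

    pair_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = {}
        for (i, j), pp in self.pair_params.items():
            if not (1 <= i <= 4 and 1 <= j <= 4):
                raise ValueError(f"species indices must be 1..4, got ({i},{j})")
            key = (min(i, j), max(i, j))
            if key in canon and canon[key] != pp:
                raise ValueError(f"conflicting parameters for pair {key}")
            canon[key] = pp
        for i in range(1, 5):
            for j in range(i, 5):
                canon.setdefault((i, j), INACTIVE)
        object.__setattr__(self, "pair_params", canon)

    # -- construction ----------------------------------------------------
    @classmethod
    def paper_n200(cls) -> "InteractionTable":
        """Published pair-parameter table for the N=200 system.

        Patch-monomer (1-2) is the single attractive pair: epsilon_12 = 29,
        with the cutoff pushed 0.085 sigma past the WCA point so that the
        potential has an attractive well of depth ~8.65 k_BT near r=0.6.
        Patch-core (2-3) and patch-crowder (2-4) do not interact.
        """
        p = {
            (1, 1): _wca(1.0),
            (1, 2): PairParams(epsilon=29.0, sigma=0.535, r_cut=0.685),
            (1, 3): _wca(1.0),
            (1, 4): _wca(1.5),
            (2, 2): PairParams(epsilon=1.0, sigma=0.178, r_cut=0.2),
            (2, 3): INACTIVE,
            (2, 4): INACTIVE,
            (3, 3): _wca(1.0),
            (3, 4): _wca(1.5),
            (4, 4): _wca(2.0),
        }
        return cls(p)

    @classmethod
    def paper_n2000(cls) -> "InteractionTable":
        """Long-chain variant: crowder diameter 4 sigma, hence larger
        monomer-crowder and core-crowder ranges (2.5 sigma)."""
        base = cls.paper_n200()
        p = dict(base.pair_params)
        p[(1, 4)] = _wca(2.5)
        p[(3, 4)] = _wca(2.5)
        p[(4, 4)] = _wca(4.0)
        return cls(p)

    # -- access ----------------------------------------------------------
    def params(self, i: int, j: int) -> PairParams:
        return self.pair_params[(min(i, j), max(i, j))]

    def deactivate(self, i: int, j: int) -> "InteractionTable":
        """Return a copy with pair (i, j) switched off (e.g. the
        crowder-permeable H-NS control deactivates 3-4 only)."""
        p = dict(self.pair_params)
        p[(min(i, j), max(i, j))] = INACTIVE
        return InteractionTable(p)

    def max_cutoff(self) -> float:
        return max(
            (pp.r_cut for pp in self.pair_params.values() if pp.active), default=0.0
        )

    def as_arrays(self):
        """Dense 4x4 arrays (eps, sigma^2, rcut^2, shift, active) for the
        force kernels; indexed by 0-based species."""
        eps = np.zeros((4, 4))
        sig2 = np.zeros((4, 4))
        rc2 = np.zeros((4, 4))
        shift = np.zeros((4, 4))
        act = np.zeros((4, 4), dtype=np.bool_)
        for (i, j), pp in self.pair_params.items():
            if not pp.active:
                continue
            for a, b in ((i - 1, j - 1), (j - 1, i - 1)):
                eps[a, b] = pp.epsilon
                sig2[a, b] = pp.sigma**2
                rc2[a, b] = pp.r_cut**2
                shift[a, b] = _lj(pp.r_cut, pp.epsilon, pp.sigma)
                act[a, b] = True
        return eps, sig2, rc2, shift, act

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for (i, j), pp in sorted(self.pair_params.items()):
            out[f"{i}-{j}"] = (
                {"epsilon": pp.epsilon, "sigma": pp.sigma, "r_cut": pp.r_cut}
                if pp.active
                else None
            )
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionTable":
        p = {}
        for key, val in d.items():
            i, j = (int(t) for t in key.split("-"))
            p[(i, j)] = (
                PairParams(val["epsilon"], val["sigma"], val["r_cut"])
                if val is not None
                else INACTIVE
            )
        return cls(p)

    def dump(self) -> str:
        """Human-readable rendering of the effective pair table (audit aid)."""
        lines = ["pair  eps[eps]  sigma[sig]  r_cut[sig]"]
        for (i, j), pp in sorted(self.pair_params.items()):
            if pp.active:
                lines.append(f"{i}-{j}   {pp.epsilon:<9g} {pp.sigma:<11g} {pp.r_cut:g}")
            else:
                lines.append(f"{i}-{j}   N/A       N/A         N/A")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def _lj(r, epsilon, sigma):
    s6 = (sigma / r) ** 6
    return 4.0 * epsilon * (s6 * s6 - s6)


def pair_energy(r, pp: PairParams):
    """Truncated-shifted LJ energy U_LJ(r) - U_LJ(r_cut) for r < r_cut, else 0.

    Accepts scalar or array ``r`` (in sigma); returns energy in epsilon.
    Inactive pairs contribute exactly zero by contract.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    if not pp.active:
        return np.zeros_like(r) if r.ndim else 0.0
    u = np.where(r < pp.r_cut, _lj(r, pp.epsilon, pp.sigma) - _lj(pp.r_cut, pp.epsilon, pp.sigma), 0.0)
    return u if u.ndim else float(u)


def pair_force(r, pp: PairParams):
    """Signed radial force -dU/dr of the truncated-shifted LJ pair.

    Positive values push the particles apart.  Identically zero at and
    beyond the cutoff (the shift does not alter the force).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    if not pp.active:
        return np.zeros_like(r) if r.ndim else 0.0
    s6 = (pp.sigma / r) ** 6
    f = np.where(r < pp.r_cut, 24.0 * pp.epsilon * (2.0 * s6 * s6 - s6) / r, 0.0)
    return f if f.ndim else float(f)


def fene_energy(r, bp: BondedParams = BondedParams()):
    """FENE bond energy -(1/2) k0 r0^2 ln[1 - (r/r0)^2]; diverges at r0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(r >= bp.fene_r0):
        raise ValueError(
            f"FENE bond overstretched (r >= r0 = {bp.fene_r0}); "
            "this usually signals integrator instability"
        )
    u = -0.5 * bp.fene_k0 * bp.fene_r0**2 * np.log1p(-((r / bp.fene_r0) ** 2))
    return u if u.ndim else float(u)


def fene_force(r, bp: BondedParams = BondedParams()):
    """Restoring force -dU_FENE/dr = -k0 r / (1 - (r/r0)^2) (always inward)."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= bp.fene_r0):
        raise ValueError("FENE bond overstretched")
    f = -bp.fene_k0 * r / (1.0 - (r / bp.fene_r0) ** 2)
    return f if f.ndim else float(f)


def hns_internal_energy(core, patch_a, patch_b, bp: BondedParams = BondedParams()):
    """Internal energy of one H-NS triplex.

    One radial spring K (r - r0)^2 per patch plus a single angle term
    k_b (theta - pi)^2, where theta is the angle between the two
    core->patch vectors.  Zero at the rest geometry (antipodal patches at
    distance r0 from the core).
    """
    core = np.asarray(core, dtype=float)
    a = np.asarray(patch_a, dtype=float) - core
    b = np.asarray(patch_b, dtype=float) - core
    ra = float(np.linalg.norm(a))
    rb = float(np.linalg.norm(b))
    if ra < 1e-12 or rb < 1e-12:
        raise ValueError("patch coincides with core; angle undefined")
    cos_t = float(np.clip(np.dot(a, b) / (ra * rb), -1.0, 1.0))
    theta = math.acos(cos_t)
    return (
        bp.hns_K * (ra - bp.hns_r0) ** 2
        + bp.hns_K * (rb - bp.hns_r0) ** 2
        + bp.hns_kb * (theta - math.pi) ** 2
    )


def potential_minimum(pp: PairParams):
    """Location and value of the global minimum of the truncated-shifted LJ
    potential on (0, r_cut].

    For attractive pairs (cutoff past the WCA point) the minimum sits at
    2^{1/6} sigma_ij; for purely repulsive pairs it is 0 at the cutoff.
    Returns ``(r_min, u_min)``.
    """
    if not pp.active:
        raise ValueError("potential_minimum requires an active pair")
    r_lo = 0.5 * pp.sigma
    res = minimize_scalar(
        lambda r: pair_energy(r, pp), bounds=(r_lo, pp.r_cut), method="bounded",
        options={"xatol": 1e-10},
    )
    r_min, u_min = float(res.x), float(res.fun)
    # the boundary r_cut (u = 0) competes for repulsive pairs
    if u_min >= 0.0:
        r_min, u_min = pp.r_cut, 0.0
    return r_min, u_min
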