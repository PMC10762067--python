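"""Unit and property tests for the closed-form interaction terms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleohns.interactions import (
    BondedParams,
    InteractionTable,
    PairParams,
    fene_energy,
    fene_force,
    hns_internal_energy,
    pair_energy,
    pair_force,
    potential_minimum,
)

RMIN = 2 ** (1 / 6)
ACTIVE_PAIRS = [(1, 1), (1, 2), (1, 3), (1, 4), (2, 2), (3, 3), (3, 4), (4, 4)]


@pytest.fixture(scope="module")
def table():
    return InteractionTable.paper_n200()


class TestPairPotential:
    def test_patch_monomer_well_depth(self, table):
        """The patch-monomer attraction has a ~ -8.65 k_BT minimum near 0.6."""
        pp = table.params(1, 2)
        u = pair_energy(0.6, pp)
        assert u == pytest.approx(-8.65, abs=0.05)
        assert pair_energy(0.62, pp) < 0 < pair_energy(0.5, pp)

    @pytest.mark.parametrize("i,j", ACTIVE_PAIRS)
    def test_zero_at_cutoff_and_beyond(self, table, i, j):
        pp = table.params(i, j)
        assert pair_energy(pp.r_cut, pp) == 0.0
        assert pair_energy(1.5 * pp.r_cut, pp) == 0.0
        assert pair_force(pp.r_cut, pp) == 0.0
        assert pair_force(1.5 * pp.r_cut, pp) == 0.0

    @pytest.mark.parametrize("i,j", ACTIVE_PAIRS)
    def test_continuity_at_cutoff(self, table, i, j):
        """Truncation-shift makes the energy continuous at r_cut: the value
        just inside the cutoff is bounded by |U'(rc)| * delta (the slope is
        zero only for exact-WCA cutoffs)."""
        pp = table.params(i, j)
        delta = 1e-7
        slope = abs(pair_force(pp.r_cut - 1e-9, pp))
        assert abs(pair_energy(pp.r_cut - delta, pp)) <= slope * delta * 1.01 + 1e-9

    def test_wca_shifted_minimum_is_zero(self, table):
        pp = table.params(1, 1)
        assert pair_energy(RMIN * pp.sigma, pp) == pytest.approx(0.0, abs=1e-12)
        assert pair_force(RMIN * pp.sigma, pp) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("i,j", ACTIVE_PAIRS)
    def test_force_matches_energy_gradient(self, table, i, j):
        """-dU/dr via central differences, 100 random radii per pair."""
        pp = table.params(i, j)
        rng = np.random.default_rng(42)
        r = rng.uniform(0.7 * pp.sigma, 1.2 * pp.r_cut, size=100)
        r = r[np.abs(r - pp.r_cut) > 1e-5]  # derivative is discontinuous there
        h = 1e-7 * pp.sigma
        fd = -(pair_energy(r + h, pp) - pair_energy(r - h, pp)) / (2 * h)
        f = pair_force(r, pp)
        assert np.all(np.abs(f - fd) / np.maximum(1.0, np.abs(f)) < 1e-6)

    @pytest.mark.parametrize(
        "i,j", [(1, 1), (1, 3), (1, 4), (2, 2), (3, 3), (3, 4), (4, 4)]
    )
    def test_purely_repulsive_pairs_nonnegative(self, table, i, j):
        """WCA-type pairs never attract (up to the ~3e-5 epsilon residue the
        3-decimal rounding of the published sigma values leaves)."""
        pp = table.params(i, j)
        assert pp.is_purely_repulsive
        r = np.linspace(0.5 * pp.sigma, 1.5 * pp.r_cut, 2000)
        assert np.all(pair_energy(r, pp) >= -1e-4)

    def test_inactive_pair_contributes_nothing(self, table):
        pp = table.params(2, 3)
        assert not pp.active
        assert pair_energy(0.5, pp) == 0.0
        assert pair_force(0.5, pp) == 0.0

    def test_domain_errors(self, table):
        pp = table.params(1, 1)
        with pytest.raises(ValueError):
            pair_energy(0.0, pp)
        with pytest.raises(ValueError):
            pair_force(-1.0, pp)


class TestPotentialMinimum:
    def test_attractive_pair(self, table):
        r, u = potential_minimum(table.params(1, 2))
        assert r == pytest.approx(0.6, abs=0.01)          # ~2^{1/6} sigma_12
        assert u == pytest.approx(-8.65, abs=0.05)
        assert u < 0

    def test_wca_pair(self, table):
        r, u = potential_minimum(table.params(1, 1))
        assert u == 0.0
        assert r == pytest.approx(RMIN, abs=1e-6)

    def test_against_dense_grid_scan(self, table):
        pp = table.params(1, 2)
        grid = np.arange(0.3, pp.r_cut, 1e-5)
        u_grid = pair_energy(grid, pp).min()
        _, u = potential_minimum(pp)
        assert abs(u - u_grid) < 0.05
        assert u <= u_grid + 1e-9


class TestTable:
    def test_reproduces_published_parameters(self, table):
        expect = {
            (1, 1): (1.0, 1.0, RMIN),
            (1, 2): (29.0, 0.535, 0.685),
            (1, 3): (1.0, 1.0, RMIN),
            (1, 4): (1.0, 1.5, 1.5 * RMIN),
            (2, 2): (1.0, 0.178, 0.2),
            (3, 3): (1.0, 1.0, RMIN),
            (3, 4): (1.0, 1.5, 1.5 * RMIN),
            (4, 4): (1.0, 2.0, 2.0 * RMIN),
        }
        for (i, j), (eps, sig, rc) in expect.items():
            pp = table.params(i, j)
            assert pp.active
            assert (pp.epsilon, pp.sigma) == (eps, sig)
            assert pp.r_cut == pytest.approx(rc, abs=1e-12)
        for pair in [(2, 3), (2, 4)]:
            assert not table.params(*pair).active

    def test_symmetry_and_n2000_variant(self, table):
        assert table.params(2, 1) == table.params(1, 2)
        t2 = InteractionTable.paper_n2000()
        assert t2.params(1, 4).sigma == 2.5
        assert t2.params(3, 4).sigma == 2.5
        assert t2.params(4, 4).sigma == 4.0
        assert t2.params(1, 2) == table.params(1, 2)

    def test_deactivate_is_scoped(self, table):
        t = table.deactivate(3, 4)
        assert not t.params(3, 4).active
        assert t.params(1, 4).active and t.params(4, 4).active

    def test_serialization_round_trip(self, table):
        assert InteractionTable.from_dict(table.to_dict()) == table

    def test_invalid_pair_params_rejected(self):
        with pytest.raises(ValueError):
            PairParams(epsilon=-1.0, sigma=1.0, r_cut=1.0)


class TestBondedTerms:
    def test_fene_reference_values(self):
        bp = BondedParams()
        assert fene_energy(0.0, bp) == 0.0
        # -(1/2) * 30 * 1.5^2 * ln(1 - 0.36) at r = 0.9
        assert fene_energy(0.9, bp) == pytest.approx(33.75 * -math.log(0.64), rel=1e-12)
        assert fene_energy(0.9, bp) == pytest.approx(15.06, abs=0.01)

    def test_fene_monotone_and_diverging(self):
        bp = BondedParams()
        r = np.linspace(0.0, 1.45, 300)
        u = fene_energy(r, bp)
        assert np.all(np.diff(u) > 0)
        with pytest.raises(ValueError):
            fene_energy(1.5, bp)

    def test_fene_force_is_gradient(self):
        bp = BondedParams()
        r = np.linspace(0.1, 1.3, 50)
        h = 1e-7
        fd = -(fene_energy(r + h, bp) - fene_energy(r - h, bp)) / (2 * h)
        assert np.allclose(fene_force(r, bp), fd, rtol=1e-6)

    def test_hns_rest_configuration_is_zero(self):
        bp = BondedParams()
        core = np.zeros(3)
        u = hns_internal_energy(core, [0, 0, 0.4], [0, 0, -0.4], bp)
        assert u == pytest.approx(0.0, abs=1e-12)

    def test_hns_stretched_patch(self):
        u = hns_internal_energy([0, 0, 0], [0, 0, 0.5], [0, 0, -0.4])
        assert u == pytest.approx(120 * 0.1**2, rel=1e-9)

    def test_hns_bent_angle(self):
        u = hns_internal_energy([0, 0, 0], [0.4, 0, 0], [0, 0.4, 0])
        assert u == pytest.approx(50 * (math.pi / 2) ** 2, rel=1e-9)

    def test_hns_coincident_patch_rejected(self):
        with pytest.raises(ValueError):
            hns_internal_energy([0, 0, 0], [0, 0, 0], [0, 0, 0.4])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_hns_energy_rigid_motion_invariant(self, seed):
        """Internal energy depends only on the triplex's shape."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        core = rng.normal(size=3)
        pa = core + rng.normal(scale=0.3, size=3)
        pb = core + rng.normal(scale=0.3, size=3)
        u0 = hns_internal_energy(core, pa, pb)
        rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        t = rng.normal(scale=10, size=3)
        u1 = hns_internal_energy(rot @ core + t, rot @ pa + t, rot @ pb + t)
        assert u1 == pytest.approx(u0, rel=1e-9, abs=1e-9)
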