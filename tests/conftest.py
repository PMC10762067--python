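"""Shared fixtures.  The heavy Langevin runs are session-scoped so the
stochastic acceptance checks and the qualitative property tests share one
set of simulations."""

from __future__ import annotations

import numpy as np
import pytest

from nucleohns import InteractionTable, SystemSpec
from nucleohns.experiments import crowding_sweep, reference_point, run_observables
from nucleohns.interactions import INACTIVE


@pytest.fixture(scope="session")
def table():
    return InteractionTable.paper_n200()


@pytest.fixture(scope="session")
def synergy_sweep():
    """Small-system sweep over phi_c in {0, 0.1, 0.2} (N=50 ring, 8 H-NS).

    Desk-scale stand-in for the crowding/bridging synergy readout."""
    return crowding_sweep(
        seed=101,
        phi_values=(0.0, 0.1, 0.2),
        n_monomers=50,
        box_side=20.0,
        n_hns=8,
        equil_tau=1_500.0,
        prod_tau=5_000.0,
        sample_tau=12.5,
    )


@pytest.fixture(scope="session")
def reference_experiment():
    """phi_c = 0 reference point: N=200 ring + 30 H-NS vs matched baseline."""
    return reference_point(
        seed=401,
        n_replicas=3,
        n_baseline_replicas=1,
        equil_tau=8_000.0,
        prod_tau=10_000.0,
        sample_tau=25.0,
    )


@pytest.fixture(scope="session")
def phantom_ring_rgs():
    """Mean squared Rg of ideal (all nonbonded interactions off) rings for
    N in {50, 100, 200}: the Gaussian ring law predicts <Rg^2> ~ N."""
    phantom = InteractionTable(
        {(i, j): INACTIVE for i in range(1, 5) for j in range(i, 5)}
    )
    out = {}
    for n, box in ((50, 60.0), (100, 60.0), (200, 80.0)):
        spec = SystemSpec(n_monomers=n, box_side=box, phi_c=0.0, n_hns=0, seed=500 + n)
        df, _, _ = run_observables(
            spec, equil_tau=1_500.0, prod_tau=4_000.0, sample_tau=10.0,
            table=phantom,
        )
        out[n] = float((df["rg"] ** 2).mean())
    return out
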