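"""Experiment presets reproducing the published parameter grids.

The flagship grid is the N=200 ring in a 50 sigma box (125 nm at
sigma = 2.5 nm): crowder volume fractions up to ~0.4 and H-NS copy
numbers {0, 4, 8, 12, 16, 20, 30}, i.e. [H-NS] = {0, 3.4, 6.8, 10.2,
13.6, 17.0, 25.5} uM.  The long-chain variant (N=2000, 110 sigma box,
4 sigma crowders) is available but computationally far heavier.
"""

from __future__ import annotations

from dataclasses import dataclass

from .builder import SystemSpec
from .dynamics import IntegratorSettings, RunSchedule
from .interactions import InteractionTable
from .units import SIGMA_NM, molar_concentration

__all__ = ["ExperimentPreset", "get_preset", "PRESETS", "hns_concentration"]

#: published H-NS copy-number grid for the N=200 box
HNS_GRID = (0, 4, 8, 12, 16, 20, 30)
#: crowder volume fractions spanning the published range 0 <= phi_c <~ 0.4
PHI_GRID = (0.0, 0.05, 0.1, 0.15, 0.2, 0.26, 0.32, 0.4)


def hns_concentration(n_hns: int, box_side_sigma: float) -> float:
    """[H-NS] in uM for a copy number in a cubic box given in sigma."""
    return molar_concentration(n_hns, box_side_sigma * SIGMA_NM)


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    spec: SystemSpec
    settings: IntegratorSettings
    schedule: RunSchedule
    grid: tuple = ()                     # (phi_c, n_hns) sweep points
    table: InteractionTable | None = None

    def effective_table(self) -> InteractionTable:
        return self.table if self.table is not None else InteractionTable.paper_n200()


def _full_schedule() -> RunSchedule:
    # the published production schedule: 1e8 equilibration + 1e9 production
    # steps, sampled every 5e3 steps (25 tau)
    return RunSchedule(
        equilibration_steps=100_000_000,
        production_steps=1_000_000_000,
        sample_interval=5_000,
    )


def _desk_schedule() -> RunSchedule:
    # desk-scale schedule: ~4e3 tau warm equilibration + 1.5e4 tau
    # production at the published sampling period of 25 tau
    return RunSchedule(
        equilibration_steps=800_000,
        production_steps=3_000_000,
        sample_interval=5_000,
    )


PRESETS = {
    "paper-N200": ExperimentPreset(
        name="paper-N200",
        spec=SystemSpec(n_monomers=200, box_side=50.0, phi_c=0.0, n_hns=30,
                        crowder_diameter=2.0),
        settings=IntegratorSettings(),
        schedule=_full_schedule(),
        grid=tuple((phi, nh) for phi in PHI_GRID for nh in HNS_GRID),
    ),
    "paper-N2000": ExperimentPreset(
        name="paper-N2000",
        spec=SystemSpec(n_monomers=2000, box_side=110.0, phi_c=0.0, n_hns=300,
                        crowder_diameter=4.0),
        settings=IntegratorSettings(),
        schedule=_full_schedule(),
        grid=tuple((phi, nh) for phi in PHI_GRID for nh in (0, 300)),
        table=InteractionTable.paper_n2000(),
    ),
    "desk-N200": ExperimentPreset(
        name="desk-N200",
        spec=SystemSpec(n_monomers=200, box_side=50.0, phi_c=0.0, n_hns=30,
                        crowder_diameter=2.0),
        settings=IntegratorSettings(),
        schedule=_desk_schedule(),
        grid=tuple((phi, nh) for phi in (0.0, 0.1, 0.2) for nh in (0, 30)),
    ),
    "desk-small": ExperimentPreset(
        name="desk-small",
        spec=SystemSpec(n_monomers=50, box_side=20.0, phi_c=0.0, n_hns=8,
                        crowder_diameter=2.0),
        settings=IntegratorSettings(),
        schedule=RunSchedule(
            equilibration_steps=200_000, production_steps=800_000,
            sample_interval=2_000,
        ),
        grid=tuple((phi, 8) for phi in (0.0, 0.1, 0.2)),
    ),
}


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
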