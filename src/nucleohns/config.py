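"""YAML configuration round-trip for specs, integrator settings, schedules.

Lengths are in sigma, energies in epsilon = k_BT, times in tau; the
``concentration`` helpers accept physical units via the sigma = 2.5 nm
mapping (see :mod:`nucleohns.units`).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .builder import SystemSpec
from .dynamics import IntegratorSettings, RunSchedule
from .interactions import InteractionTable

__all__ = ["save_config", "load_config"]


def save_config(
    path,
    spec: SystemSpec,
    settings: IntegratorSettings | None = None,
    schedule: RunSchedule | None = None,
    table: InteractionTable | None = None,
) -> None:
    doc = {
        "system": asdict(spec),
        "integrator": asdict(settings or IntegratorSettings()),
        "schedule": asdict(schedule or RunSchedule()),
    }
    if table is not None:
        doc["interaction_table"] = table.to_dict()
    Path(path).write_text(
        "# nucleohns configuration (lengths: sigma, energies: k_BT, times: tau)\n"
        + yaml.safe_dump(doc, sort_keys=True)
    )


def load_config(path):
    doc = yaml.safe_load(Path(path).read_text())
    spec = SystemSpec(**doc["system"])
    settings = IntegratorSettings(**doc.get("integrator", {}))
    schedule = RunSchedule(**doc.get("schedule", {}))
    table = (
        InteractionTable.from_dict(doc["interaction_table"])
        if "interaction_table" in doc
        else None
    )
    return spec, settings, schedule, table
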