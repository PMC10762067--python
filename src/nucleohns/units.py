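"""Reduced-unit conventions and conversions to physical units.

The monomer diameter sets the length unit, sigma = 2.5 nm (one bead
coarse-grains ~7.35 bp of hydrated B-DNA); energies are in epsilon = k_B T
and times in tau = sigma * sqrt(m / epsilon).
"""

from __future__ import annotations

SIGMA_NM = 2.5          # nm per reduced length unit
AVOGADRO = 6.02214076e23

__all__ = ["SIGMA_NM", "molar_concentration", "count_for_concentration"]


def molar_concentration(count: int, box_side_nm: float) -> float:
    """Molar concentration (in uM) of ``count`` particles in a cubic box.

    Example: 200 monomers in a (125 nm)^3 box give ~170 uM; 30 H-NS dimers
    give ~25.5 uM.
    """
    if box_side_nm <= 0:
        raise ValueError("box side must be positive")
    volume_l = (box_side_nm * 1e-9) ** 3 * 1e3  # m^3 -> liters
    return count / (AVOGADRO * volume_l) * 1e6


def count_for_concentration(conc_um: float, box_side_nm: float) -> int:
    """Inverse of :func:`molar_concentration`, rounded to the nearest count."""
    volume_l = (box_side_nm * 1e-9) ** 3 * 1e3
    return int(round(conc_um * 1e-6 * AVOGADRO * volume_l))
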