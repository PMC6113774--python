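"""Dermis volume and fibroblast division-count estimates from body measurements.

The mouse trunk is idealised as a cylinder; the dermis is the cylindrical
shell of thickness h under the surface, so its volume for trunk length L
and radius R is pi*L*(R^2 - (R-h)^2).  Multiplying by fibroblast density
gives cell numbers, and the predicted number of cell divisions between a
younger and an older age is log2 of the cell-number ratio.  With a ~13-fold
postnatal volume increase but a large drop in cell density, the estimate
comes out near 1.3 divisions — postnatal dermal growth is matrix expansion,
not proliferation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["BodySnapshot", "dermis_volume", "predicted_divisions", "cell_number"]


@dataclass(frozen=True)
class BodySnapshot:
    """Body measurements at one age (lengths in mm, density per mm^3)."""

    age: float
    trunk_length: float
    trunk_diameter: float
    dermis_thickness: float
    fibroblast_density: float

    def __post_init__(self) -> None:
        for name in ("trunk_length", "trunk_diameter", "dermis_thickness", "fibroblast_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dermis_thickness >= self.trunk_diameter / 2:
            raise ValueError("dermis thickness must be less than the trunk radius")


def dermis_volume(snapshot: BodySnapshot, geometry: str = "shell") -> float:
    """Dermis volume in mm^3.

    ``"shell"`` (default) treats the dermis as the surface layer of the
    trunk cylinder; ``"solid"`` returns the full cylinder volume, for
    comparison with conventions that do not subtract the core.
    """
    R = snapshot.trunk_diameter / 2.0
    h = snapshot.dermis_thickness
    L = snapshot.trunk_length
    if h >= R:
        raise ValueError("dermis thickness must be less than the trunk radius")
    if geometry == "shell":
        return math.pi * L * (R**2 - (R - h) ** 2)
    if geometry == "solid":
        return math.pi * L * R**2
    raise ValueError(f"unknown geometry {geometry!r}")


def cell_number(snapshot: BodySnapshot, geometry: str = "shell") -> float:
    """Estimated fibroblast count: density times dermis volume."""
    return snapshot.fibroblast_density * dermis_volume(snapshot, geometry)


def predicted_divisions(n_older: float, n_younger: float) -> float:
    """log2(N_older / N_younger): divisions needed to explain the change in
    cell number between two ages.  Additive over consecutive intervals."""
    if n_older <= 0 or n_younger <= 0:
        raise ValueError("cell numbers must be positive")
    return math.log2(n_older / n_younger)
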