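"""Configuration of the Cellular Potts tissue model.

All numeric parameters of the lattice model live here, with defaults tuned
once so that the simulated proliferation time course is anchored at
MCS 300 to the birth-time (P0) measurement; no sensitivity analysis is
implied.  The full default set is also shipped as ``data/cpm_defaults.toml``
and any run can be reproduced from a TOML file via :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

__all__ = ["CpmConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class CpmConfig:
    # lattice & geometry (pixels)
    size: int = 200
    lumen_radius: float = 45.0
    epidermis_inner_radius: float = 78.0
    epidermis_thickness: float = 4.0
    n_epidermal_cells: int = 48
    n_fibroblasts: int = 10
    # initial fibroblasts are radial spokes spanning the (embryonically
    # thin) dermis, touching both the epidermis and the body wall
    fibroblast_spoke_halfangle: float = 0.03  # radians

    # Metropolis dynamics
    temperature: float = 14.0
    lambda_volume: float = 4.0
    ecm_stiffness: float = 25.0  # extra work to displace a matrix pixel
    target_volume: float = 25.0
    division_volume: float = 45.0
    target_volume_cap: float = 60.0  # growth stalls at this size until division
    qf_target_volume: float = 12.0  # quiescent cells condense, freeing space for matrix
    target_relax: float = 0.02  # per-MCS relaxation of growth drive toward baseline
    qf_condense_rate: float = 0.01  # per-MCS relaxation of QF size toward resting

    # contact energies by type pair (symmetric); "cell" covers the three
    # fibroblast states and adipocytes
    j_cell_medium: float = 9.0
    j_cell_cell: float = 20.0
    j_cell_ecm: float = 4.0
    j_cell_epidermis: float = 25.0
    j_cell_clot: float = 8.0
    j_epidermis_medium: float = 6.0
    j_epidermis_epidermis: float = 2.0
    j_epidermis_clot: float = 6.0
    j_default: float = 10.0

    # epidermal signal field
    epi_amplitude: float = 1.0
    epi_half_life_mcs: float = 90.0
    epi_decay: float = 0.003  # per-sweep loss -> decay length ~ sqrt(1/(4*decay))
    epi_sweeps: int = 6  # Jacobi relaxation sweeps per MCS

    # wound signal field (short range, own decay clock)
    wound_amplitude: float = 1.0
    wound_half_life_mcs: float = 150.0
    wound_decay: float = 0.08
    wound_sweeps: int = 6

    # growth / division
    growth_rate: float = 2.5  # target-volume gain per MCS per unit local signal
    wound_growth_rate: float = 2.5  # extra gain for activated cells from wound field
    epidermal_wound_growth: float = 0.3

    # matrix deposition (per adjacent free pixel per MCS)
    p_deposit_qf: float = 0.055
    p_deposit_pf: float = 0.005
    # matrix maturation: deposited fibrils extend into adjacent free space
    p_ecm_spread: float = 0.009
    # matrix compaction: fibrils encroach on cells above their target size,
    # squeezing them back to it (per boundary pixel per MCS)
    p_ecm_compact: float = 0.02

    # differentiation & wounding schedule (MCS)
    adipocyte_onset_mcs: int = 300
    wound_mcs: int = 1200
    end_mcs: int = 1500
    wound_halfangle: float = 0.13  # radians; slice ~20 px wide at the epidermis
    activation_radius: float = 14.0
    n_immune_cells: int = 6

    # chemotaxis strengths toward the wound field
    chemotaxis_activated: float = 60.0
    chemotaxis_epidermis: float = 30.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("lattice size must be at least 64")
        if not (0 < self.lumen_radius < self.epidermis_inner_radius):
            raise ValueError("need 0 < lumen_radius < epidermis_inner_radius")
        if self.epidermis_inner_radius + self.epidermis_thickness >= self.size / 2:
            raise ValueError("epidermis ring does not fit on the lattice")
        for name in ("p_deposit_qf", "p_deposit_pf"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def save_config(config: CpmConfig, path: Union[str, Path]) -> None:
    """Write every field of the config as a flat TOML file."""
    lines = ["# Cellular Potts tissue model configuration\n"]
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, bool):
            lines.append(f"{f.name} = {str(v).lower()}")
        elif isinstance(v, (int, float)):
            lines.append(f"{f.name} = {v!r}")
        else:
            lines.append(f'{f.name} = "{v}"')
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_config(path: Union[str, Path]) -> CpmConfig:
    """Read a config written by :func:`save_config` (unknown keys rejected)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    names = {f.name for f in dataclasses.fields(CpmConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return CpmConfig(**raw)
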