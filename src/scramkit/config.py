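"""Configurable physical constants, overridable from a YAML file.

Keys:

* ``area_per_lipid_nm2`` — phospholipid cross-section (nm^2)
* ``lipid_molar_mass`` — lipid molar mass (g/mol)
* ``avg_protein_mass_da`` — average membrane-protein mass (Da)
* ``total_er_membrane_proteins`` — ER membrane proteins per cell
* ``vesicle_diameter_nm`` — default vesicle diameter (nm)
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .occupancy import (
    AREA_PER_LIPID_NM2,
    AVG_PROTEIN_MASS_DA,
    DEFAULT_VESICLE_DIAMETER_NM,
    EGG_PC_MOLAR_MASS_G_MOL,
    TOTAL_ER_MEMBRANE_PROTEINS,
)

DEFAULT_CONSTANTS: dict[str, float] = {
    "area_per_lipid_nm2": AREA_PER_LIPID_NM2,
    "lipid_molar_mass": EGG_PC_MOLAR_MASS_G_MOL,
    "avg_protein_mass_da": AVG_PROTEIN_MASS_DA,
    "total_er_membrane_proteins": TOTAL_ER_MEMBRANE_PROTEINS,
    "vesicle_diameter_nm": DEFAULT_VESICLE_DIAMETER_NM,
}


def load_constants(path: str | Path | None = None) -> dict[str, float]:
    """Defaults merged with overrides from a YAML file (if given).

    Unknown keys raise :class:`ConfigurationError` rather than being
    silently ignored.
    """
    constants = dict(DEFAULT_CONSTANTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigurationError(f"{path}: expected a mapping of constants")
        unknown = set(loaded) - set(constants)
        if unknown:
            raise ConfigurationError(f"{path}: unknown constant keys {sorted(unknown)}")
        for key, value in loaded.items():
            constants[key] = float(value)
    for key, value in constants.items():
        if value <= 0:
            raise ConfigurationError(f"constant {key} must be > 0, got {value}")
    return constants


def load_yaml(path: str | Path) -> dict[str, Any]:
    """Load an arbitrary YAML mapping (e.g. a simulation config)."""
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, Mapping):
        raise ConfigurationError(f"{path}: expected a YAML mapping")
    return dict(loaded)
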