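"""Cellular constants of *H. salinarum* and conversions between the
concentration units used across the bioenergetics literature.

All conversions pivot through the amount per "OD·mL" — one millilitre of
suspension at optical density 1, which contains a known cell count, cell
volume, cell-water volume and protein mass. Every unit maps linearly to
moles per OD·mL, so conversions are exact, invertible and composable.

Two volume pivots coexist deliberately: intracellular model concentrations
are treated as per litre of *cell water* when converting to mass-of-water
units (mmol/kg cell water, nmol/mg protein), but the compartment
conservation laws of the ODE model use the *total cell volume* (1.36 μL
per OD·mL). Both pivots are exposed as explicit units so the caller
chooses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources


class UnitError(ValueError):
    """Unknown or presently unusable unit."""


@dataclass(frozen=True)
class CellGeometry:
    """Building-block constants of a 1 OD·mL suspension.

    Volumes in μL per OD·mL, masses as annotated. ``protein_mass_per_ODmL``
    is a calibrated constant (chosen so that 2.2 mmol ATP/L cell water
    corresponds to 7.5 nmol ATP/mg protein) and should be overridden with a
    measured protein content when one is available. The shipped organic
    material (0.47) and cellular salt (0.45) volumes do not sum to the cell
    volume (1.36); the constants are kept verbatim and no such sum is
    enforced.
    """

    pellet_volume_per_ODmL: float = 1.81       # μL
    cells_per_ODmL: float = 1.36e9
    cell_volume_per_ODmL: float = 1.36         # μL
    cell_water_per_ODmL: float = 0.80          # μL
    organic_material_per_ODmL: float = 0.47    # μL
    cellular_basal_salt_per_ODmL: float = 0.45  # μL
    intercellular_salt_per_ODmL: float = 0.89  # μL
    cell_mass_per_ODmL: float = 1.63           # μg
    mass_per_cell: float = 1.2                 # pg
    protein_mass_per_ODmL: float | None = 0.2347  # mg, calibrated

    def with_values(self, **kw) -> "CellGeometry":
        return replace(self, **kw)

    @property
    def volume_per_cell_fL(self) -> float:
        """Cell volume in femtolitres (≈ 1 fL)."""
        return self.cell_volume_per_ODmL * 1e-6 / self.cells_per_ODmL * 1e15


def default_geometry() -> CellGeometry:
    with resources.files("haloresp.data").joinpath("cell_geometry.json").open() as fh:
        payload = json.load(fh)
    g = payload["geometry"]
    return CellGeometry(
        pellet_volume_per_ODmL=g["pellet_volume_per_ODmL_uL"],
        cells_per_ODmL=g["cells_per_ODmL"],
        cell_volume_per_ODmL=g["cell_volume_per_ODmL_uL"],
        cell_water_per_ODmL=g["cell_water_per_ODmL_uL"],
        organic_material_per_ODmL=g["organic_material_per_ODmL_uL"],
        cellular_basal_salt_per_ODmL=g["cellular_basal_salt_per_ODmL_uL"],
        intercellular_salt_per_ODmL=g["intercellular_salt_per_ODmL_uL"],
        cell_mass_per_ODmL=g["cell_mass_per_ODmL_ug"],
        mass_per_cell=g["mass_per_cell_pg"],
        protein_mass_per_ODmL=g["protein_mass_per_ODmL_mg"],
    )


def _per_ODmL_factor(unit: str, geometry: CellGeometry) -> float:
    """Moles per OD·mL corresponding to one unit of ``unit``."""
    water_L = geometry.cell_water_per_ODmL * 1e-6
    volume_L = geometry.cell_volume_per_ODmL * 1e-6
    if unit == "mol_per_ODmL":
        return 1.0
    if unit == "mol_per_cell":
        return geometry.cells_per_ODmL
    if unit == "mol/L_cell_water":
        return water_L
    if unit == "mmol/kg_cell_water":
        # density of cell water taken as 1 kg/L
        return 1e-3 * water_L
    if unit == "mol/L_cell_volume":
        return volume_L
    if unit == "nmol/mg_protein":
        if geometry.protein_mass_per_ODmL is None:
            raise UnitError(
                "protein-based unit requested but protein_mass_per_ODmL is "
                "not calibrated; supply a geometry with a protein mass")
        return 1e-9 * geometry.protein_mass_per_ODmL
    raise UnitError(f"unknown unit {unit!r}")


UNITS = ("mol/L_cell_water", "mmol/kg_cell_water", "mol/L_cell_volume",
         "nmol/mg_protein", "mol_per_cell", "mol_per_ODmL")


def convert(value: float, from_unit: str, to_unit: str,
            geometry: CellGeometry | None = None) -> float:
    """Convert ``value`` between concentration/amount units.

    Linear and exactly invertible: ``convert(convert(x, A, B), B, A) == x``
    to floating-point round-off.
    """
    if geometry is None:
        geometry = default_geometry()
    if from_unit == to_unit:
        _per_ODmL_factor(from_unit, geometry)  # still validate the name
        return value
    return value * _per_ODmL_factor(from_unit, geometry) / _per_ODmL_factor(to_unit, geometry)


def geometry_report(geometry: CellGeometry | None = None) -> dict:
    """Structured summary of the cellular constants, by volume and mass,
    with units and provenance notes."""
    if geometry is None:
        geometry = default_geometry()
    protein = geometry.protein_mass_per_ODmL
    return {
        "per_ODmL": {
            "pellet_volume_uL": geometry.pellet_volume_per_ODmL,
            "cell_count": geometry.cells_per_ODmL,
            "cell_volume_uL": geometry.cell_volume_per_ODmL,
            "cell_water_uL": geometry.cell_water_per_ODmL,
            "organic_material_uL": geometry.organic_material_per_ODmL,
            "cellular_basal_salt_uL": geometry.cellular_basal_salt_per_ODmL,
            "intercellular_salt_uL": geometry.intercellular_salt_per_ODmL,
            "cell_mass_ug": geometry.cell_mass_per_ODmL,
            "protein_mass_mg": protein,
        },
        "per_cell": {
            "mass_pg": geometry.mass_per_cell,
            "volume_fL": geometry.volume_per_cell_fL,
        },
        "derived": {
            "water_fraction_of_cell_volume":
                geometry.cell_water_per_ODmL / geometry.cell_volume_per_ODmL,
        },
        "provenance": {
            "protein_mass_mg": "calibrated against the printed pair "
                               "(2.2 mmol/L cell water, 7.5 nmol/mg protein); "
                               "overridable",
            "others": "literature-derived constants for a 1 OD·mL suspension",
        },
    }
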