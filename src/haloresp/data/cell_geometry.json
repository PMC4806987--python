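{
  "version": "1.0",
  "description": "Cellular 'building block' constants for H. salinarum, normalized to 1 mL of suspension at OD 1 (one OD.mL). Volumes in microliters, masses in micrograms unless noted.",
  "geometry": {
    "pellet_volume_per_ODmL_uL": 1.81,
    "cells_per_ODmL": 1.36e9,
    "cell_volume_per_ODmL_uL": 1.36,
    "cell_water_per_ODmL_uL": 0.80,
    "organic_material_per_ODmL_uL": 0.47,
    "cellular_basal_salt_per_ODmL_uL": 0.45,
    "intercellular_salt_per_ODmL_uL": 0.89,
    "cell_mass_per_ODmL_ug": 1.63,
    "mass_per_cell_pg": 1.2,
    "protein_mass_per_ODmL_mg": 0.2347
  },
  "provenance": {
    "protein_mass_per_ODmL_mg": "calibrated: chosen so that 2.2 mmol ATP / L cell water corresponds to 7.5 nmol ATP / mg protein; override with measured protein content when available",
    "others": "literature-derived constants for a 1 OD.mL suspension"
  }
}
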