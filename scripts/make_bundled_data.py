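"""Regenerate the static CSV tables bundled under ``src/dentalcbct/data``.

Run from the repository root:

    python scripts/make_bundled_data.py

The element attenuation table and the tube spectra come from the analytic
models in ``dentalcbct._physics_model``; the material table is the reference
jaw-region composition table typed in verbatim.
"""

from __future__ import annotations

import csv
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from dentalcbct._physics_model import (
    ELEMENTS,
    ENERGY_GRID_KEV,
    mass_attenuation_parts,
    tube_spectrum,
)

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "dentalcbct" / "data"

# Reference material table for the dental jaw region: structure ID, name,
# ICRP phantom organ ID, density [mg/cm^3], elemental weight fractions [%]
# for H, C, N, O, P, Ca.  Note structure ID 7 intentionally does not exist.
MATERIALS = [
    (0, "air", 0, 1, 0.0, 0.0, 70.0, 30.0, 0.0, 0.0),
    (1, "cranium_cortical", 26, 1920, 3.6, 15.9, 4.2, 44.8, 9.4, 21.3),
    (2, "cranium_spongiosa", 27, 1245, 8.1, 31.7, 2.8, 45.1, 3.7, 7.8),
    (3, "mandible_cortical", 39, 1920, 3.6, 15.9, 4.2, 44.8, 9.4, 21.3),
    (4, "mandible_spongiosa", 40, 1189, 8.7, 35.7, 2.6, 42.9, 3.0, 6.3),
    (5, "cervical_spine_cortical", 47, 1920, 3.6, 15.9, 4.2, 44.8, 9.4, 21.3),
    (6, "cervical_spine_spongiosa", 48, 1135, 9.2, 35.1, 2.9, 45.8, 2.1, 4.3),
    (8, "residual_tissue_head", 116, 950, 11.4, 58.9, 0.7, 28.7, 0.0, 0.0),
    (9, "skin_head", 122, 1090, 10.0, 19.9, 4.2, 65.0, 0.1, 0.0),
    (10, "tooth", 128, 2750, 2.2, 9.5, 2.9, 42.1, 13.7, 28.9),
    (11, "air_inside_body", 140, 1, 0.0, 0.0, 70.0, 30.0, 0.0, 0.0),
]

SPECTRA = {
    "soft-90kVp": (90.0, 2.5),
    "hard-90kVp": (90.0, 6.5),
    "100kVp": (100.0, 6.5),
}


def write_materials() -> None:
    with open(DATA / "materials.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "name", "icrp_id", "density_mg_cm3", "wH", "wC", "wN", "wO", "wP", "wCa"]
        )
        writer.writerows(MATERIALS)


def write_elements() -> None:
    path = DATA / "elements_mu.csv"
    with open(path, "w", newline="") as fh:
        fh.write(
            "# Per-element mass attenuation [cm^2/g], 1-keV grid. Each column\n"
            "# already absorbs the Z*N_A/A electrons-per-gram factor, so the\n"
            "# linear attenuation of a pure element is rho * (pe + compton + rayleigh).\n"
            "# Analytic model: Klein-Nishina Compton, E^-3 photoelectric anchored at\n"
            "# 30 keV to reference totals, water-calibrated Z^2.5/E^2 Rayleigh.\n"
        )
        writer = csv.writer(fh)
        writer.writerow(
            [
                "element",
                "Z",
                "A",
                "energy_keV",
                "mu_over_rho_pe",
                "mu_over_rho_compton",
                "mu_over_rho_rayleigh",
            ]
        )
        for element, (z, a, _anchor) in ELEMENTS.items():
            pe, compton, rayleigh = mass_attenuation_parts(element, ENERGY_GRID_KEV)
            for i, energy in enumerate(ENERGY_GRID_KEV):
                writer.writerow(
                    [
                        element,
                        z,
                        a,
                        f"{energy:.0f}",
                        f"{pe[i]:.8e}",
                        f"{compton[i]:.8e}",
                        f"{rayleigh[i]:.8e}",
                    ]
                )


def write_spectra() -> None:
    for name, (kvp, al_mm) in SPECTRA.items():
        weights = tube_spectrum(kvp, al_mm)
        mean_e = float(np.sum(ENERGY_GRID_KEV * weights))
        with open(DATA / "spectra" / f"{name}.csv", "w", newline="") as fh:
            fh.write(
                f"# {name}: tungsten anode {kvp:.0f} kVp, {al_mm} mm Al filter\n"
                f"# simplified Kramers + K-line model; mean energy {mean_e:.2f} keV\n"
            )
            writer = csv.writer(fh)
            writer.writerow(["energy_keV", "weight"])
            for energy, weight in zip(ENERGY_GRID_KEV, weights):
                writer.writerow([f"{energy:.0f}", f"{weight:.8e}"])


if __name__ == "__main__":
    write_materials()
    write_elements()
    write_spectra()
    print(f"wrote tables under {DATA}")
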