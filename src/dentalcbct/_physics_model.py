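"""Analytic photon cross-section and X-ray tube spectrum models.

This module is the generator behind the static tables bundled under
``dentalcbct/data``; ``scripts/make_bundled_data.py`` calls into it to
(re)write those CSVs.  Runtime code reads the CSVs, so this module is only
imported when regenerating package data or when a test wants the closed-form
model directly.

Cross sections
--------------
For the diagnostic range (10-120 keV) the linear attenuation of element *m*
decomposes into photoelectric absorption, Compton (incoherent) scattering and
Rayleigh (coherent) scattering.  The model used here is:

* Compton: exact free-electron Klein-Nishina cross section per electron,
  multiplied by Z electrons per atom.  For Z <= 20 above ~20 keV electron
  binding corrections are at the percent level and are neglected.
* Photoelectric: a per-element ``tau(E) = tau_30 * (30/E)**3`` power law.
  ``tau_30`` is anchored so that the *total* mass attenuation at 30 keV
  matches standard reference values for each element.
* Rayleigh: ``sigma_R/rho = C_R * Z**2.5 / A * (30/E)**2`` with a single
  constant calibrated on liquid water at 60 keV.

The resulting totals agree with standard reference tables to within a few
percent over 30-120 keV for H, C, N, O, P, Ca and Al, which is sufficient for
simulating realistic beam hardening and material contrast.

Spectra
-------
Tube spectra are a simplified tungsten-anode model: Kramers bremsstrahlung
``n(E) ~ (E_max - E)/E``, tungsten K characteristic lines (only above the
69.5 keV K edge), and aluminium filtration applied with the Al attenuation
from the cross-section model above.
"""

from __future__ import annotations

import numpy as np

R_E_CM = 2.8179403262e-13  # classical electron radius [cm]
MEC2_KEV = 510.99895  # electron rest energy [keV]
N_AVOGADRO = 6.02214076e23  # [1/mol]

ENERGY_GRID_KEV = np.arange(10.0, 121.0)  # 1-keV bins, inclusive

#: Z, atomic weight A [g/mol], and reference total mass attenuation at
#: 30 keV [cm^2/g] used to anchor the photoelectric term.
ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 0.3570),
    "C": (6, 12.011, 0.2562),
    "N": (7, 14.007, 0.3066),
    "O": (8, 15.999, 0.3779),
    "P": (15, 30.974, 1.700),
    "Ca": (20, 40.078, 4.080),
    "Al": (13, 26.982, 1.128),
}

_C_RAYLEIGH = 3.90e-3  # [cm^2/g] at 30 keV for Z^2.5/A = 1, water-calibrated
_ANCHOR_KEV = 30.0

AL_DENSITY_G_CM3 = 2.699

# Tungsten K lines [keV] and relative fluence weights (pre-filtration),
# expressed as a fraction of the total bremsstrahlung fluence.
_W_KLINES = ((59.0, 0.10), (58.0, 0.055), (67.0, 0.025), (69.0, 0.012))
_W_K_EDGE_KEV = 69.5


def klein_nishina_sigma(energy_kev):
    """Total Klein-Nishina cross section per free electron [cm^2]."""
    k = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    t = 1.0 + 2.0 * k
    return (
        2.0
        * np.pi
        * R_E_CM**2
        * (
            (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - np.log(t) / k)
            + np.log(t) / (2.0 * k)
            - (1.0 + 3.0 * k) / t**2
        )
    )


def mass_attenuation_parts(element: str, energy_kev):
    """(photoelectric, Compton, Rayleigh) mass attenuation [cm^2/g].

    Each part already absorbs the Z*N_A/A electrons-per-gram factor, so the
    linear attenuation of a pure element is ``rho * sum(parts)``.
    """
    z, a, anchor_total = ELEMENTS[element]
    energy = np.asarray(energy_kev, dtype=float)
    compton = N_AVOGADRO * z / a * klein_nishina_sigma(energy)
    rayleigh = _C_RAYLEIGH * z**2.5 / a * (_ANCHOR_KEV / energy) ** 2
    compton_30 = N_AVOGADRO * z / a * klein_nishina_sigma(_ANCHOR_KEV)
    rayleigh_30 = _C_RAYLEIGH * z**2.5 / a
    tau_30 = max(anchor_total - compton_30 - rayleigh_30, 0.0)
    photoelectric = tau_30 * (_ANCHOR_KEV / energy) ** 3
    return photoelectric, compton, rayleigh


def mass_attenuation_total(element: str, energy_kev):
    """Total mass attenuation coefficient mu/rho [cm^2/g]."""
    pe, co, ra = mass_attenuation_parts(element, energy_kev)
    return pe + co + ra


def tube_spectrum(kvp: float, al_filter_mm: float, energy_kev=None):
    """Relative photon fluence per 1-keV bin for a tungsten anode.

    Kramers bremsstrahlung with tungsten K lines (above the K edge only),
    filtered by ``al_filter_mm`` of aluminium.  The returned weights are
    normalized to unit sum over the provided grid; bins at or above ``kvp``
    are exactly zero.
    """
    if energy_kev is None:
        energy_kev = ENERGY_GRID_KEV
    energy = np.asarray(energy_kev, dtype=float)
    fluence = np.clip(kvp - energy, 0.0, None) / energy
    if kvp > _W_K_EDGE_KEV:
        total_brems = fluence.sum()
        for line_kev, frac in _W_KLINES:
            if line_kev < kvp:
                idx = int(np.argmin(np.abs(energy - line_kev)))
                fluence[idx] += frac * total_brems
    mu_rho_al = mass_attenuation_total("Al", energy)
    transmission = np.exp(-mu_rho_al * AL_DENSITY_G_CM3 * al_filter_mm / 10.0)
    weights = fluence * transmission
    weights[energy >= kvp] = 0.0
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"empty spectrum for kvp={kvp}, filter={al_filter_mm} mm Al")
    return weights / total
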