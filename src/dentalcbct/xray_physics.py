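"""Energy spectra and energy-dependent attenuation of mixture materials.

All computation lives on a common 1-keV energy grid (10-120 keV).  The linear
attenuation of a material row is the density times the mass-fraction-weighted
sum of per-element mass attenuation coefficients,

    mu(E) = rho * sum_m w_m (mu/rho)_m(E),

with the per-element coefficients read from the bundled table, which keeps
the photoelectric / Compton / Rayleigh process decomposition as separate
columns (each already absorbing the Z*N_A/A electrons-per-gram factor).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import ELEMENT_ORDER, MaterialRow, VoxelPhantom

logger = logging.getLogger(__name__)

ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 120.0

BUNDLED_SPECTRA = ("soft-90kVp", "hard-90kVp", "100kVp")

_MONO_RE = re.compile(r"^mono-(\d+)$")


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per 1-keV energy bin.

    ``weights`` holds the product of the bin fraction and the source photon
    number — the effective per-bin fluence weighting of the polychromatic
    projection sum.
    """

    energies: np.ndarray  # keV, strictly increasing, 1-keV spacing
    weights: np.ndarray  # >= 0, at least one positive
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "energies", np.asarray(self.energies, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.energies.ndim != 1 or self.energies.shape != self.weights.shape:
            raise ValueError("energies and weights must be 1-D and equal length")
        diffs = np.diff(self.energies)
        if self.energies.size > 1 and not np.allclose(diffs, 1.0):
            raise ValueError("energies must be a strictly increasing 1-keV grid")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be nonnegative with at least one positive")

    def normalized(self) -> "Spectrum":
        """Copy with weights summing to one."""
        return Spectrum(self.energies, self.weights / self.weights.sum(), self.label)

    def mean_energy(self) -> float:
        w = self.weights / self.weights.sum()
        return float(np.sum(self.energies * w))

    def max_energy(self) -> float:
        return float(self.energies[self.weights > 0].max())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"energy_keV": self.energies, "weight": self.weights}).to_csv(
            path, index=False
        )


def load_spectrum(name_or_path: str | Path) -> Spectrum:
    """Load a bundled spectrum by name, a monoenergetic test spectrum
    (``"mono-<keV>"``), or a user CSV with columns ``energy_keV,weight``."""
    name = str(name_or_path)
    match = _MONO_RE.match(name)
    if match:
        energy = float(match.group(1))
        if not (ENERGY_MIN_KEV <= energy <= ENERGY_MAX_KEV):
            raise ValueError(f"mono energy {energy} keV outside table range")
        energies = np.arange(ENERGY_MIN_KEV, ENERGY_MAX_KEV + 1)
        weights = np.zeros_like(energies)
        weights[int(energy - ENERGY_MIN_KEV)] = 1.0
        return Spectrum(energies, weights, label=name)
    if name in BUNDLED_SPECTRA:
        resource = importlib.resources.files("dentalcbct").joinpath(
            f"data/spectra/{name}.csv"
        )
        with importlib.resources.as_file(resource) as path:
            frame = pd.read_csv(path, comment="#")
        return Spectrum(frame["energy_keV"].values, frame["weight"].values, label=name)
    path = Path(name)
    if path.exists():
        frame = pd.read_csv(path, comment="#")
        return Spectrum(frame["energy_keV"].values, frame["weight"].values, label=path.stem)
    raise ValueError(
        f"unknown spectrum {name!r}; bundled spectra are {list(BUNDLED_SPECTRA)} "
        "plus 'mono-<keV>'"
    )


class ElementTable:
    """Per-element mass attenuation on the 1-keV grid, by process."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame
        self.energies = np.sort(frame["energy_keV"].unique()).astype(float)
        self._total: dict[str, np.ndarray] = {}
        for element, sub in frame.groupby("element"):
            sub = sub.sort_values("energy_keV")
            self._total[element] = (
                sub["mu_over_rho_pe"].values
                + sub["mu_over_rho_compton"].values
                + sub["mu_over_rho_rayleigh"].values
            )

    @classmethod
    def bundled(cls) -> "ElementTable":
        resource = importlib.resources.files("dentalcbct").joinpath("data/elements_mu.csv")
        with importlib.resources.as_file(resource) as path:
            return cls(pd.read_csv(path, comment="#"))

    def mass_attenuation(self, element: str, energy_kev) -> np.ndarray | float:
        """Total mu/rho [cm^2/g]; off-grid energies round to the nearest bin."""
        energy = np.asarray(energy_kev, dtype=float)
        if np.any(energy < self.energies[0]) or np.any(energy > self.energies[-1]):
            raise ValueError(
                f"energy {energy_kev} keV outside table range "
                f"[{self.energies[0]:.0f}, {self.energies[-1]:.0f}]"
            )
        idx = np.rint(energy - self.energies[0]).astype(int)
        if not np.allclose(energy, self.energies[idx]):
            logger.warning("off-grid energy %s keV rounded to nearest 1-keV bin", energy_kev)
        out = self._total[element][idx]
        return float(out) if np.isscalar(energy_kev) else out


_BUNDLED_ELEMENTS: ElementTable | None = None


def element_table() -> ElementTable:
    """The bundled element table (cached)."""
    global _BUNDLED_ELEMENTS
    if _BUNDLED_ELEMENTS is None:
        _BUNDLED_ELEMENTS = ElementTable.bundled()
    return _BUNDLED_ELEMENTS


def mu_material(material: MaterialRow, energy_kev, elements: ElementTable | None = None):
    """Linear attenuation mu [1/cm] of one material row at ``energy_kev``."""
    table = elements if elements is not None else element_table()
    fractions = material.weight_fractions
    mu_rho = sum(
        fractions[el] * np.asarray(table.mass_attenuation(el, energy_kev))
        for el in ELEMENT_ORDER
    )
    out = material.density_g_cm3 * mu_rho
    return float(out) if np.isscalar(energy_kev) else out


def mu_by_label(
    phantom: VoxelPhantom, energies_kev, elements: ElementTable | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(label IDs, mu matrix [n_labels, n_energies]) for the phantom's labels.

    This is the per-material attenuation lookup the forward projector works
    from: because attenuation depends on the voxel only through its label,
    ray sums reduce to per-label path lengths times this matrix.
    """
    label_ids = np.array(sorted(phantom.materials.rows), dtype=np.int64)
    energies = np.atleast_1d(np.asarray(energies_kev, dtype=float))
    mu = np.stack(
        [mu_material(phantom.materials[int(sid)], energies, elements) for sid in label_ids]
    )
    return label_ids, mu


def mu_volume(phantom: VoxelPhantom, energy_kev, elements: ElementTable | None = None):
    """Per-voxel linear attenuation map [1/cm] at a single energy."""
    label_ids, mu = mu_by_label(phantom, [energy_kev], elements)
    lut = np.zeros(int(label_ids.max()) + 1)
    lut[label_ids] = mu[:, 0]
    return lut[phantom.labels]
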