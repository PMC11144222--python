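"""Voxel jaw phantoms: material table, I/O, deformation and density variation.

A phantom is a 3-D integer grid of anatomical structure IDs plus a parallel
grid of per-tooth instance IDs (anatomical tooth numbering 101-128, zero
outside teeth).  Each structure ID maps to a material row (density and
elemental weight fractions for H, C, N, O, P, Ca) patterned on the ICRP
reference-phantom compositions; attenuation is derived from those rows by
:mod:`dentalcbct.xray_physics`.

The module also provides a procedural jaw-like fixture generator
(:func:`build_synthetic_jaw`) producing small phantoms with ellipsoid-crown /
cylinder-root "teeth" embedded in a bone slab — geometric fixtures for tests
and scaled experiments, not anatomy.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

ELEMENT_ORDER = ("H", "C", "N", "O", "P", "Ca")

TOOTH_STRUCTURE_ID = 10
TOOTH_INSTANCE_MIN = 101
TOOTH_INSTANCE_MAX = 128

_WEIGHT_COLS = [f"w{el}" for el in ELEMENT_ORDER]


@dataclasses.dataclass(frozen=True)
class MaterialRow:
    """One structure's material: density and elemental weight fractions."""

    structure_id: int
    name: str
    icrp_id: int
    density: float  # mg/cm^3
    weights: tuple[float, ...]  # percent, ordered as ELEMENT_ORDER

    @property
    def density_g_cm3(self) -> float:
        return self.density / 1000.0

    @property
    def weight_fractions(self) -> dict[str, float]:
        """Mass fractions (0-1) per element."""
        return {el: w / 100.0 for el, w in zip(ELEMENT_ORDER, self.weights)}


class MaterialTable:
    """Mapping from structure ID to :class:`MaterialRow`.

    Weight fractions per row must sum to 100% within printed-rounding slack
    (the reference rows drop ICRP minor elements, so sums land at 99.2-100),
    and densities of non-air rows must be positive.
    """

    def __init__(self, rows: dict[int, MaterialRow]):
        self.rows = dict(rows)
        self.validate()

    def validate(self) -> None:
        for sid, row in self.rows.items():
            total = sum(row.weights)
            if not (99.0 <= total <= 101.0):
                raise ValueError(
                    f"material {sid} ({row.name}): weight fractions sum to {total}, "
                    "expected 100 within rounding"
                )
            if row.density <= 0:
                raise ValueError(f"material {sid} ({row.name}): density must be > 0")

    def __getitem__(self, structure_id: int) -> MaterialRow:
        return self.rows[int(structure_id)]

    def __contains__(self, structure_id: int) -> bool:
        return int(structure_id) in self.rows

    def __iter__(self):
        return iter(sorted(self.rows))

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, MaterialTable) and self.rows == other.rows

    def scaled_densities(self, factors: dict[int, float]) -> "MaterialTable":
        """New table with densities multiplied per structure ID."""
        for sid, factor in factors.items():
            if int(sid) not in self.rows:
                raise KeyError(f"density factor given for unknown structure ID {sid}")
            if factor <= 0:
                raise ValueError(f"density factor for ID {sid} must be > 0, got {factor}")
        rows = {}
        for sid, row in self.rows.items():
            factor = float(factors.get(sid, 1.0))
            rows[sid] = dataclasses.replace(row, density=row.density * factor)
        return MaterialTable(rows)

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "id": row.structure_id,
                "name": row.name,
                "icrp_id": row.icrp_id,
                "density_mg_cm3": row.density,
                **{col: w for col, w in zip(_WEIGHT_COLS, row.weights)},
            }
            for _, row in sorted(self.rows.items())
        ]
        return pd.DataFrame.from_records(records)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MaterialTable":
        rows = {}
        for rec in frame.to_dict("records"):
            sid = int(rec["id"])
            rows[sid] = MaterialRow(
                structure_id=sid,
                name=str(rec["name"]),
                icrp_id=int(rec["icrp_id"]),
                density=float(rec["density_mg_cm3"]),
                weights=tuple(float(rec[c]) for c in _WEIGHT_COLS),
            )
        return cls(rows)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MaterialTable":
        return cls.from_frame(pd.read_csv(path, comment="#"))


def reference_materials() -> MaterialTable:
    """The bundled jaw-region reference material table.

    Eleven structures (IDs 0-6 and 8-11; ID 7 is unassigned): air, three
    cortical and three spongiosa bone compartments, residual head tissue,
    skin, tooth (2750 mg/cm^3, 28.9% Ca) and air inside the body.
    """
    with importlib.resources.as_file(
        importlib.resources.files("dentalcbct").joinpath("data/materials.csv")
    ) as path:
        return MaterialTable.from_csv(path)


@dataclasses.dataclass
class VoxelPhantom:
    """Labeled voxel volume with per-tooth instances and a material table."""

    labels: np.ndarray  # int, 3-D structure IDs
    tooth_instances: np.ndarray  # int, 3-D; 101-128 on tooth voxels, else 0
    voxel_pitch: tuple[float, float, float]  # mm per axis
    materials: MaterialTable

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.tooth_instances = np.asarray(self.tooth_instances)
        self.voxel_pitch = tuple(float(p) for p in self.voxel_pitch)
        self.validate()

    def validate(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        if self.labels.shape != self.tooth_instances.shape:
            raise ValueError(
                f"label grid {self.labels.shape} and instance grid "
                f"{self.tooth_instances.shape} differ in shape"
            )
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError(f"voxel pitch must be positive, got {self.voxel_pitch}")
        present = np.unique(self.labels)
        missing = [int(sid) for sid in present if sid not in self.materials]
        if missing:
            raise ValueError(f"labels with no material row: {missing}")
        stray = self.tooth_instances[
            (self.tooth_instances != 0) & (self.labels != TOOTH_STRUCTURE_ID)
        ]
        if stray.size:
            raise ValueError(
                "tooth_instances nonzero outside tooth-labeled voxels "
                f"(instance IDs {sorted(set(int(v) for v in stray))})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def tooth_ids(self) -> list[int]:
        """Sorted anatomical IDs of teeth present in the phantom."""
        ids = np.unique(self.tooth_instances)
        return [int(i) for i in ids if i != 0]

    def tooth_mask(self, tooth_id: int) -> np.ndarray:
        if tooth_id not in self.tooth_ids():
            raise KeyError(f"tooth {tooth_id} not present; have {self.tooth_ids()}")
        return self.tooth_instances == tooth_id

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            labels=self.labels.copy(),
            tooth_instances=self.tooth_instances.copy(),
            voxel_pitch=self.voxel_pitch,
            materials=MaterialTable(self.materials.rows),
        )


# ---------------------------------------------------------------------------
# volume I/O (NIfTI via nibabel, MetaImage via SimpleITK)
# ---------------------------------------------------------------------------


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def _write_volume(array: np.ndarray, pitch: tuple[float, float, float], path: Path) -> None:
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag([pitch[0], pitch[1], pitch[2], 1.0])
        nib.save(nib.Nifti1Image(array.astype(np.int16), affine), str(path))
    elif path.suffix == ".mhd":
        import SimpleITK as sitk

        image = sitk.GetImageFromArray(np.ascontiguousarray(array.astype(np.int16).T))
        image.SetSpacing(tuple(float(p) for p in pitch))
        sitk.WriteImage(image, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name} (use .nii/.nii.gz/.mhd)")


def _read_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        pitch = tuple(float(z) for z in img.header.get_zooms()[:3])
        return np.asarray(img.dataobj).astype(np.int32), pitch
    if path.suffix == ".mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        array = sitk.GetArrayFromImage(img).T.astype(np.int32)
        return np.ascontiguousarray(array), tuple(float(s) for s in img.GetSpacing())
    raise ValueError(f"unsupported volume format: {path.name} (use .nii/.nii.gz/.mhd)")


def save_phantom(phantom: VoxelPhantom, label_path, material_path, instance_path=None) -> None:
    """Write labels (+ optional instances) and the material CSV."""
    label_path = Path(label_path)
    _write_volume(phantom.labels, phantom.voxel_pitch, label_path)
    phantom.materials.to_csv(material_path)
    if instance_path is not None:
        _write_volume(phantom.tooth_instances, phantom.voxel_pitch, Path(instance_path))


def load_phantom(label_path, material_path, instance_path=None, voxel_pitch=None) -> VoxelPhantom:
    """Load a phantom from a label volume, material CSV and optional instances.

    Pitch comes from the volume header unless ``voxel_pitch`` overrides it.
    Raises if any label lacks a material row or the instance grid mismatches.
    """
    labels, pitch = _read_volume(Path(label_path))
    if instance_path is not None:
        instances, _ = _read_volume(Path(instance_path))
    else:
        instances = np.zeros_like(labels)
    if voxel_pitch is not None:
        pitch = tuple(float(p) for p in np.broadcast_to(voxel_pitch, (3,)))
    return VoxelPhantom(
        labels=labels,
        tooth_instances=instances,
        voxel_pitch=pitch,
        materials=MaterialTable.from_csv(material_path),
    )


# ---------------------------------------------------------------------------
# synthetic jaw fixture
# ---------------------------------------------------------------------------


def build_synthetic_jaw(
    size: int | tuple[int, int, int] = 64,
    n_teeth: int = 4,
    seed: int = 0,
    voxel_pitch: float = 0.2,
    crown_radius: int | None = None,
) -> VoxelPhantom:
    """Procedural jaw-like fixture phantom (geometry, not anatomy).

    A soft-tissue block with a skin shell sits in air; a mandible slab
    (cortical shell, spongiosa core) crosses its lower half; ``n_teeth``
    disjoint teeth — ellipsoidal crowns on cylindrical roots — are planted
    along the slab with instance IDs 101, 102, ...  Deterministic per seed.

    ``crown_radius`` (voxels) sets the tooth size; the default scales with
    the grid.  At the 0.2 mm default pitch a realistic crown spans tens of
    voxels, so small grids should pass an explicit radius (fewer, larger
    teeth) when tooth-to-voxel scale matters.
    """
    shape = tuple(np.broadcast_to(size, (3,)).astype(int))
    if min(shape) < 32:
        raise ValueError(f"grid must be at least 32^3, got {shape}")
    if n_teeth < 1:
        raise ValueError("need at least one tooth")
    rng = np.random.default_rng(seed)

    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)
    instances = np.zeros(shape, dtype=np.int16)
    xs, ys, zs = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")

    # soft-tissue body with a 1-voxel skin shell, leaving an air margin
    margin = max(2, nx // 16)
    body = (
        (xs >= margin)
        & (xs < nx - margin)
        & (ys >= margin)
        & (ys < ny - margin)
        & (zs >= margin)
        & (zs < nz - margin)
    )
    labels[body] = 9  # skin shell, interior overwritten below
    interior = ndimage.binary_erosion(body, iterations=1)
    labels[interior] = 8

    # mandible slab across the lower third of the body
    slab_z0 = margin + 2
    slab_z1 = slab_z0 + max(4, nz // 5)
    slab = interior & (zs >= slab_z0) & (zs < slab_z1)
    labels[slab] = 3
    slab_core = ndimage.binary_erosion(slab, iterations=1)
    labels[slab_core] = 4

    # teeth: crowns above the slab, roots reaching into it
    crown_r = crown_radius if crown_radius is not None else max(2, min(nx, ny) // 16)
    spacing = 2 * crown_r + 2
    x_lo, x_hi = margin + crown_r + 1, nx - margin - crown_r - 1
    y_lo, y_hi = margin + crown_r + 1, ny - margin - crown_r - 1
    cols = max(0, (x_hi - x_lo) // spacing + 1)
    rows = max(0, (y_hi - y_lo) // spacing + 1)
    if n_teeth > cols * rows:
        raise ValueError(
            f"cannot pack {n_teeth} teeth of radius {crown_r} into grid {shape} "
            f"(capacity {cols * rows})"
        )
    crown_z = slab_z1 + crown_r  # crown centre just above the slab
    if crown_z + crown_r >= nz - margin:
        crown_z = nz - margin - crown_r - 1
    placed = 0
    for k in range(cols * rows):
        if placed >= n_teeth:
            break
        cx = x_lo + (k % cols) * spacing + rng.integers(-1, 2)
        cy = y_lo + (k // cols) * spacing + rng.integers(-1, 2)
        cx = int(np.clip(cx, x_lo, x_hi))
        cy = int(np.clip(cy, y_lo, y_hi))
        rz = crown_r + rng.integers(0, 2)
        crown = (
            ((xs - cx) / crown_r) ** 2
            + ((ys - cy) / crown_r) ** 2
            + ((zs - crown_z) / max(rz, 1)) ** 2
        ) <= 1.0
        root_r = max(1, crown_r // 2)
        root = (
            ((xs - cx) ** 2 + (ys - cy) ** 2 <= root_r**2)
            & (zs >= slab_z0 + 1)
            & (zs <= crown_z)
        )
        tooth = (crown | root) & (instances == 0)
        labels[tooth] = TOOTH_STRUCTURE_ID
        instances[tooth] = TOOTH_INSTANCE_MIN + placed
        placed += 1

    return VoxelPhantom(
        labels=labels,
        tooth_instances=instances,
        voxel_pitch=(voxel_pitch,) * 3,
        materials=reference_materials(),
    )


# ---------------------------------------------------------------------------
# phantom-library expansion
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DeformationSpec:
    """Per-axis rescale of one tooth about its centroid."""

    tooth_id: int
    scale: tuple[float, float, float]

    def __post_init__(self):
        if not (TOOTH_INSTANCE_MIN <= self.tooth_id <= TOOTH_INSTANCE_MAX):
            raise ValueError(f"tooth_id must be in 101-128, got {self.tooth_id}")
        if len(self.scale) != 3 or any(not (0.5 < s < 2.0) for s in self.scale):
            raise ValueError(f"scale factors must each be in (0.5, 2.0), got {self.scale}")


def _majority_fill(labels: np.ndarray, holes: np.ndarray, forbidden: np.ndarray) -> None:
    """Fill ``holes`` in-place with the 6-neighbourhood majority label.

    ``forbidden`` marks voxels whose labels must not be used as donors (the
    tooth being removed).  Iterates so fully enclosed holes fill from the
    outside in; any never-reachable remainder takes the global mode of the
    donor boundary.
    """
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    pending = holes.copy()
    max_label = int(labels.max()) + 1
    while pending.any():
        idx = np.argwhere(pending)
        counts = np.zeros((idx.shape[0], max_label), dtype=np.int32)
        for off in offsets:
            nbr = idx + np.array(off)
            valid = np.all((nbr >= 0) & (nbr < labels.shape), axis=1)
            donors = valid.copy()
            donors[valid] &= ~pending[tuple(nbr[valid].T)] & ~forbidden[tuple(nbr[valid].T)]
            if donors.any():
                lab = labels[tuple(nbr[donors].T)]
                counts[np.nonzero(donors)[0], lab] += 1
        has_donor = counts.sum(axis=1) > 0
        if not has_donor.any():
            # isolated region: use the most common non-forbidden label overall
            fallback = np.bincount(labels[~holes & ~forbidden].ravel()).argmax()
            labels[pending] = fallback
            return
        fill = counts[has_donor].argmax(axis=1)
        labels[tuple(idx[has_donor].T)] = fill
        pending[tuple(idx[has_donor].T)] = False


def deform_tooth(phantom: VoxelPhantom, spec: DeformationSpec) -> VoxelPhantom:
    """Rescale one tooth's mask about its centroid (nearest-neighbour).

    Voxels vacated by contraction are filled with the surrounding majority
    label; voxels claimed by expansion overwrite non-tooth labels only (other
    teeth are never touched).  Returns a new phantom.
    """
    old_mask = phantom.tooth_mask(spec.tooth_id)  # raises if absent
    centroid = np.array(ndimage.center_of_mass(old_mask))
    grid = np.indices(phantom.shape).reshape(3, -1).astype(float)
    # voxel v belongs to the scaled mask iff the pre-image point lies in the
    # original mask (pull-back nearest-neighbour resampling)
    src = centroid[:, None] + (grid - centroid[:, None]) / np.array(spec.scale)[:, None]
    src = np.rint(src).astype(int)
    inside = np.all((src >= 0) & (src < np.array(phantom.shape)[:, None]), axis=0)
    new_mask = np.zeros(phantom.shape, dtype=bool)
    flat = np.zeros(grid.shape[1], dtype=bool)
    flat[inside] = old_mask[tuple(src[:, inside])]
    new_mask = flat.reshape(phantom.shape)

    labels = phantom.labels.copy()
    instances = phantom.tooth_instances.copy()
    other_teeth = (instances != 0) & ~old_mask
    new_mask &= ~other_teeth  # expansion never claims another tooth

    vacated = old_mask & ~new_mask
    labels[vacated] = -1  # sentinel, filled below
    instances[vacated] = 0
    claimed = new_mask & ~old_mask
    labels[new_mask] = TOOTH_STRUCTURE_ID
    instances[new_mask] = spec.tooth_id
    del claimed

    holes = labels == -1
    if holes.any():
        _majority_fill(labels, holes, forbidden=new_mask)

    return VoxelPhantom(
        labels=labels,
        tooth_instances=instances,
        voxel_pitch=phantom.voxel_pitch,
        materials=MaterialTable(phantom.materials.rows),
    )


def vary_densities(phantom: VoxelPhantom, factors: dict[int, float]) -> VoxelPhantom:
    """Phantom with densities scaled per structure ID; grids untouched."""
    return VoxelPhantom(
        labels=phantom.labels,
        tooth_instances=phantom.tooth_instances,
        voxel_pitch=phantom.voxel_pitch,
        materials=phantom.materials.scaled_densities(factors),
    )
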