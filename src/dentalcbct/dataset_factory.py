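"""Turn phantom variants x scan conditions into a per-tooth training corpus.

The factory enumerates the Cartesian grid of phantom variants, density sets,
spectra, noise levels and cutoffs, runs the simulate -> reconstruct chain for
each condition, crops every tooth into a fixed-size cube with random margins
around its bounding box, and applies orientation augmentation from the
48-element group of axis permutations x per-axis flips.  Every sample is
recorded in a manifest with enough provenance to regenerate it bit-exactly
from the global seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import DeformationSpec, VoxelPhantom, deform_tooth, vary_densities
from .projector import ScanGeometry, add_noise, apply_cutoff, forward_project
from .recon import FilterSpec, ReconVolume, fdk_reconstruct
from .xray_physics import load_spectrum

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ConditionGrid:
    """The phantom x imaging-condition grid.

    ``phantoms`` holds one deformation recipe per phantom variant (an empty
    tuple is the undeformed base), ``density_sets`` one density-factor map
    per set, ``noise_levels`` photon counts I0 with ``None`` for noise-free,
    and ``cutoffs`` intensity-ratio floors with ``None`` for no cutoff.
    ``n_augmentations`` is the per-crop orientation/margin augmentation count.
    """

    phantoms: tuple[tuple[DeformationSpec, ...], ...]
    density_sets: tuple[dict, ...]
    spectra: tuple[str, ...]
    noise_levels: tuple[float | None, ...]
    cutoffs: tuple[float | None, ...]
    n_augmentations: int = 1

    def __post_init__(self):
        for name in ("phantoms", "density_sets", "spectra", "noise_levels", "cutoffs"):
            if len(getattr(self, name)) < 1:
                raise ValueError(f"{name} must have at least one entry")
        if self.n_augmentations < 1:
            raise ValueError("n_augmentations must be >= 1")

    @property
    def counts(self) -> tuple[int, int, int, int, int]:
        return (
            len(self.phantoms),
            len(self.density_sets),
            len(self.spectra),
            len(self.noise_levels),
            len(self.cutoffs),
        )

    @property
    def n_conditions(self) -> int:
        return int(np.prod(self.counts))


def default_condition_grid(n_augmentations: int = 50) -> ConditionGrid:
    """The study's default grid: 7 phantom variants (base plus six
    single-axis tooth expansions/contractions), 2 density sets, 3 spectra,
    3 noise levels (noise-free, I0 = 1e4, 1e5) and a single pass-through
    cutoff slot — 126 imaging conditions."""
    base: tuple[DeformationSpec, ...] = ()
    variants = [base]
    for axis in range(3):
        for factor in (1.15, 0.85):
            scale = [1.0, 1.0, 1.0]
            scale[axis] = factor
            variants.append((DeformationSpec(tooth_id=101, scale=tuple(scale)),))
    bone_tooth_ids = (1, 2, 3, 4, 5, 6, 10)
    density_sets = (
        {sid: 1.0 for sid in bone_tooth_ids},
        {sid: 1.05 for sid in bone_tooth_ids},
    )
    return ConditionGrid(
        phantoms=tuple(variants),
        density_sets=density_sets,
        spectra=("soft-90kVp", "hard-90kVp", "100kVp"),
        noise_levels=(None, 1e4, 1e5),
        cutoffs=(None,),
        n_augmentations=n_augmentations,
    )


Condition = tuple[int, int, str, float | None, float | None]


def enumerate_conditions(grid: ConditionGrid) -> list[Condition]:
    """Cartesian product (phantom, density, spectrum, noise, cutoff), ordered
    with phantom slowest and cutoff fastest."""
    return [
        (pi, di, spectrum, noise, cutoff)
        for pi in range(len(grid.phantoms))
        for di in range(len(grid.density_sets))
        for spectrum in grid.spectra
        for noise in grid.noise_levels
        for cutoff in grid.cutoffs
    ]


def count_samples(grid: ConditionGrid, teeth_per_phantom: int) -> int:
    """P*D*S*N*C * teeth * A without generating anything."""
    return grid.n_conditions * teeth_per_phantom * grid.n_augmentations


@dataclasses.dataclass
class ToothSample:
    """One cropped tooth: image cube, binary mask and provenance metadata."""

    image: np.ndarray
    mask: np.ndarray
    meta: dict

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} shapes differ"
            )
        if not self.mask.any():
            raise ValueError("tooth mask is empty")


def crop_tooth(
    vol: ReconVolume,
    phantom: VoxelPhantom,
    tooth_id: int,
    margin_range: tuple[int, int] = (2, 10),
    out_size: int = 128,
    seed: int = 0,
) -> ToothSample:
    """Crop one tooth from a reconstructed volume into an ``out_size`` cube.

    The tooth's instance-mask bounding box is expanded by per-face margins
    drawn uniformly from ``margin_range`` (seeded), clipped to the volume,
    then resampled: trilinear for the image, nearest-neighbour for the mask.
    """
    if vol.values.shape != phantom.shape:
        raise ValueError(
            f"volume grid {vol.values.shape} does not match phantom {phantom.shape}; "
            "crop requires a shared coordinate frame"
        )
    mask = phantom.tooth_mask(tooth_id)  # raises if absent
    rng = np.random.default_rng(seed)
    bbox = ndimage.find_objects(mask.astype(np.int8))[0]
    lo = np.array([s.start for s in bbox])
    hi = np.array([s.stop for s in bbox])
    margins = rng.integers(margin_range[0], margin_range[1] + 1, size=6)
    lo_m = lo - margins[:3]
    hi_m = hi + margins[3:]
    lo_c = np.maximum(lo_m, 0)
    hi_c = np.minimum(hi_m, np.array(phantom.shape))
    if np.any(lo_c != lo_m) or np.any(hi_c != hi_m):
        logger.info(
            "tooth %d crop box clipped to volume (wanted %s-%s)", tooth_id, lo_m, hi_m
        )
    # map output grid coordinates onto the crop box (voxel-centre aligned)
    coords = np.meshgrid(
        *[
            lo_c[a] + (np.arange(out_size) + 0.5) * (hi_c[a] - lo_c[a]) / out_size - 0.5
            for a in range(3)
        ],
        indexing="ij",
    )
    coords = np.stack(coords)
    image = ndimage.map_coordinates(vol.values, coords, order=1, mode="nearest")
    mask_out = ndimage.map_coordinates(
        mask.astype(np.uint8), coords, order=0, mode="constant"
    ).astype(bool)
    return ToothSample(
        image=image,
        mask=mask_out,
        meta={
            "tooth_id": int(tooth_id),
            "crop_lo": lo_c.tolist(),
            "crop_hi": hi_c.tolist(),
            "margins": margins.tolist(),
            "out_size": int(out_size),
            "crop_seed": int(seed),
            "orientation": None,
        },
    )


def orientation_group() -> list[tuple[tuple[int, int, int], tuple[bool, bool, bool]]]:
    """The 48 (axis permutation, per-axis flip) orientation transforms,
    identity first."""
    perms = list(itertools.permutations((0, 1, 2)))
    flips = list(itertools.product((False, True), repeat=3))
    group = [(p, f) for p in perms for f in flips]
    group.remove(((0, 1, 2), (False, False, False)))
    return [((0, 1, 2), (False, False, False))] + group


def apply_orientation(
    array: np.ndarray, perm: tuple[int, int, int], flips: tuple[bool, bool, bool]
) -> np.ndarray:
    out = np.transpose(array, perm)
    axes = tuple(a for a, f in enumerate(flips) if f)
    return np.flip(out, axis=axes) if axes else out


def augment_orientations(sample: ToothSample, n: int, seed: int = 0) -> list[ToothSample]:
    """``n`` distinct orientation transforms of one sample (identity first,
    remaining transforms drawn without replacement, seeded)."""
    group = orientation_group()
    if n > len(group):
        raise ValueError(f"at most {len(group)} distinct orientations, asked for {n}")
    rng = np.random.default_rng(seed)
    order = [0] + list(1 + rng.permutation(len(group) - 1))[: n - 1]
    out = []
    for g in order[:n]:
        perm, flips = group[g]
        meta = dict(sample.meta)
        meta["orientation"] = {"perm": list(perm), "flips": list(flips)}
        out.append(
            ToothSample(
                image=apply_orientation(sample.image, perm, flips),
                mask=apply_orientation(sample.mask, perm, flips),
                meta=meta,
            )
        )
    return out


def _condition_phantom(
    base: VoxelPhantom, grid: ConditionGrid, phantom_idx: int, density_idx: int
) -> VoxelPhantom:
    phantom = base
    for spec in grid.phantoms[phantom_idx]:
        phantom = deform_tooth(phantom, spec)
    factors = grid.density_sets[density_idx]
    if factors:
        phantom = vary_densities(phantom, factors)
    return phantom


def generate_dataset(
    grid: ConditionGrid,
    base_phantom: VoxelPhantom,
    geometry: ScanGeometry,
    out_dir: str | Path,
    seed: int = 0,
    crop_size: int = 128,
    margin_range: tuple[int, int] = (2, 10),
    recon_filter: FilterSpec | None = None,
    median_filter: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Generate the full corpus: one HDF5 shard per condition plus a manifest.

    Resumable: shards whose ``complete`` attribute is set are skipped and
    their manifest rows reused.  Conditions whose simulation fails are marked
    ``status=failed`` in the manifest and the run continues.

    When ``n_augmentations`` exceeds the 48 distinct orientations, the
    surplus draws re-sample the crop margins (seeded) so samples stay
    distinct.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conditions = enumerate_conditions(grid)
    group = orientation_group()
    rows: list[dict] = []

    cond_iter = list(enumerate(conditions))
    if progress:
        from tqdm import tqdm

        cond_iter = tqdm(cond_iter, desc="conditions")
    for ci, (pi, di, spectrum_label, noise, cutoff) in cond_iter:
        shard = out_dir / f"cond_{ci:04d}.h5"
        cond_meta = {
            "condition_index": ci,
            "phantom_variant": pi,
            "density_set": di,
            "spectrum": spectrum_label,
            "noise_I0": noise,
            "cutoff": cutoff,
        }
        if shard.exists():
            with h5py.File(shard, "r") as fh:
                if fh.attrs.get("complete", False):
                    rows.extend(json.loads(fh.attrs["manifest_rows"]))
                    continue
            shard.unlink()  # partial shard from an interrupted run
        try:
            phantom = _condition_phantom(base_phantom, grid, pi, di)
            stack = forward_project(phantom, load_spectrum(spectrum_label), geometry)
            cond_seed = np.random.SeedSequence([seed, ci]).generate_state(1)[0] % (2**31)
            if noise is not None:
                stack = add_noise(stack, noise, seed=int(cond_seed))
            if cutoff is not None:
                stack = apply_cutoff(stack, cutoff)
            vol = fdk_reconstruct(
                stack,
                recon_filter,
                out_shape=phantom.shape,
                out_pitch=phantom.voxel_pitch,
                median_filter=median_filter,
            )
        except Exception:
            logger.exception("condition %d failed", ci)
            rows.append({**cond_meta, "status": "failed"})
            continue

        shard_rows: list[dict] = []
        images, masks = [], []
        for tooth_id in phantom.tooth_ids():
            tooth_seq = np.random.SeedSequence([seed, ci, tooth_id])
            crop_seeds = tooth_seq.generate_state(1 + grid.n_augmentations // len(group))
            orient_seed = int(tooth_seq.generate_state(2)[1] % (2**31))
            crops: dict[int, ToothSample] = {}
            for a in range(grid.n_augmentations):
                redraw = a // len(group)
                if redraw not in crops:
                    crops[redraw] = crop_tooth(
                        vol,
                        phantom,
                        tooth_id,
                        margin_range=margin_range,
                        out_size=crop_size,
                        seed=int(crop_seeds[redraw] % (2**31)),
                    )
                g = a % len(group)
                if g == 0 and a > 0:
                    pass  # new margin redraw restarts the orientation cycle
                aug = augment_orientations(crops[redraw], g + 1, seed=orient_seed)[g]
                index = len(images)
                images.append(aug.image)
                masks.append(aug.mask.astype(np.uint8))
                shard_rows.append(
                    {
                        **cond_meta,
                        "status": "ok",
                        "sample_id": f"c{ci:04d}_t{tooth_id}_a{a:03d}",
                        "file": shard.name,
                        "index_in_shard": index,
                        "tooth_id": int(tooth_id),
                        "augmentation": a,
                        "orientation": json.dumps(aug.meta["orientation"]),
                        "crop_lo": json.dumps(aug.meta["crop_lo"]),
                        "crop_hi": json.dumps(aug.meta["crop_hi"]),
                        "crop_seed": aug.meta["crop_seed"],
                        "orient_seed": orient_seed,
                    }
                )

        with h5py.File(shard, "w") as fh:
            fh.create_dataset("image", data=np.stack(images), compression="gzip")
            fh.create_dataset("mask", data=np.stack(masks), compression="gzip")
            fh.attrs["condition"] = json.dumps(cond_meta)
            fh.attrs["manifest_rows"] = json.dumps(shard_rows)
            fh.attrs["complete"] = True
        rows.extend(shard_rows)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps(
            {
                "seed": seed,
                "counts": grid.counts,
                "n_augmentations": grid.n_augmentations,
                "crop_size": crop_size,
                "margin_range": list(margin_range),
                "geometry": dataclasses.asdict(geometry),
            },
            indent=2,
        )
    )
    return manifest


def export_sample_nifti(sample: ToothSample, path, pitch_mm: float = 0.2) -> None:
    """Write one sample's image and mask as NIfTI files for inspection."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([pitch_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(sample.image, affine), str(path))
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    nib.save(
        nib.Nifti1Image(sample.mask.astype(np.uint8), affine),
        str(path.with_name(stem + ".mask.nii.gz")),
    )
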