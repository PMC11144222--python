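"""Shared fixtures: small phantoms, scaled scan geometry, and a generated
fixture corpus reused by the dataset and segmentation tests."""

from __future__ import annotations

import numpy as np
import pytest

from dentalcbct.dataset_factory import ConditionGrid, count_samples, generate_dataset
from dentalcbct.phantom import (
    VoxelPhantom,
    build_synthetic_jaw,
    reference_materials,
)
from dentalcbct.projector import ScanGeometry, forward_project
from dentalcbct.recon import fdk_reconstruct
from dentalcbct.xray_physics import load_spectrum


@pytest.fixture(scope="session")
def materials():
    return reference_materials()


@pytest.fixture(scope="session")
def jaw_phantom():
    """64^3 synthetic jaw with three teeth (0.2 mm pitch)."""
    return build_synthetic_jaw(size=64, n_teeth=3, seed=1)


@pytest.fixture(scope="session")
def corpus_phantom():
    """64^3 jaw with two realistically proportioned teeth (10-voxel crowns)."""
    return build_synthetic_jaw(size=64, n_teeth=2, seed=1, crown_radius=10)


@pytest.fixture(scope="session")
def corpus_geometry():
    """Corpus-generation geometry: 90 views keep aliasing blur mild."""
    return ScanGeometry(
        detector_cols=128,
        detector_rows=64,
        detector_pitch=0.4,
        n_projections=90,
        angular_step=4.0,
    )


@pytest.fixture(scope="session")
def scaled_geometry():
    """Desk-scale scan geometry: 128x64 detector, 60 views over 360 deg."""
    return ScanGeometry(
        detector_cols=128,
        detector_rows=64,
        detector_pitch=0.4,
        n_projections=60,
        angular_step=6.0,
    )


def make_cylinder_phantom(
    materials, structure_id=8, radius_cm=2.0, n=96, nz=32, pitch_mm=0.5
) -> VoxelPhantom:
    """Homogeneous axial cylinder of one material in air."""
    labels = np.zeros((n, n, nz), dtype=np.int16)
    x, y = np.meshgrid(*(np.arange(s) - (s - 1) / 2 for s in (n, n)), indexing="ij")
    r_cm = np.sqrt(x**2 + y**2) * pitch_mm / 10.0
    labels[r_cm <= radius_cm] = structure_id
    return VoxelPhantom(
        labels=labels,
        tooth_instances=np.zeros_like(labels),
        voxel_pitch=(pitch_mm,) * 3,
        materials=materials,
    )


@pytest.fixture(scope="session")
def cylinder_geometry():
    return ScanGeometry(
        detector_cols=160,
        detector_rows=80,
        detector_pitch=1.0,
        n_projections=90,
        angular_step=4.0,
    )


@pytest.fixture(scope="session")
def cylinder_recon(materials, cylinder_geometry):
    """(phantom, stack, volume) for the 2-cm tissue cylinder at mono-60."""
    phantom = make_cylinder_phantom(materials)
    stack = forward_project(phantom, load_spectrum("mono-60"), cylinder_geometry)
    volume = fdk_reconstruct(stack, out_shape=(96, 96, 32), out_pitch=0.5)
    return phantom, stack, volume


@pytest.fixture(scope="session")
def mini_grid():
    """Miniature condition grid: 2 phantom variants x 2 noise levels."""
    from dentalcbct.phantom import DeformationSpec

    return ConditionGrid(
        phantoms=((), (DeformationSpec(tooth_id=101, scale=(1.15, 1.0, 1.0)),)),
        density_sets=({},),
        spectra=("hard-90kVp",),
        noise_levels=(None, 1e5),
        cutoffs=(None,),
        n_augmentations=8,
    )


@pytest.fixture(scope="session")
def fixture_corpus(tmp_path_factory, corpus_phantom, corpus_geometry, mini_grid):
    """Generated corpus for the miniature grid (64^3 recon, 32^3 crops)."""
    out = tmp_path_factory.mktemp("corpus")
    manifest = generate_dataset(
        mini_grid,
        corpus_phantom,
        corpus_geometry,
        out,
        seed=7,
        crop_size=32,
        margin_range=(2, 5),
    )
    expected = count_samples(mini_grid, len(corpus_phantom.tooth_ids()))
    assert len(manifest) == expected
    return out, manifest
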