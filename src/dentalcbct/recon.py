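"""FDK cone-beam reconstruction with a windowed ramp filter.

The pipeline is the standard Feldkamp-Davis-Kress chain for a circular
full scan on a flat detector: per-pixel cosine weighting of the line
integrals ``y = -ln(I/I_0)``, row-wise frequency-domain filtering with a
windowed ramp (generalized-Hamming apodization with window parameter
``alpha``, frequency-scale ``gamma`` and a hard cutoff at ``W`` times the
Nyquist frequency; the alpha=0.54 default is Hamming-style), and
distance-weighted voxel-driven backprojection with bilinear detector
interpolation.  Values come out as effective linear attenuation in 1/cm at
the spectrum's effective energy; no Hounsfield conversion is applied.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .projector import ProjectionStack, line_integrals

NYQUIST = 0.5  # cycles per sample


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Windowed ramp filter parameters (defaults alpha=0.54, gamma=1.0, W=0.8)."""

    alpha: float = 0.54
    gamma: float = 1.0
    W: float = 0.8

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (0.0 < self.W <= 1.0):
            raise ValueError(f"W must be in (0, 1], got {self.W}")


@dataclasses.dataclass
class ReconVolume:
    """Reconstructed attenuation grid [1/cm] with provenance metadata."""

    values: np.ndarray  # 3-D, finite
    voxel_pitch: tuple[float, float, float]  # mm
    provenance: dict

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstructed values must be finite")
        self.voxel_pitch = tuple(float(p) for p in self.voxel_pitch)
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError("voxel pitch must be positive")

    def save_nifti(self, path) -> None:
        """Write the volume as NIfTI-1 with a JSON provenance sidecar."""
        import nibabel as nib

        path = Path(path)
        affine = np.diag([*self.voxel_pitch, 1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        sidecar = path.with_name(stem + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, default=str))


def ramp_window(freqs, spec: FilterSpec) -> np.ndarray:
    """Windowed ramp magnitude at ``freqs`` (cycles/sample, within +-Nyquist).

    H(nu) = |nu| * [alpha + (1-alpha) cos(pi nu / (gamma nu_N))] for
    |nu| <= W * nu_N, zero beyond; even, and zero at DC.
    """
    nu = np.asarray(freqs, dtype=float)
    window = spec.alpha + (1.0 - spec.alpha) * np.cos(np.pi * nu / (spec.gamma * NYQUIST))
    h = np.abs(nu) * window
    h[np.abs(nu) > spec.W * NYQUIST + 1e-12] = 0.0
    return h


def _filter_rows(weighted: np.ndarray, pitch_iso_cm: float, spec: FilterSpec) -> np.ndarray:
    """Ramp-filter each detector row (last axis) in the frequency domain.

    Zero-pads to the next power of two >= 2*cols so the circular FFT product
    realizes a linear convolution; divides by the (isocenter-scaled) sample
    pitch so the output carries 1/cm.
    """
    cols = weighted.shape[-1]
    n = 1 << int(np.ceil(np.log2(2 * cols)))
    freqs = np.fft.fftfreq(n)  # cycles per sample
    h = ramp_window(freqs, spec)
    spectrum = np.fft.fft(weighted, n=n, axis=-1)
    filtered = np.fft.ifft(spectrum * h, axis=-1).real[..., :cols]
    return filtered / pitch_iso_cm


def fdk_reconstruct(
    stack: ProjectionStack,
    filter_spec: FilterSpec | None = None,
    out_shape: tuple[int, int, int] = (128, 128, 64),
    out_pitch: float | tuple[float, float, float] = 0.2,
    median_filter: bool = False,
    progress: bool = False,
) -> ReconVolume:
    """Feldkamp-Davis-Kress reconstruction of a full circular scan.

    ``out_shape``/``out_pitch`` (mm) define the reconstruction grid, centred
    on the isocenter with z along the rotation axis.
    """
    filter_spec = filter_spec or FilterSpec()
    geom = stack.geometry
    if geom.n_projections * geom.angular_step < 360.0 - 1e-6:
        raise ValueError(
            "FDK needs full 360 degree coverage; got "
            f"{geom.n_projections} x {geom.angular_step} deg"
        )
    pitch = tuple(float(p) for p in np.broadcast_to(out_pitch, (3,)))
    nx, ny, nz = out_shape

    R = geom.source_to_isocenter
    D = geom.source_to_detector
    mag = R / D
    pitch_det_cm = geom.detector_pitch / 10.0
    pitch_iso = pitch_det_cm * mag  # detector pitch rescaled to the isocenter plane

    y = line_integrals(stack)  # [n_angles, rows, cols]
    rows, cols = geom.detector_rows, geom.detector_cols
    u = (np.arange(cols) - (cols - 1) / 2.0) * pitch_iso
    v = (np.arange(rows) - (rows - 1) / 2.0) * pitch_iso
    cosw = R / np.sqrt(R**2 + u[None, :] ** 2 + v[:, None] ** 2)

    # voxel centre world coordinates (cm), grid centred at the isocenter
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pitch[0] / 10.0
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pitch[1] / 10.0
    zs = (np.arange(nz) - (nz - 1) / 2.0) * pitch[2] / 10.0
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    volume = np.zeros((nx, ny, nz))
    angle_iter = enumerate(np.deg2rad(geom.angles_deg))
    if progress:
        from tqdm import tqdm

        angle_iter = tqdm(list(angle_iter), desc="FDK backproject")
    for k, beta in angle_iter:
        q = _filter_rows(cosw * y[k], pitch_iso, filter_spec)  # [rows, cols]
        s = gx * np.cos(beta) + gy * np.sin(beta)  # toward the source
        t = -gx * np.sin(beta) + gy * np.cos(beta)  # along detector u
        inv_l = R / (R - s)  # magnification onto the isocenter plane
        col_f = (t * inv_l) / pitch_iso + (cols - 1) / 2.0  # [nx, ny]
        weight = inv_l**2
        # v' = z * inv_l: separable in z, so broadcast over the z axis
        row_f = (zs[None, None, :] * inv_l[..., None]) / pitch_iso + (rows - 1) / 2.0
        c0 = np.floor(col_f).astype(np.int64)
        r0 = np.floor(row_f).astype(np.int64)
        fc = col_f - c0
        fr = row_f - r0
        valid_c = (c0 >= 0) & (c0 < cols - 1)
        valid_r = (r0 >= 0) & (r0 < rows - 1)
        c0c = np.clip(c0, 0, cols - 2)
        r0c = np.clip(r0, 0, rows - 2)
        flat = q.ravel()
        base = r0c * cols + c0c[..., None]
        sample = (
            flat[base] * (1 - fr) * (1 - fc[..., None])
            + flat[base + 1] * (1 - fr) * fc[..., None]
            + flat[base + cols] * fr * (1 - fc[..., None])
            + flat[base + cols + 1] * fr * fc[..., None]
        )
        sample *= valid_r & valid_c[..., None]
        volume += weight[..., None] * sample

    # full-scan normalization: each plane integral is measured twice over 2*pi
    volume *= np.deg2rad(geom.angular_step) / 2.0

    provenance = {
        "geometry": dataclasses.asdict(geom),
        "filter": dataclasses.asdict(filter_spec),
        "conditions": stack.meta,
        "out_shape": list(out_shape),
        "out_pitch_mm": list(pitch),
        "median_filter": bool(median_filter),
    }
    vol = ReconVolume(values=volume, voxel_pitch=pitch, provenance=provenance)
    if median_filter:
        vol = median_filter_3x3(vol)
    return vol


def median_filter_3x3(vol: ReconVolume, three_d: bool = False) -> ReconVolume:
    """3x3 spatial median per axial (z) slice, edge-replicated.

    ``three_d=True`` switches to a full 3x3x3 median.
    """
    size = (3, 3, 3) if three_d else (3, 3, 1)
    filtered = ndimage.median_filter(vol.values, size=size, mode="nearest")
    provenance = dict(vol.provenance)
    provenance["median_filter"] = "3x3x3" if three_d else "3x3"
    return ReconVolume(values=filtered, voxel_pitch=vol.voxel_pitch, provenance=provenance)
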