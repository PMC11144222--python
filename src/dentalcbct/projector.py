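"""Cone-beam geometry, ray tracing and polychromatic forward projection.

The forward model computes, for detector pixel *i*,

    I_i / I_0 = sum_E alpha(E) n0(E) exp(-sum_j a_ij mu_j(E)) / sum_E alpha(E) n0(E)

where ``a_ij`` are exact voxel intersection lengths along the source-to-pixel
segment (incremental parametric / Siddon traversal) and ``mu_j(E)`` the voxel
material's linear attenuation.  Because ``mu_j`` depends on the voxel only
through its structure label, each ray is reduced to a per-label path-length
vector and the energy sum becomes a dense matrix product — the
material-based forward projection in its natural factored form.

Photon noise follows the intensity-domain model ``I* = I + z sqrt(I)`` with
standard-normal ``z`` (a Gaussian approximation of Poisson counting noise at
mean I), and the limited detector dynamic range is emulated by clamping
intensity ratios below a cutoff ``c``.
"""

from __future__ import annotations

import dataclasses
import logging

import numba
import numpy as np

from .phantom import VoxelPhantom
from .xray_physics import Spectrum, mu_by_label

logger = logging.getLogger(__name__)

RATIO_FLOOR = 1e-6  # positive floor applied after noise, before any log


@dataclasses.dataclass(frozen=True)
class ScanGeometry:
    """Circular cone-beam scan geometry (rotation about the volume z-axis).

    Angle convention: projection k is taken at ``k * angular_step`` degrees,
    counterclockwise about +z viewed from above, with the source on the +x
    axis at angle 0.  Distances in cm, detector pitch in mm.
    """

    source_to_isocenter: float = 30.0
    source_to_detector: float = 55.0
    detector_cols: int = 2000
    detector_rows: int = 1000
    detector_pitch: float = 0.2
    n_projections: int = 360
    angular_step: float = 1.0

    def __post_init__(self):
        if not (self.source_to_detector > self.source_to_isocenter > 0):
            raise ValueError(
                "need source_to_detector > source_to_isocenter > 0, got "
                f"{self.source_to_detector}, {self.source_to_isocenter}"
            )
        if self.detector_cols < 1 or self.detector_rows < 1 or self.detector_pitch <= 0:
            raise ValueError("detector must have positive pixel counts and pitch")
        if self.n_projections < 1 or self.angular_step <= 0:
            raise ValueError("need at least one projection and a positive angular step")

    @property
    def is_full_scan(self) -> bool:
        return abs(self.n_projections * self.angular_step - 360.0) < 1e-6

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_projections) * self.angular_step

    @property
    def magnification(self) -> float:
        return self.source_to_detector / self.source_to_isocenter

    def pixel_position(self, angle_deg: float, row: int, col: int) -> np.ndarray:
        """World position (cm) of a detector pixel centre."""
        theta = np.deg2rad(angle_deg)
        e_r = np.array([np.cos(theta), np.sin(theta), 0.0])
        e_u = np.array([-np.sin(theta), np.cos(theta), 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        pitch_cm = self.detector_pitch / 10.0
        u = (col - (self.detector_cols - 1) / 2.0) * pitch_cm
        v = (row - (self.detector_rows - 1) / 2.0) * pitch_cm
        center = (self.source_to_isocenter - self.source_to_detector) * e_r
        return center + u * e_u + v * e_v

    def source_position(self, angle_deg: float) -> np.ndarray:
        theta = np.deg2rad(angle_deg)
        return self.source_to_isocenter * np.array([np.cos(theta), np.sin(theta), 0.0])


@dataclasses.dataclass
class ProjectionStack:
    """Per-angle detector intensity ratios I_i/I_0 with full provenance."""

    ratios: np.ndarray  # [n_angles, rows, cols], in (0, 1] before noise
    geometry: ScanGeometry
    meta: dict

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=np.float64)
        if self.ratios.ndim != 3:
            raise ValueError("ratios must be [n_angles, rows, cols]")
        if np.any(self.ratios <= 0):
            raise ValueError("ratios must be strictly positive")

    @property
    def noise_applied(self) -> bool:
        return self.meta.get("noise_I0") is not None

    def replace(self, ratios: np.ndarray, **meta_updates) -> "ProjectionStack":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return ProjectionStack(ratios=ratios, geometry=self.geometry, meta=meta)

    def save_h5(self, path) -> None:
        import h5py
        import json

        with h5py.File(path, "w") as fh:
            fh.create_dataset("ratios", data=self.ratios, compression="gzip")
            fh.attrs["geometry"] = json.dumps(dataclasses.asdict(self.geometry))
            fh.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load_h5(cls, path) -> "ProjectionStack":
        import h5py
        import json

        with h5py.File(path, "r") as fh:
            ratios = fh["ratios"][...]
            geometry = ScanGeometry(**json.loads(fh.attrs["geometry"]))
            meta = json.loads(fh.attrs["meta"])
        return cls(ratios=ratios, geometry=geometry, meta=meta)


@dataclasses.dataclass(frozen=True)
class RayPath:
    """Ordered voxel indices with exact intersection lengths (cm)."""

    voxel_indices: np.ndarray  # [n, 3] int
    lengths: np.ndarray  # [n] cm, all >= 0

    @property
    def chord_length(self) -> float:
        return float(self.lengths.sum())


def _grid_frame(phantom: VoxelPhantom) -> tuple[np.ndarray, np.ndarray]:
    """(origin corner, pitch) of the volume in cm, centred at the isocenter."""
    pitch_cm = np.asarray(phantom.voxel_pitch, dtype=np.float64) / 10.0
    dims = np.asarray(phantom.shape, dtype=np.float64)
    origin = -dims * pitch_cm / 2.0
    return origin, pitch_cm


@numba.njit(cache=True)
def _traverse(src, direction, t_stop, origin, pitch, dims, out_idx, out_len):
    """Siddon/Amanatides-Woo traversal of one ray; returns step count.

    Records every voxel crossed by the segment src + t*direction for
    t in [0, t_stop], with exact intersection lengths.
    """
    tmin = 0.0
    tmax = t_stop
    for a in range(3):
        d = direction[a]
        lo = origin[a]
        hi = origin[a] + dims[a] * pitch[a]
        if abs(d) < 1e-12:
            if src[a] <= lo or src[a] >= hi:
                return 0
        else:
            t0 = (lo - src[a]) / d
            t1 = (hi - src[a]) / d
            if t0 > t1:
                t0, t1 = t1, t0
            if t0 > tmin:
                tmin = t0
            if t1 < tmax:
                tmax = t1
    if tmax <= tmin:
        return 0

    ix = np.empty(3, dtype=np.int64)
    step = np.empty(3, dtype=np.int64)
    t_next = np.empty(3, dtype=np.float64)
    dt = np.empty(3, dtype=np.float64)
    eps = 1e-10 * (tmax - tmin)
    for a in range(3):
        pos = src[a] + (tmin + eps) * direction[a]
        i = int(np.floor((pos - origin[a]) / pitch[a]))
        if i < 0:
            i = 0
        if i >= dims[a]:
            i = dims[a] - 1
        ix[a] = i
        d = direction[a]
        if abs(d) < 1e-12:
            step[a] = 0
            t_next[a] = 1e300
            dt[a] = 1e300
        elif d > 0:
            step[a] = 1
            t_next[a] = (origin[a] + (i + 1) * pitch[a] - src[a]) / d
            dt[a] = pitch[a] / d
        else:
            step[a] = -1
            t_next[a] = (origin[a] + i * pitch[a] - src[a]) / d
            dt[a] = -pitch[a] / d

    t = tmin
    n = 0
    while t < tmax - 1e-12:
        a = 0
        if t_next[1] < t_next[a]:
            a = 1
        if t_next[2] < t_next[a]:
            a = 2
        t_exit = t_next[a]
        if t_exit > tmax:
            t_exit = tmax
        seg = t_exit - t
        if seg > 0:
            out_idx[n, 0] = ix[0]
            out_idx[n, 1] = ix[1]
            out_idx[n, 2] = ix[2]
            out_len[n] = seg
            n += 1
        t = t_exit
        ix[a] += step[a]
        if ix[a] < 0 or ix[a] >= dims[a]:
            break
        t_next[a] += dt[a]
    return n


@numba.njit(cache=True, parallel=False)
def _accumulate_label_lengths(
    labels, label_lut, n_materials, src, directions, origin, pitch, dims
):
    """Per-ray path length within each material label [n_rays, n_materials]."""
    n_rays = directions.shape[0]
    out = np.zeros((n_rays, n_materials), dtype=np.float64)
    max_steps = int(dims[0] + dims[1] + dims[2] + 4)
    idx_buf = np.empty((max_steps, 3), dtype=np.int64)
    len_buf = np.empty(max_steps, dtype=np.float64)
    for r in range(n_rays):
        n = _traverse(
            src, directions[r], 1e300, origin, pitch, dims, idx_buf, len_buf
        )
        for s in range(n):
            lab = labels[idx_buf[s, 0], idx_buf[s, 1], idx_buf[s, 2]]
            m = label_lut[lab]
            out[r, m] += len_buf[s]
    return out


def trace_ray(
    geometry: ScanGeometry,
    angle_deg: float,
    row: int,
    col: int,
    grid_shape: tuple[int, int, int],
    voxel_pitch,
) -> RayPath:
    """Exact voxel intersection lengths along source -> detector pixel."""
    if not (0 <= row < geometry.detector_rows and 0 <= col < geometry.detector_cols):
        raise ValueError(f"pixel ({row}, {col}) outside detector")
    pitch_cm = np.broadcast_to(np.asarray(voxel_pitch, dtype=float), (3,)) / 10.0
    if np.any(pitch_cm <= 0):
        raise ValueError("voxel pitch must be positive")
    dims = np.asarray(grid_shape, dtype=np.int64)
    origin = -dims * pitch_cm / 2.0
    src = geometry.source_position(angle_deg)
    pixel = geometry.pixel_position(angle_deg, row, col)
    direction = pixel - src
    direction = direction / np.linalg.norm(direction)
    max_steps = int(dims.sum() + 4)
    idx_buf = np.empty((max_steps, 3), dtype=np.int64)
    len_buf = np.empty(max_steps, dtype=np.float64)
    n = _traverse(
        src.astype(np.float64),
        direction.astype(np.float64),
        1e300,
        origin.astype(np.float64),
        np.ascontiguousarray(pitch_cm),
        dims,
        idx_buf,
        len_buf,
    )
    return RayPath(voxel_indices=idx_buf[:n].copy(), lengths=len_buf[:n].copy())


def _detector_directions(geometry: ScanGeometry, angle_deg: float) -> np.ndarray:
    """Unit source->pixel directions for every detector pixel [rows*cols, 3]."""
    theta = np.deg2rad(angle_deg)
    e_r = np.array([np.cos(theta), np.sin(theta), 0.0])
    e_u = np.array([-np.sin(theta), np.cos(theta), 0.0])
    e_v = np.array([0.0, 0.0, 1.0])
    pitch_cm = geometry.detector_pitch / 10.0
    u = (np.arange(geometry.detector_cols) - (geometry.detector_cols - 1) / 2.0) * pitch_cm
    v = (np.arange(geometry.detector_rows) - (geometry.detector_rows - 1) / 2.0) * pitch_cm
    uu, vv = np.meshgrid(u, v)  # [rows, cols]
    center = (geometry.source_to_isocenter - geometry.source_to_detector) * e_r
    src = geometry.source_to_isocenter * e_r
    pixels = (
        center[None, None, :]
        + uu[..., None] * e_u[None, None, :]
        + vv[..., None] * e_v[None, None, :]
    )
    directions = pixels - src[None, None, :]
    directions /= np.linalg.norm(directions, axis=-1, keepdims=True)
    return directions.reshape(-1, 3)


def forward_project(
    phantom: VoxelPhantom,
    spectrum: Spectrum,
    geometry: ScanGeometry,
    progress: bool = False,
) -> ProjectionStack:
    """Polychromatic forward projection of a phantom (noise-free ratios)."""
    spectrum = spectrum.normalized()
    active = spectrum.weights > 0
    energies = spectrum.energies[active]
    weights = spectrum.weights[active]
    label_ids, mu = mu_by_label(phantom, energies)  # [n_mats, nE], 1/cm
    lut = np.full(int(label_ids.max()) + 1, -1, dtype=np.int64)
    lut[label_ids] = np.arange(label_ids.size)
    origin, pitch_cm = _grid_frame(phantom)
    dims = np.asarray(phantom.shape, dtype=np.int64)
    labels = np.ascontiguousarray(phantom.labels.astype(np.int64))

    n_angles = geometry.n_projections
    ratios = np.empty((n_angles, geometry.detector_rows, geometry.detector_cols))
    angle_iter = enumerate(geometry.angles_deg)
    if progress:
        from tqdm import tqdm

        angle_iter = tqdm(list(angle_iter), desc="forward project")
    for k, angle in angle_iter:
        src = geometry.source_position(angle).astype(np.float64)
        directions = _detector_directions(geometry, angle)
        lengths = _accumulate_label_lengths(
            labels, lut, label_ids.size, src, directions, origin, pitch_cm, dims
        )
        y = lengths @ mu  # [n_rays, nE]
        ratio = np.exp(-y) @ weights
        if not np.all(np.isfinite(ratio)):
            bad = np.argwhere(~np.isfinite(ratio))[0]
            raise FloatingPointError(
                f"non-finite intensity ratio at angle {angle} deg, pixel {bad}"
            )
        ratios[k] = ratio.reshape(geometry.detector_rows, geometry.detector_cols)
    return ProjectionStack(
        ratios=ratios,
        geometry=geometry,
        meta={
            "spectrum": spectrum.label,
            "noise_I0": None,
            "noise_seed": None,
            "cutoff": None,
            "transforms": ["forward_project"],
        },
    )


def add_noise(stack: ProjectionStack, I0: float, seed: int) -> ProjectionStack:
    """Inject photon noise: I* = I + z*sqrt(I), I = I0 * ratio, z ~ N(0,1).

    Single-shot: raises if the stack already carries noise.  Returned ratios
    are I*/I0 floored at a small positive value (the floored-pixel count is
    logged and recorded in the metadata).
    """
    if I0 <= 0:
        raise ValueError(f"I0 must be positive, got {I0}")
    if stack.noise_applied:
        raise ValueError("noise has already been applied to this stack")
    rng = np.random.default_rng(seed)
    intensity = I0 * stack.ratios
    noisy = intensity + rng.standard_normal(intensity.shape) * np.sqrt(intensity)
    ratios = noisy / I0
    n_floored = int(np.count_nonzero(ratios < RATIO_FLOOR))
    if n_floored:
        logger.info("floored %d nonpositive/low pixels at %g", n_floored, RATIO_FLOOR)
    ratios = np.maximum(ratios, RATIO_FLOOR)
    return stack.replace(
        ratios,
        noise_I0=float(I0),
        noise_seed=int(seed),
        n_floored=n_floored,
        transforms=stack.meta["transforms"] + ["add_noise"],
    )


def apply_cutoff(stack: ProjectionStack, c: float) -> ProjectionStack:
    """Clamp intensity ratios below the cutoff c (idempotent)."""
    if not (0.0 < c < 1.0):
        raise ValueError(f"cutoff must be in (0, 1), got {c}")
    ratios = np.maximum(stack.ratios, c)
    return stack.replace(
        ratios,
        cutoff=float(c),
        transforms=stack.meta["transforms"] + ["apply_cutoff"],
    )


def line_integrals(stack: ProjectionStack) -> np.ndarray:
    """Per-pixel line integrals y_i = -ln(I_i/I_0)."""
    if np.any(stack.ratios <= 0):
        raise ValueError("ratios must be positive to take line integrals")
    return -np.log(stack.ratios)
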