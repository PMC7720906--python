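"""Mapping space -> material for layered slabs and voxel label volumes.

Conventions: right-handed coordinates in mm, z axis pointing *into* the
medium with the top surface at z = 0 (depth is z >= 0).  Everything not
covered by a structure is void (material id 0): photons there fly in
straight lines with no events.  Voxels are 0-indexed and own the
half-open cube [i*pitch, (i+1)*pitch) on each axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "InterfaceHit",
    "LayeredGeometry",
    "VoxelGeometry",
    "load_label_volume",
]

_EPS = 1e-9  # mm; nudge used to sample material just past a surface


@dataclass(frozen=True)
class InterfaceHit:
    """Nearest material change along a ray segment."""

    distance: float            # mm along the ray, within [0, step]
    normal: np.ndarray         # unit, oriented against the ray (d . n < 0)
    material_before: int
    material_after: int


class LayeredGeometry:
    """Stack of layers between z planes, laterally bounded, in void.

    ``z_edges`` are the K+1 strictly increasing layer boundaries
    (z_edges[0] is the top surface) and ``layer_materials`` the K
    material ids.  ``half_x``/``half_y`` bound the slab laterally at
    |x| <= half_x, |y| <= half_y (may be ``np.inf``).
    """

    kind = "LAYERED"

    def __init__(self, z_edges: Sequence[float], layer_materials: Sequence[int],
                 half_x: float = np.inf, half_y: float = np.inf):
        self.z_edges = np.asarray(z_edges, dtype=float)
        self.layer_materials = np.asarray(layer_materials, dtype=np.int64)
        if self.z_edges.ndim != 1 or self.z_edges.size < 2:
            raise ValueError("need at least two z edges")
        if not np.all(np.diff(self.z_edges) > 0):
            raise ValueError("z edges must be strictly increasing")
        if self.layer_materials.size != self.z_edges.size - 1:
            raise ValueError("one material id per layer required")
        if half_x <= 0 or half_y <= 0:
            raise ValueError("lateral half extents must be positive")
        self.half_x = float(half_x)
        self.half_y = float(half_y)

    def material_at(self, x: float, y: float, z: float) -> int:
        if abs(x) > self.half_x or abs(y) > self.half_y:
            return 0
        if z < self.z_edges[0] or z >= self.z_edges[-1]:
            return 0
        k = int(np.searchsorted(self.z_edges, z, side="right")) - 1
        return int(self.layer_materials[k])

    def first_interface(self, origin, direction, step: float) -> InterfaceHit | None:
        p = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        if step < 0:
            raise ValueError("step must be nonnegative")
        cands: list[tuple[float, int]] = []  # (t, axis)
        if d[2] != 0.0:
            for ze in self.z_edges:
                t = (ze - p[2]) / d[2]
                if _EPS < t <= step:
                    cands.append((t, 2))
        for axis, half in ((0, self.half_x), (1, self.half_y)):
            if d[axis] != 0.0 and math.isfinite(half):
                for plane in (-half, half):
                    t = (plane - p[axis]) / d[axis]
                    if _EPS < t <= step:
                        cands.append((t, axis))
        cands.sort()
        m_prev = self.material_at(*(p + _EPS * d))
        for t, axis in cands:
            q = p + (t + _EPS) * d
            m_next = self.material_at(q[0], q[1], q[2])
            if m_next != m_prev:
                normal = np.zeros(3)
                normal[axis] = -math.copysign(1.0, d[axis])
                return InterfaceHit(t, normal, m_prev, m_next)
        return None

    def to_voxel(self, pitch: float, half_x: float | None = None,
                 half_y: float | None = None) -> "VoxelGeometry":
        """Rasterize to a voxel label volume (finite lateral extent required)."""
        hx = self.half_x if half_x is None else half_x
        hy = self.half_y if half_y is None else half_y
        if not (math.isfinite(hx) and math.isfinite(hy)):
            raise ValueError("rasterizing needs finite lateral extents")
        nx = max(1, int(round(2 * hx / pitch)))
        ny = max(1, int(round(2 * hy / pitch)))
        nz = max(1, int(round((self.z_edges[-1] - self.z_edges[0]) / pitch)))
        z_centers = self.z_edges[0] + (np.arange(nz) + 0.5) * pitch
        layer_idx = np.searchsorted(self.z_edges, z_centers, side="right") - 1
        layer_idx = np.clip(layer_idx, 0, self.layer_materials.size - 1)
        col = self.layer_materials[layer_idx].astype(np.int64)
        labels = np.broadcast_to(col[:, None, None], (nz, ny, nx)).copy()
        origin = (-nx * pitch / 2.0, -ny * pitch / 2.0, float(self.z_edges[0]))
        return VoxelGeometry(labels, pitch, origin)


class VoxelGeometry:
    """Voxel label volume (labels[z, y, x]; 0 = void) embedded in void."""

    kind = "VOXEL"

    def __init__(self, labels: np.ndarray, pitch: float, origin=(0.0, 0.0, 0.0)):
        labels = np.asarray(labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3-D array (nz, ny, nx)")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer material ids")
        if pitch <= 0:
            raise ValueError("voxel pitch must be positive")
        self.labels = labels  # dtype preserved: large volumes stay uint8/16
        self.pitch = float(pitch)
        self.origin = np.asarray(origin, dtype=float)
        # precomputed structure flags for exact interface fast paths:
        # a segment whose endpoints stay inside a uniform volume (or inside
        # one contiguous equal-label z-run of a z-stratified volume) cannot
        # cross a material change, so the DDA can be skipped outright.
        self.uniform = bool((labels == labels.flat[0]).all())
        self.z_runs = None
        if not self.uniform:
            nz = labels.shape[0]
            flat = labels.reshape(nz, -1)
            if bool((flat == flat[:, :1]).all()):
                zlab = flat[:, 0].astype(np.int64)
                self.z_runs = np.concatenate(
                    ([0], np.cumsum(np.diff(zlab) != 0))).astype(np.int64)

    @property
    def shape(self):
        return self.labels.shape  # (nz, ny, nx)

    @property
    def extent(self):
        nz, ny, nx = self.labels.shape
        return np.array([nx, ny, nz]) * self.pitch

    def _voxel_index(self, x: float, y: float, z: float):
        ix = math.floor((x - self.origin[0]) / self.pitch)
        iy = math.floor((y - self.origin[1]) / self.pitch)
        iz = math.floor((z - self.origin[2]) / self.pitch)
        return int(ix), int(iy), int(iz)

    def _label(self, ix: int, iy: int, iz: int) -> int:
        nz, ny, nx = self.labels.shape
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            return int(self.labels[iz, iy, ix])
        return 0

    def material_at(self, x: float, y: float, z: float) -> int:
        return self._label(*self._voxel_index(x, y, z))

    def first_interface(self, origin, direction, step: float) -> InterfaceHit | None:
        """Exact 3-D DDA traversal to the first label change within step."""
        p = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        if step < 0:
            raise ValueError("step must be nonnegative")
        nz, ny, nx = self.labels.shape
        lo = self.origin
        hi = self.origin + np.array([nx, ny, nz]) * self.pitch

        # exact fast path: both endpoints inside the grid and provably in
        # one material region -> no interface (mirrored in the compiled
        # kernel; keep the condition arithmetic in sync)
        if self.uniform or self.z_runs is not None:
            e = p + step * d
            if (lo[0] <= p[0] < hi[0] and lo[1] <= p[1] < hi[1]
                    and lo[2] <= p[2] < hi[2]
                    and lo[0] <= e[0] < hi[0] and lo[1] <= e[1] < hi[1]
                    and lo[2] <= e[2] < hi[2]):
                if self.uniform:
                    return None
                iz0 = int(math.floor((p[2] - lo[2]) / self.pitch))
                iz1 = int(math.floor((e[2] - lo[2]) / self.pitch))
                if self.z_runs[iz0] == self.z_runs[iz1]:
                    return None

        # entry into the grid box if starting outside
        t0 = 0.0
        entry_axis = -1
        ix, iy, iz = self._voxel_index(p[0], p[1], p[2])
        inside = 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz
        if not inside:
            t_enter, t_exit = -math.inf, math.inf
            for a in range(3):
                if d[a] == 0.0:
                    if p[a] < lo[a] or p[a] >= hi[a]:
                        return None
                    continue
                t1 = (lo[a] - p[a]) / d[a]
                t2 = (hi[a] - p[a]) / d[a]
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > t_enter:
                    t_enter, entry_axis = t1, a
                t_exit = min(t_exit, t2)
            if t_enter >= t_exit or t_enter > step or t_exit <= 0.0:
                return None
            t0 = max(t_enter, 0.0)
            q = p + (t0 + _EPS) * d
            ix, iy, iz = self._voxel_index(q[0], q[1], q[2])
            lab = self._label(ix, iy, iz)
            if lab != 0 and t_enter > 0.0:
                normal = np.zeros(3)
                normal[entry_axis] = -math.copysign(1.0, d[entry_axis])
                return InterfaceHit(t0, normal, 0, lab)
            cur = lab  # void voxel inside the grid (or started on the box face)
        else:
            cur = self._label(ix, iy, iz)

        # Amanatides-Woo incremental traversal
        step_i = [0, 0, 0]
        t_max = [math.inf, math.inf, math.inf]
        t_delta = [math.inf, math.inf, math.inf]
        idx = [ix, iy, iz]
        for a in range(3):
            if d[a] > 0.0:
                step_i[a] = 1
                t_max[a] = (lo[a] + (idx[a] + 1) * self.pitch - p[a]) / d[a]
                t_delta[a] = self.pitch / d[a]
            elif d[a] < 0.0:
                step_i[a] = -1
                t_max[a] = (lo[a] + idx[a] * self.pitch - p[a]) / d[a]
                t_delta[a] = -self.pitch / d[a]
        dims = (nx, ny, nz)
        while True:
            a = 0
            if t_max[1] < t_max[a]:
                a = 1
            if t_max[2] < t_max[a]:
                a = 2
            t = t_max[a]
            if t > step or not math.isfinite(t):
                return None
            idx[a] += step_i[a]
            outside = not (0 <= idx[a] < dims[a])
            nxt = 0 if outside else int(self.labels[idx[2], idx[1], idx[0]])
            if nxt != cur:
                normal = np.zeros(3)
                normal[a] = -math.copysign(1.0, d[a])
                return InterfaceHit(t, normal, cur, nxt)
            if outside:
                return None  # exited the grid still in void: void all the way
            t_max[a] += t_delta[a]


def load_label_volume(source, pitch: float, origin=(0.0, 0.0, 0.0)) -> VoxelGeometry:
    """Build a voxel geometry from a stack of grayscale images.

    ``source`` may be a directory (slices read in alphabetical filename
    order), a list of image paths, or a 3-D integer array.  All slices
    must share one shape and hold integer pixel values (material
    labels).
    """
    if isinstance(source, np.ndarray):
        arr = source
    else:
        import imageio.v3 as iio

        if isinstance(source, (str, Path)) and Path(source).is_dir():
            paths = sorted(Path(source).iterdir())
            paths = [p for p in paths if p.suffix.lower() in
                     (".png", ".tif", ".tiff")]
        else:
            paths = [Path(p) for p in source]
        if not paths:
            raise ValueError("no image slices found")
        slices = [np.asarray(iio.imread(p)) for p in paths]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"ragged image stack: shapes {sorted(shapes)}")
        if any(s.ndim != 2 for s in slices):
            raise ValueError("slices must be single-channel grayscale images")
        arr = np.stack(slices, axis=0)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ValueError("pixel values must be integer material labels")
        arr = arr.astype(np.int64)
    return VoxelGeometry(arr, pitch, origin)
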