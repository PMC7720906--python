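"""Per-photon event-management engine.

Each launched photon repeats the following loop until it is absorbed,
escapes the simulation domain, or hits the iteration cap:

1. Raman check: one uniform (xi6) against the local material's
   per-step Raman conversion CDF; on a shift the wavelength and optical
   properties update and the conversion depth (z) is recorded.
2. Elastic step: free path (xi1), azimuth (xi2) and Henyey-Greenstein
   polar deflection (xi3) are drawn at the current wavelength; the
   direction rotates, then the photon attempts to travel the free path.
3. Interfaces: if a material change lies within the segment the photon
   moves to it, survives an absorption roulette over the traveled
   length (xi4), then reflects or refracts by a Fresnel draw (xi7); a
   fresh free path is sampled in the new medium (no residual-path
   rescaling).
4. Completed segments undergo the absorption roulette over the traveled
   length (xi4).  On absorption, a draw (xi5) against the fluorescence
   CDF decides annihilation versus isotropic re-emission at a
   CDF-sampled wavelength.
5. Photons in void fly straight: they either escape (no structure
   ahead) or hit a surface and reflect/refract back in.

Two engines implement this loop: the readable scalar reference in this
module and the numba-compiled batch kernel in ``_kernel``.  Both consume
uniforms in exactly the order above so they can be driven by a shared
recorded variate stream and compared record-for-record.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import LayeredGeometry, VoxelGeometry
from ._kernel import _sincos
from .sampling import (
    _rotate_cs,
    hg_cos_theta,
    refract,
    reflect,
    sample_shift_wavelength,
)
from .spectra import Material

__all__ = [
    "ABSORBED",
    "ESCAPED",
    "ITERATION_CAP",
    "SourceSpec",
    "MaterialTable",
    "RunConfig",
    "RunResult",
    "launch_photon",
    "propagate_photon",
    "run_simulation",
]

ABSORBED = 0
ESCAPED = 1
ITERATION_CAP = 2
STATE_NAMES = {ABSORBED: "ABSORBED", ESCAPED: "ESCAPED", ITERATION_CAP: "ITERATION_CAP"}

_NUDGE = 1e-9   # mm; push positions off surfaces after boundary events
_LAUNCH_STANDOFF = 1e-6  # mm; launch height above the z=0 surface (in void)
_VOID_STEP = 1e30  # "infinite" straight flight through void

RECORD_COLUMNS = [
    "state", "x", "y", "z", "ux", "uy", "uz", "wl_index", "wavelength_nm",
    "has_raman", "has_fluoresced", "raman_depth_mm", "n_iterations", "batch",
]


class RandomStream:
    """Uniform variate stream backed by a numpy Generator."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def u(self) -> float:
        return float(self.rng.random())


class RecordingStream:
    """Wraps a stream and records every drawn uniform (oracle support)."""

    def __init__(self, inner):
        self.inner = inner
        self.values: list[float] = []

    def u(self) -> float:
        v = self.inner.u()
        self.values.append(v)
        return v


class ArrayStream:
    """Replays a pre-recorded uniform stream."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)
        self.cursor = 0

    def u(self) -> float:
        v = float(self.values[self.cursor])
        self.cursor += 1
        return v


@dataclass(frozen=True)
class SourceSpec:
    """Monochromatic Gaussian source at the top surface, aimed along +z.

    The radial offset is Gaussian with ``std_mm`` truncated at
    ``radius_mm`` (no photon is emitted beyond the source radius); the
    launch direction is uniform in solid angle within the illumination
    cone of ``half_angle_deg`` about +z.
    """

    wavelength_nm: float = 785.0
    radius_mm: float = 0.2
    std_mm: float = 1e-4
    half_angle_deg: float = 8.0
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.radius_mm < 0 or self.std_mm < 0:
            raise ValueError("source radius and std must be nonnegative")
        if not (0.0 <= self.half_angle_deg <= 90.0):
            raise ValueError("illumination half angle must lie in [0, 90] deg")


@dataclass
class MaterialTable:
    """Optical properties of all materials sampled on the run grid.

    Row ``m`` of each array holds material id ``m`` (row 0 is void and
    is never dereferenced for transport properties; its n is 1).
    """

    grid: np.ndarray      # (W,) nm; index 0 is the source wavelength
    mu_s: np.ndarray      # (M+1, W) mm^-1
    mu_a: np.ndarray      # (M+1, W) mm^-1
    g: np.ndarray         # (M+1, W)
    n: np.ndarray         # (M+1, W)
    rho_R: np.ndarray     # (M+1, W) cumulative per-step Raman CDF
    rho_F: np.ndarray     # (M+1, W) cumulative per-absorption fluorescence CDF

    @classmethod
    def build(cls, materials: Sequence[Material], grid: np.ndarray) -> "MaterialTable":
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size < 1:
            raise ValueError("wavelength grid must be a 1-D array")
        ids = [m.id for m in materials]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate material ids")
        n_rows = max(ids) + 1
        W = grid.size
        mu_s = np.zeros((n_rows, W))
        mu_a = np.zeros((n_rows, W))
        g = np.zeros((n_rows, W))
        n = np.ones((n_rows, W))
        rho_R = np.zeros((n_rows, W))
        rho_F = np.zeros((n_rows, W))
        for m in materials:
            for j, lam in enumerate(grid):
                mu_s[m.id, j] = m.mu_s(lam)
                mu_a[m.id, j] = m.mu_a_at(lam)
                g[m.id, j] = m.g(lam)
                n[m.id, j] = m.n(lam)
            if np.any(mu_s[m.id] <= 0):
                raise ValueError(f"material {m.id}: mu_s must be positive on the grid")
            if np.any((g[m.id] < 0) | (g[m.id] >= 1)) or np.any(n[m.id] < 1):
                raise ValueError(f"material {m.id}: g or n outside bounds on the grid")
            for name, dest in (("rho_R", rho_R), ("rho_F", rho_F)):
                s = getattr(m, name)
                if s is None:
                    continue
                if s.wavelengths.size != W or not np.allclose(s.wavelengths, grid):
                    raise ValueError(
                        f"material {m.id}: {name} CDF must be tabulated on the "
                        "run wavelength grid (cumulative mass is grid-specific)"
                    )
                dest[m.id] = s.values
        return cls(grid, mu_s, mu_a, g, n, rho_R, rho_F)


@dataclass
class RunConfig:
    geometry: LayeredGeometry | VoxelGeometry
    materials: list[Material]
    grid: np.ndarray
    source: SourceSpec
    detector: object | None = None       # probes.DetectorSpec; stored, not used here
    photons_per_batch: int = 100_000
    n_batches: int = 10
    max_iterations: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.photons_per_batch <= 0 or self.n_batches <= 0:
            raise ValueError("photon and batch counts must be positive")
        if self.max_iterations <= 0:
            raise ValueError("max_iterations must be positive")
        self.grid = np.asarray(self.grid, dtype=float)

    @property
    def n_photons(self) -> int:
        return self.photons_per_batch * self.n_batches

    def table(self) -> MaterialTable:
        return MaterialTable.build(self.materials, self.grid)

    def digest(self) -> str:
        """Stable hash of the physically meaningful configuration."""
        h = hashlib.sha256()
        geom = self.geometry
        if isinstance(geom, VoxelGeometry):
            h.update(geom.labels.tobytes())
            h.update(np.asarray([geom.pitch, *geom.origin]).tobytes())
        else:
            h.update(geom.z_edges.tobytes())
            h.update(geom.layer_materials.tobytes())
            h.update(np.asarray([geom.half_x, geom.half_y]).tobytes())
        t = self.table()
        for arr in (t.grid, t.mu_s, t.mu_a, t.g, t.n, t.rho_R, t.rho_F):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(json.dumps({
            "source": [self.source.wavelength_nm, self.source.radius_mm,
                       self.source.std_mm, self.source.half_angle_deg,
                       list(self.source.center_xy)],
            "photons_per_batch": self.photons_per_batch,
            "n_batches": self.n_batches,
            "max_iterations": self.max_iterations,
        }, sort_keys=True).encode())
        return h.hexdigest()[:16]


@dataclass
class RunResult:
    records: pd.DataFrame
    meta: dict

    def save(self, records_path, meta_path=None) -> None:
        self.records.to_csv(records_path, index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.meta, fh, indent=2)


# ---------------------------------------------------------------------------
# scalar reference engine
# ---------------------------------------------------------------------------

def launch_photon(source: SourceSpec, stream) -> tuple[np.ndarray, np.ndarray]:
    """Sample a launch position (in void, just above z=0) and direction.

    Draw order: Box-Muller pairs for the truncated-Gaussian radial
    offset (re-drawn until inside the source radius), then cone cosine
    and azimuth for the direction.
    """
    gx = gy = 0.0
    if source.std_mm > 0.0 and source.radius_mm > 0.0:
        while True:
            ua = stream.u()
            ub = stream.u()
            r = source.std_mm * math.sqrt(-2.0 * math.log1p(-ua))
            sb, cb = _sincos(2.0 * math.pi * ub)
            gx = r * cb
            gy = r * sb
            if gx * gx + gy * gy <= source.radius_mm * source.radius_mm:
                break
    if source.half_angle_deg > 0.0:
        uc = stream.u()
        ud = stream.u()
        cos_min = math.cos(math.radians(source.half_angle_deg))
        ct = 1.0 - uc * (1.0 - cos_min)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        sp, cp = _sincos(2.0 * math.pi * ud)
        direction = np.array([st * cp, st * sp, ct])
    else:
        direction = np.array([0.0, 0.0, 1.0])
    pos = np.array([source.center_xy[0] + gx, source.center_xy[1] + gy,
                    -_LAUNCH_STANDOFF])
    return pos, direction


def propagate_photon(pos, direction, wl_index: int, geometry, table: MaterialTable,
                     stream, max_iterations: int = 100_000) -> dict:
    """Scalar reference implementation of the event loop (one photon).

    Returns a record dict.  This is the readable oracle the compiled
    batch kernel is tested against; keep the uniform draw order in sync
    with ``_kernel._run_batch``.
    """
    pos = np.asarray(pos, dtype=float).copy()
    d = np.asarray(direction, dtype=float).copy()
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(d))):
        raise FloatingPointError(f"photon state corrupted: pos={pos}, dir={d}")
    wl = int(wl_index)
    mat = geometry.material_at(pos[0], pos[1], pos[2])
    has_raman = False
    has_fluor = False
    raman_depth = math.nan
    state = ITERATION_CAP
    it = 0
    while it < max_iterations:
        it += 1
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(d))):
            raise FloatingPointError(
                f"photon state corrupted: pos={pos}, dir={d}, iteration {it}"
            )
        if mat == 0:
            hit = geometry.first_interface(pos, d, _VOID_STEP)
            if hit is None:
                state = ESCAPED
                break
            pos = pos + hit.distance * d
            m2 = hit.material_after
            u7 = stream.u()
            R, refr = refract(d, hit.normal, 1.0, table.n[m2, wl])
            if u7 < R:
                d = reflect(d, hit.normal)
            else:
                d = refr
                mat = m2
            pos = pos + _NUDGE * d
            continue

        # (1) Raman check against the local per-step conversion CDF
        u6 = stream.u()
        rcdf = table.rho_R[mat]
        if u6 < rcdf[-1]:
            j = int(np.searchsorted(rcdf, u6, side="right"))
            if not has_raman:
                raman_depth = pos[2]
            has_raman = True
            wl = j

        # (2) free path and scattering angles at the current wavelength
        u1 = stream.u()
        u2 = stream.u()
        u3 = stream.u()
        l = -math.log1p(-u1) / table.mu_s[mat, wl]
        phi = 2.0 * math.pi * u2
        ct = hg_cos_theta(u3, table.g[mat, wl])
        st = math.sqrt(1.0 - ct * ct)
        sphi, cphi = _sincos(phi)
        d = np.array(_rotate_cs(d[0], d[1], d[2], ct, st, cphi, sphi))

        # (3)/(4) travel the segment, handling interfaces and absorption
        absorbed = False
        while True:
            hit = geometry.first_interface(pos, d, l)
            mua = table.mu_a[mat, wl]
            if hit is None:
                pos = pos + l * d
                u4 = stream.u()
                # 1 - e^-x < x: u4 >= mua*l already implies survival
                absorbed = u4 < mua * l and u4 < -math.expm1(-mua * l)
                break
            pos = pos + hit.distance * d
            u4 = stream.u()
            if u4 < mua * hit.distance and u4 < -math.expm1(-mua * hit.distance):
                absorbed = True
                break
            m2 = hit.material_after
            n2 = 1.0 if m2 == 0 else table.n[m2, wl]
            u7 = stream.u()
            R, refr = refract(d, hit.normal, table.n[mat, wl], n2)
            if u7 < R:
                d = reflect(d, hit.normal)
                pos = pos + _NUDGE * d
            else:
                d = refr
                pos = pos + _NUDGE * d
                if m2 == 0:
                    mat = 0
                    break   # straight flight handled at the next iteration
                mat = m2
            u1 = stream.u()
            l = -math.log1p(-u1) / table.mu_s[mat, wl]

        if absorbed:
            # (5) fluorescence branch
            u5 = stream.u()
            fcdf = table.rho_F[mat]
            j = sample_shift_wavelength(u5, fcdf)
            if j is None:
                state = ABSORBED
                break
            has_fluor = True
            wl = j
            ua = stream.u()
            ub = stream.u()
            ct = 2.0 * ua - 1.0
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            sf, cf = _sincos(2.0 * math.pi * ub)
            d = np.array([st * cf, st * sf, ct])

    return {
        "state": state,
        "x": pos[0], "y": pos[1], "z": pos[2],
        "ux": d[0], "uy": d[1], "uz": d[2],
        "wl_index": wl,
        "has_raman": has_raman,
        "has_fluoresced": has_fluor,
        "raman_depth_mm": raman_depth,
        "n_iterations": it,
    }


def _batch_seed(seed: int, batch: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(batch)]).generate_state(1)[0]
               % (2 ** 31))


def _run_batch_reference(config: RunConfig, table: MaterialTable, batch: int,
                         stream=None) -> pd.DataFrame:
    if stream is None:
        stream = RandomStream(np.random.default_rng(_batch_seed(config.seed, batch)))
    rows = []
    for _ in range(config.photons_per_batch):
        pos, d = launch_photon(config.source, stream)
        rec = propagate_photon(pos, d, 0, config.geometry, table, stream,
                               config.max_iterations)
        rows.append(rec)
    df = pd.DataFrame(rows)
    df["wavelength_nm"] = table.grid[df["wl_index"].to_numpy()]
    df["batch"] = batch
    return df[RECORD_COLUMNS]


def _run_batch_kernel(config: RunConfig, table: MaterialTable, batch: int,
                      stream_values: np.ndarray | None = None,
                      finalize: bool = True) -> pd.DataFrame:
    from . import _kernel

    arrays = _kernel.run_batch(
        config.geometry, table, config.source,
        n_photons=config.photons_per_batch,
        max_iterations=config.max_iterations,
        seed=_batch_seed(config.seed, batch),
        stream=stream_values,
    )
    df = pd.DataFrame(arrays, copy=False)
    df["batch"] = batch
    if finalize:
        df = _finalize_records(df, table)
    return df


def _finalize_records(df: pd.DataFrame, table: MaterialTable) -> pd.DataFrame:
    df = df.copy()
    df["wavelength_nm"] = table.grid[df["wl_index"].to_numpy()]
    return df[RECORD_COLUMNS]


def run_simulation(config: RunConfig, engine: str = "kernel",
                   batch_filter: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
                   progress: Callable[[int, dict], None] | None = None) -> RunResult:
    """Launch all batches with independently seeded streams.

    ``engine`` is ``"kernel"`` (numba batch kernel, default) or
    ``"reference"`` (scalar Python loop; slow, for oracles only).
    ``batch_filter`` optionally thins each batch's records before they
    are accumulated (terminal-state counts are always exact).
    """
    table = config.table()
    counts = {name: 0 for name in STATE_NAMES.values()}
    kept = []
    for b in range(config.n_batches):
        if engine == "kernel":
            # filtering happens before the (copying) column finalization,
            # so heavy runs that keep only detected photons stay cheap
            df = _run_batch_kernel(config, table, b, finalize=False)
        elif engine == "reference":
            df = _run_batch_reference(config, table, b)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        vals, cnts = np.unique(df["state"].to_numpy(), return_counts=True)
        for v, c in zip(vals, cnts):
            counts[STATE_NAMES[int(v)]] += int(c)
        if batch_filter is not None:
            df = batch_filter(df)
        if engine == "kernel":
            df = _finalize_records(df, table)
        kept.append(df)
        if progress is not None:
            progress(b, dict(counts))
    records = pd.concat(kept, ignore_index=True)
    meta = {
        "seed": config.seed,
        "engine": engine,
        "config_digest": config.digest(),
        "photons_per_batch": config.photons_per_batch,
        "n_batches": config.n_batches,
        "n_photons": config.n_photons,
        "max_iterations": config.max_iterations,
        "counts": counts,
    }
    assert sum(counts.values()) == config.n_photons
    return RunResult(records, meta)
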