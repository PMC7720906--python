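"""In-silico phantom fixtures.

Replicas of the validation phantoms (I: PDMS slab, II: nylon slab,
III: thin PDMS layer over a nylon substrate) and the homogeneous
semi-infinite media of the depth study, plus synthetic PDMS-like /
nylon-like conversion spectra.  The measured material spectra are not
tabulated anywhere, so the fixtures use smooth synthetic stand-ins
pinned to the printed endpoint values of the optical-property curves:
a decreasing power law for mu_s' and a linear ramp for mu_a between
500 and 1000 nm.  Raman spectra are sums of narrow Lorentzians at
profile-specific positions (disjoint between the two profiles so
layered simulations can attribute peaks to layers); fluorescence is one
broad hump.  Absolute conversion probabilities are free parameters of
the model (no published cross sections); the documented defaults are
rho_R_scale = 1e-3 and rho_F_scale = 2e-3 per event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import VoxelGeometry
from .probes import DetectorSpec
from .spectra import Material, DispersionModel, Spectrum, build_conversion_cdf
from .transport import MaterialTable, RunConfig, SourceSpec

__all__ = [
    "emission_grid",
    "PhantomFixture",
    "make_phantom",
    "make_material_spectra",
    "make_depth_medium",
]

SOURCE_WAVELENGTH_NM = 785.0
EMISSION_BAND_NM = (810.0, 932.0)
N_EMISSION = 100

# printed endpoint values of the measured optical-property curves
# (mu_a in mm^-1 at 500 -> 1000 nm; mu_s' likewise)
_PDMS_MU_A = (0.11, 0.075)
_PDMS_MU_SP = (0.65, 0.45)
_NYLON_MU_A = (0.02, 0.01)
_NYLON_MU_SP = (1.05, 0.25)
_BAND = (500.0, 1000.0)

# Raman peak centers as fractions of the emission band; interleaved and
# >= 3 grid bins apart between the two profiles by construction
_PEAK_FRACTIONS = {
    "PDMS_like": (0.08, 0.22, 0.38, 0.55, 0.72, 0.88),
    "nylon_like": (0.15, 0.30, 0.47, 0.63, 0.80, 0.95),
}


def emission_grid() -> np.ndarray:
    """Run wavelength grid: source wavelength + 100 equally spaced
    emission wavelengths over 810-932 nm."""
    return np.concatenate(([SOURCE_WAVELENGTH_NM],
                           np.linspace(*EMISSION_BAND_NM, N_EMISSION)))


def probe_source(**overrides) -> SourceSpec:
    """785 nm Gaussian source: std 0.1 um truncated at the 200 um fiber
    radius, illumination cone half-angle 8 deg."""
    kw = dict(wavelength_nm=SOURCE_WAVELENGTH_NM, radius_mm=0.2,
              std_mm=1e-4, half_angle_deg=8.0)
    kw.update(overrides)
    return SourceSpec(**kw)


def probe_detector(**overrides) -> DetectorSpec:
    """Probe collection aperture: 600 um diameter disk, 30 deg acceptance
    half-angle (pass ``inner_radius_mm=0.2`` for the annular reading)."""
    kw = dict(inner_radius_mm=0.0, outer_radius_mm=0.3, half_angle_deg=30.0)
    kw.update(overrides)
    return DetectorSpec(**kw)


@dataclass
class PhantomFixture:
    geometry: VoxelGeometry
    materials: list[Material]
    source: SourceSpec
    detector: DetectorSpec
    grid: np.ndarray
    name: str = ""

    def run_config(self, photons_per_batch: int, n_batches: int, *,
                   seed: int = 0, max_iterations: int = 100_000) -> RunConfig:
        return RunConfig(
            geometry=self.geometry, materials=self.materials, grid=self.grid,
            source=self.source, detector=self.detector,
            photons_per_batch=photons_per_batch, n_batches=n_batches,
            max_iterations=max_iterations, seed=seed,
        )

    def validate(self) -> MaterialTable:
        """Full consistency check: registered labels, property bounds on
        the grid, conversion CDFs nondecreasing and bounded by 1."""
        table = MaterialTable.build(self.materials, self.grid)
        labels = np.unique(self.geometry.labels)
        known = {0} | {m.id for m in self.materials}
        missing = set(int(v) for v in labels) - known
        if missing:
            raise ValueError(f"geometry labels without materials: {sorted(missing)}")
        for name, arr in (("rho_R", table.rho_R), ("rho_F", table.rho_F)):
            if np.any(np.diff(arr, axis=1) < -1e-15) or np.any(arr > 1.0 + 1e-12):
                raise ValueError(f"{name} CDF violates monotonicity/bounds")
        return table


def _power_law_dispersion(mu_sp_endpoints, g: float, n: float) -> DispersionModel:
    """Fit mu_s'(lam) = A lam^-b through the printed endpoints, then
    convert to mu_s = mu_s'/(1-g)."""
    lam0, lam1 = _BAND
    v0, v1 = mu_sp_endpoints
    b = math.log(v0 / v1) / math.log(lam1 / lam0)
    a1 = (v0 * lam0 ** b) / (1.0 - g)
    return DispersionModel(a1=a1, a2=b, a3=g, a4=0.0, a5=n, a6=0.0)


def _linear_mu_a(endpoints) -> Spectrum:
    return Spectrum(np.array(_BAND), np.array(endpoints, dtype=float))


def make_material_spectra(profile: str, n_peaks: int = 5, seed: int = 0,
                          grid: np.ndarray | None = None):
    """Synthetic Raman and fluorescence conversion-rate spectra.

    The Raman rate is a sum of ``n_peaks`` narrow Lorentzians at fixed,
    profile-specific grid positions (the seed jitters amplitudes and
    widths, never positions, so peak bins are reproducible and the two
    profiles never collide).  The fluorescence rate is a broad Gaussian
    hump plus a small mass at grid index 0 (re-emission at the source
    wavelength).  Both rates are normalized to unit sum, so the total
    event probability is set entirely by the scale passed to
    ``build_conversion_cdf``.
    """
    if profile not in _PEAK_FRACTIONS:
        raise ValueError(f"unknown profile {profile!r}")
    if n_peaks < 1 or n_peaks > len(_PEAK_FRACTIONS[profile]):
        raise ValueError(f"n_peaks must lie in [1, {len(_PEAK_FRACTIONS[profile])}]")
    if grid is None:
        grid = emission_grid()
    rng = np.random.default_rng(seed)
    W = grid.size
    bins = np.arange(W, dtype=float)

    raman = np.zeros(W)
    centers = [1 + frac * (W - 2) for frac in _PEAK_FRACTIONS[profile][:n_peaks]]
    for c in centers:
        amp = rng.uniform(0.5, 1.0)
        gamma = rng.uniform(0.8, 1.4)  # half width in bins: narrow peaks
        raman += amp / (1.0 + ((bins - round(c)) / gamma) ** 2)
    raman[0] = 0.0  # no Raman mass at the source wavelength
    raman /= raman.sum()

    fluor = np.exp(-0.5 * ((bins - 0.45 * W) / (0.25 * W)) ** 2)
    fluor[0] = 0.1 * fluor.max()  # re-emission at the initial wavelength
    fluor /= fluor.sum()

    return Spectrum(grid, raman), Spectrum(grid, fluor)


def peak_bins(profile: str, n_peaks: int = 5, grid: np.ndarray | None = None):
    """Grid indices of the synthetic Raman peaks of ``profile``."""
    if grid is None:
        grid = emission_grid()
    W = grid.size
    return [int(round(1 + frac * (W - 2)))
            for frac in _PEAK_FRACTIONS[profile][:n_peaks]]


def _pdms_material(mat_id: int, rho_R_scale: float, rho_F_scale: float,
                   seed: int, grid: np.ndarray, g: float, n: float) -> Material:
    raman, fluor = make_material_spectra("PDMS_like", seed=seed, grid=grid)
    return Material(
        id=mat_id,
        dispersion=_power_law_dispersion(_PDMS_MU_SP, g, n),
        mu_a=_linear_mu_a(_PDMS_MU_A),
        rho_R=build_conversion_cdf(raman, rho_R_scale),
        rho_F=build_conversion_cdf(fluor, rho_F_scale),
    )


def _nylon_material(mat_id: int, rho_R_scale: float, rho_F_scale: float,
                    seed: int, grid: np.ndarray, g: float, n: float) -> Material:
    raman, fluor = make_material_spectra("nylon_like", seed=seed, grid=grid)
    return Material(
        id=mat_id,
        dispersion=_power_law_dispersion(_NYLON_MU_SP, g, n),
        mu_a=_linear_mu_a(_NYLON_MU_A),
        rho_R=build_conversion_cdf(raman, rho_R_scale),
        rho_F=build_conversion_cdf(fluor, rho_F_scale),
    )


def make_phantom(which: str, *, rho_R_scale: float = 1e-3,
                 rho_F_scale: float = 2e-3, seed: int = 0,
                 g: float = 0.9, n: float = 1.4,
                 n_voxels: int | None = None) -> PhantomFixture:
    """In-silico replica of validation phantom I, II or III.

    I / II: a 10 mm single layer of PDMS / nylon on a 256^3 voxel grid
    covering a 2x2x2 cm^3 domain (material in the top half, void below).
    III: a 913 um PDMS layer over a 10 mm nylon substrate on a
    501x501x203 grid.  ``n_voxels`` overrides the grid size (scaled-down
    grids for fast tests; the pitch shrinks/grows accordingly).
    """
    which = str(which).upper()
    grid = emission_grid()
    if which in ("I", "II"):
        nv = n_voxels or 256
        pitch = 20.0 / nv
        nz_mat = int(round(10.0 / pitch))
        labels = np.zeros((nv, nv, nv), dtype=np.uint8)
        labels[:nz_mat] = 1
        geometry = VoxelGeometry(labels, pitch,
                                 origin=(-nv * pitch / 2, -nv * pitch / 2, 0.0))
        if which == "I":
            mats = [_pdms_material(1, rho_R_scale, rho_F_scale, seed, grid, g, n)]
        else:
            mats = [_nylon_material(1, rho_R_scale, rho_F_scale, seed, grid, g, n)]
    elif which == "III":
        nxy = n_voxels or 501
        nz = 203 if n_voxels is None else max(3, int(round(n_voxels * 203 / 501)))
        total_z = 0.913 + 10.0
        pitch = total_z / nz
        nz_pdms = max(1, int(round(0.913 / pitch)))
        labels = np.zeros((nz, nxy, nxy), dtype=np.uint8)
        labels[:nz_pdms] = 1
        labels[nz_pdms:] = 2
        geometry = VoxelGeometry(labels, pitch,
                                 origin=(-nxy * pitch / 2, -nxy * pitch / 2, 0.0))
        mats = [
            _pdms_material(1, rho_R_scale, rho_F_scale, seed, grid, g, n),
            _nylon_material(2, rho_R_scale, rho_F_scale, seed + 1, grid, g, n),
        ]
    else:
        raise ValueError("phantom must be 'I', 'II' or 'III'")
    return PhantomFixture(geometry, mats, probe_source(), probe_detector(),
                          grid, name=f"phantom_{which}")


def make_depth_medium(mu_a: float, mu_s_prime: float, rho_R_total: float, *,
                      g: float = 0.9, n: float = 1.4,
                      n_voxels: int = 256) -> PhantomFixture:
    """Homogeneous semi-infinite medium of the depth study.

    A 2x2x2 cm^3 slab on an ``n_voxels``^3 grid, constant optical
    properties (mu_s = mu_s'/(1-g)), a flat per-step Raman conversion
    rate integrating to ``rho_R_total`` over the emission grid, and no
    fluorescence.
    """
    if mu_a < 0 or mu_s_prime <= 0:
        raise ValueError("need mu_a >= 0 and mu_s' > 0")
    if not (0.0 <= rho_R_total <= 1.0):
        raise ValueError("rho_R_total must lie in [0, 1]")
    grid = emission_grid()
    mu_s = mu_s_prime / (1.0 - g)
    flat = np.ones(grid.size)
    flat[0] = 0.0
    flat /= flat.sum()
    material = Material(
        id=1,
        dispersion=DispersionModel(a1=mu_s, a2=0.0, a3=g, a4=0.0, a5=n, a6=0.0),
        mu_a=Spectrum(np.array(_BAND), np.array([mu_a, mu_a], dtype=float)),
        rho_R=build_conversion_cdf(Spectrum(grid, flat), rho_R_total),
        rho_F=None,
    )
    pitch = 20.0 / n_voxels
    labels = np.ones((n_voxels, n_voxels, n_voxels), dtype=np.uint8)
    geometry = VoxelGeometry(labels, pitch,
                             origin=(-10.0, -10.0, 0.0))
    return PhantomFixture(geometry, [material], probe_source(), probe_detector(),
                          grid, name=f"depth_medium_mua{mu_a}_musp{mu_s_prime}")
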