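"""Fiber-probe detection model.

The handheld probe is modeled as a collection aperture on the top
surface (z = 0) around the illumination spot: a photon is detected iff
it escapes through the top surface with its exit point inside
[inner_radius, outer_radius) of the probe axis and its exit direction
(in void, i.e. after refraction at the surface) within the acceptance
half-angle of the outward normal.

The default reading of the 600-um collection port is the full disk
(inner radius 0, outer radius 300 um).  The alternative annular reading
(collection ring between the 400-um source bore and the 600-um outer
diameter, ``inner_radius_mm = 0.2``) is a config switch.  The disk
reading reproduces the published sensing-depth extremes far better at
both ends of the optical-property grid and is what the probe
description ("a cylinder of 600-um diameter") literally states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transport import ESCAPED

__all__ = ["DetectorSpec", "DetectedSpectrum", "accept", "detected_mask", "bin_spectrum"]

_TOP_Z_TOL = 1e-6  # mm; exit points on the z=0 plane


@dataclass(frozen=True)
class DetectorSpec:
    inner_radius_mm: float = 0.0
    outer_radius_mm: float = 0.3
    half_angle_deg: float = 30.0
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (0.0 <= self.inner_radius_mm < self.outer_radius_mm):
            raise ValueError("need 0 <= inner radius < outer radius")
        if not (0.0 < self.half_angle_deg <= 90.0):
            raise ValueError("acceptance half-angle must lie in (0, 90] deg")


@dataclass
class DetectedSpectrum:
    """Counts of detected photons per emission-grid wavelength.

    ``elastic_count`` tallies detected photons still at the source
    wavelength (grid index 0), kept out of the shifted-photon bins.
    """

    wavelengths: np.ndarray
    counts: np.ndarray
    elastic_count: int
    total_launched: int

    def to_csv(self, path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths,
                      "counts": self.counts}).to_csv(path, index=False)


def accept(record, det: DetectorSpec):
    """Aperture test for records already known to exit the top surface.

    ``record`` may be a single record mapping or a DataFrame/dict of
    arrays with fields x, y, ux, uy, uz.  The exit direction points into
    void (uz < 0; the outward surface normal is -z), so the angular cut
    is ``-uz >= cos(half_angle)``.
    """
    x = np.asarray(record["x"], dtype=float)
    y = np.asarray(record["y"], dtype=float)
    uz = np.asarray(record["uz"], dtype=float)
    r = np.hypot(x - det.center_xy[0], y - det.center_xy[1])
    cos_cut = np.cos(np.radians(det.half_angle_deg))
    ok = (r >= det.inner_radius_mm) & (r < det.outer_radius_mm) & (-uz >= cos_cut)
    if np.ndim(record["x"]) == 0:
        return bool(ok)
    return ok


def detected_mask(records: pd.DataFrame, det: DetectorSpec) -> np.ndarray:
    """Full detection test: escaped photon, top-surface exit, aperture."""
    top = ((records["state"].to_numpy() == ESCAPED)
           & (records["z"].to_numpy() <= _TOP_Z_TOL)
           & (records["uz"].to_numpy() < 0.0))
    return top & np.asarray(accept(records, det))


def bin_spectrum(records: pd.DataFrame, det: DetectorSpec, grid: np.ndarray,
                 total_launched: int | None = None) -> DetectedSpectrum:
    """Histogram of detected photons over the emission wavelength grid.

    ``grid`` is the full run grid (index 0 = source wavelength); bins
    cover indices 1..W-1, and source-wavelength photons fill the elastic
    channel.
    """
    grid = np.asarray(grid, dtype=float)
    det_recs = records[detected_mask(records, det)]
    wl = det_recs["wl_index"].to_numpy()
    if np.any((wl < 0) | (wl >= grid.size)):
        raise ValueError("record wavelength index off the run grid")
    counts = np.bincount(wl, minlength=grid.size)
    if total_launched is None:
        total_launched = len(records)
    return DetectedSpectrum(
        wavelengths=grid[1:],
        counts=counts[1:],
        elastic_count=int(counts[0]),
        total_launched=int(total_launched),
    )
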