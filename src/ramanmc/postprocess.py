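"""Spectral post-processing and Raman sensing-depth statistics.

Sensing-depth convention: ``d_X`` is the depth *beyond which* a fraction
X of detected Raman photons were generated, i.e. the (1 - X) empirical
quantile of the conversion-depth sample measured from the surface
(nearest-rank rule).  Under this convention d90 <= d75: the depth beyond
which 90% of the photons lie is shallower than the depth beyond which
75% lie.  The complementary "X% from above" reading is available via
``from_above=True`` for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .probes import DetectorSpec, detected_mask
from .spectra import Spectrum

__all__ = [
    "DepthCurve",
    "DepthMetrics",
    "sensing_depth",
    "bootstrap_sensing_depth",
    "rolling_ball_baseline",
    "snv_normalize",
    "depth_study",
]


@dataclass
class DepthCurve:
    """Cumulative distribution of detected-Raman conversion depths."""

    depths: np.ndarray     # mm, sorted ascending
    cumulative: np.ndarray  # fraction of detected Raman photons at depth <= d

    @classmethod
    def from_depths(cls, depths) -> "DepthCurve":
        d = np.sort(np.asarray(depths, dtype=float))
        if d.size == 0:
            raise ValueError("no detected Raman depths")
        frac = np.arange(1, d.size + 1) / d.size
        return cls(d, frac)


@dataclass
class DepthMetrics:
    d75_mm: float
    d90_mm: float
    n_detected: int


def sensing_depth(depths, fraction: float, from_above: bool = False) -> float:
    """Depth beyond which ``fraction`` of detected Raman photons were generated.

    Nearest-rank empirical quantile: sort depths ascending and return
    the element at rank ceil((1 - fraction) * N) (or ceil(fraction * N)
    with ``from_above=True``).
    """
    d = np.sort(np.asarray(depths, dtype=float))
    if d.size == 0:
        raise ValueError("empty depth sample")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    q = fraction if from_above else 1.0 - fraction
    rank = max(1, math.ceil(q * d.size))
    return float(d[rank - 1])


def bootstrap_sensing_depth(depths, fraction: float, n_boot: int = 1000,
                            ci: float = 0.95, seed: int = 0,
                            from_above: bool = False):
    """Percentile bootstrap CI for the sensing depth (resampling depths)."""
    depths = np.asarray(depths, dtype=float)
    rng = np.random.default_rng(seed)
    est = sensing_depth(depths, fraction, from_above)
    idx = rng.integers(0, depths.size, size=(n_boot, depths.size))
    boots = np.array([
        sensing_depth(depths[row], fraction, from_above) for row in idx
    ])
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return est, float(lo), float(hi)


def rolling_ball_baseline(spectrum: Spectrum, half_width: int) -> Spectrum:
    """Rolling-ball (grayscale morphological opening) baseline estimate.

    A moving minimum followed by a moving maximum over a flat window of
    ``2 * half_width + 1`` bins; edges are extended by replication.  The
    baseline never exceeds the spectrum, so the residual is >= 0.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    size = 2 * half_width + 1
    if size > len(spectrum):
        raise ValueError("rolling-ball window larger than the spectrum")
    base = ndimage.grey_opening(spectrum.values, size=size, mode="nearest")
    return Spectrum(spectrum.wavelengths, base)


def snv_normalize(spectrum: Spectrum) -> np.ndarray:
    """Standard normal variate: zero mean, unit sample (N-1) std.

    Returns a bare array since SNV output is signed (a Spectrum's values
    are nonnegative by construction).
    """
    v = spectrum.values
    if v.size < 2:
        raise ValueError("SNV needs at least two bins")
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a zero-variance spectrum")
    return (v - np.mean(v)) / sd


def detected_raman_depths(records: pd.DataFrame, det: DetectorSpec) -> np.ndarray:
    """Conversion depths (mm) of detected Raman-shifted photons."""
    mask = detected_mask(records, det) & records["has_raman"].to_numpy()
    return records.loc[mask, "raman_depth_mm"].to_numpy()


def depth_study(mu_a_values, mu_s_prime_values, rho_R_values, *,
                photons_per_batch: int = 100_000, n_batches: int = 10,
                seed: int = 0, g: float = 0.9, n: float = 1.4,
                n_voxels: int = 256, n_detected_floor: int = 10,
                n_boot: int = 500, engine: str = "kernel",
                progress=None) -> pd.DataFrame:
    """Sensing-depth table over a (mu_a, mu_s', rho_R) grid.

    Each grid point runs a full simulation of the semi-infinite slab
    (2x2x2 cm^3 on an ``n_voxels``^3 grid), collects conversion depths
    of detected Raman photons and reports d75/d90 with bootstrap CIs.
    Points with fewer than ``n_detected_floor`` detected Raman photons
    are flagged unreliable and their metrics withheld (NaN).
    """
    from .phantoms import make_depth_medium
    from .transport import run_simulation

    rows = []
    for mu_a in np.atleast_1d(mu_a_values):
        for mu_sp in np.atleast_1d(mu_s_prime_values):
            for rho in np.atleast_1d(rho_R_values):
                fixture = make_depth_medium(mu_a, mu_sp, rho, g=g, n=n,
                                            n_voxels=n_voxels)
                cfg = fixture.run_config(photons_per_batch, n_batches, seed=seed)
                det = fixture.detector
                res = run_simulation(
                    cfg, engine=engine,
                    batch_filter=lambda df: df[detected_mask(df, det)
                                               & df["has_raman"].to_numpy()],
                )
                depths = res.records["raman_depth_mm"].to_numpy()
                row = {
                    "mu_a_mm^-1": float(mu_a),
                    "mu_s_prime_mm^-1": float(mu_sp),
                    "rho_R": float(rho),
                    "n_detected": int(depths.size),
                    "reliable": bool(depths.size >= n_detected_floor),
                }
                if depths.size >= n_detected_floor:
                    for frac, name in ((0.75, "d75"), (0.90, "d90")):
                        est, lo, hi = bootstrap_sensing_depth(
                            depths, frac, n_boot=n_boot, seed=seed)
                        row[f"{name}_um"] = est * 1e3
                        row[f"{name}_ci_lo_um"] = lo * 1e3
                        row[f"{name}_ci_hi_um"] = hi * 1e3
                else:
                    for name in ("d75", "d90"):
                        row[f"{name}_um"] = np.nan
                        row[f"{name}_ci_lo_um"] = np.nan
                        row[f"{name}_ci_hi_um"] = np.nan
                rows.append(row)
                if progress is not None:
                    progress(row)
    return pd.DataFrame(rows)
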