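"""Wavelength-dependent optical properties of materials.

Scattering follows a decreasing power law, anisotropy and refractive
index are affine in wavelength, and absorption plus the fluorescence /
Raman conversion rates are tabulated spectra.  Conversion rates are
turned into per-event cumulative distribution functions (CDFs) over the
emission wavelength grid; during transport a uniform variate is compared
against a material's CDF to decide whether a photon shifts and to which
grid wavelength.

Units: wavelengths in nm, coefficients in mm^-1, conversion rates and
CDFs dimensionless (probability per event).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "DispersionModel",
    "Material",
    "mu_s_at",
    "g_at",
    "n_at",
    "build_conversion_cdf",
    "interp_spectrum",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength: strictly ascending grid + values >= 0."""

    wavelengths: np.ndarray  # nm, strictly ascending
    values: np.ndarray       # unit depends on context (mm^-1, probability, counts)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size or w.size < 1:
            raise ValueError("spectrum needs matching 1-D grids with >= 1 point")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite and nonnegative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.wavelengths.size


def interp_spectrum(s: Spectrum, lam: float | np.ndarray):
    """Linear interpolation on the grid; queries outside it clamp to end values."""
    if len(s) == 0:  # pragma: no cover - excluded by Spectrum invariant
        raise ValueError("empty spectrum")
    return np.interp(lam, s.wavelengths, s.values)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a two-column CSV (wavelength_nm, value) with header."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
    return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_spectrum_csv(s: Spectrum, path: str | Path, value_name: str = "value") -> None:
    pd.DataFrame({"wavelength_nm": s.wavelengths, value_name: s.values}).to_csv(
        path, index=False, float_format="%.17g"  # full-precision round trip
    )


@dataclass(frozen=True)
class DispersionModel:
    """Empirical dispersion laws for scattering, anisotropy and refractive index.

    mu_s(lam) = a1 * lam**(-a2)   [mm^-1, lam in nm]
    g(lam)    = a3 + a4 * lam     [dimensionless]
    n(lam)    = a5 + a6 * lam     [dimensionless]
    """

    a1: float  # mm^-1 nm^a2, > 0
    a2: float  # >= 0
    a3: float
    a4: float  # nm^-1
    a5: float
    a6: float  # nm^-1

    def __post_init__(self) -> None:
        if not (self.a1 > 0):
            raise ValueError("a1 must be positive")
        if self.a2 < 0:
            raise ValueError("a2 must be nonnegative")

    def validate_band(self, lam_min: float, lam_max: float) -> None:
        """Check 0 <= g < 1 and n >= 1 over the declared operating band."""
        for lam in (lam_min, lam_max):
            g = g_at(self, lam)
            n = n_at(self, lam)
            if not (0.0 <= g < 1.0):
                raise ValueError(f"g({lam} nm) = {g} outside [0, 1)")
            if n < 1.0:
                raise ValueError(f"n({lam} nm) = {n} < 1")


def mu_s_at(model: DispersionModel, lam: float) -> float:
    """Scattering coefficient (mm^-1) at wavelength lam (nm)."""
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    return model.a1 * lam ** (-model.a2)


def g_at(model: DispersionModel, lam: float) -> float:
    return model.a3 + model.a4 * lam


def n_at(model: DispersionModel, lam: float) -> float:
    return model.a5 + model.a6 * lam


def build_conversion_cdf(rate: Spectrum, scale: float = 1.0) -> Spectrum:
    """Cumulative conversion CDF from a nonnegative rate spectrum.

    The CDF is built by discrete summation of ``scale * rate`` over the
    grid (the grid is a set of discrete emission wavelengths, and a
    uniform variate is compared against per-wavelength cumulative mass,
    so only the mass assigned to each grid point matters).  The final
    value is the total per-event probability and must not exceed 1.
    """
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    cdf = np.cumsum(scale * rate.values)
    if cdf.size and cdf[-1] > 1.0 + 1e-12:
        raise ValueError(f"total conversion probability {cdf[-1]} exceeds 1")
    return Spectrum(rate.wavelengths, np.minimum(cdf, 1.0))


@dataclass
class Material:
    """One medium: dispersion (or tabulated overrides) + tabulated spectra.

    ``rho_F`` / ``rho_R`` are the *cumulative* conversion probabilities
    per absorption event / per propagation step, nondecreasing in
    wavelength with final value <= 1.
    """

    id: int
    dispersion: DispersionModel | None = None
    mu_a: Spectrum | None = None
    rho_F: Spectrum | None = None
    rho_R: Spectrum | None = None
    # direct tabulated overrides of the dispersion laws
    mu_s_tab: Spectrum | None = None
    g_tab: Spectrum | None = None
    n_tab: Spectrum | None = None

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError("material id must be a positive integer (0 is void)")
        if self.dispersion is None and (
            self.mu_s_tab is None or self.g_tab is None or self.n_tab is None
        ):
            raise ValueError("need a dispersion model or full tabulated mu_s/g/n")
        for name in ("rho_F", "rho_R"):
            s = getattr(self, name)
            if s is not None:
                if np.any(np.diff(s.values) < -1e-15):
                    raise ValueError(f"{name} CDF must be nondecreasing")
                if s.values[-1] > 1.0 + 1e-12:
                    raise ValueError(f"{name} total probability exceeds 1")

    # -- wavelength queries ------------------------------------------------
    def mu_s(self, lam: float) -> float:
        if self.mu_s_tab is not None:
            return float(interp_spectrum(self.mu_s_tab, lam))
        return mu_s_at(self.dispersion, lam)

    def g(self, lam: float) -> float:
        if self.g_tab is not None:
            return float(interp_spectrum(self.g_tab, lam))
        return g_at(self.dispersion, lam)

    def n(self, lam: float) -> float:
        if self.n_tab is not None:
            return float(interp_spectrum(self.n_tab, lam))
        return n_at(self.dispersion, lam)

    def mu_a_at(self, lam: float) -> float:
        if self.mu_a is None:
            return 0.0
        return float(interp_spectrum(self.mu_a, lam))

    # -- config round trip -------------------------------------------------
    def to_config(self, directory: str | Path, prefix: str | None = None) -> dict:
        """Write spectra as CSV next to a JSON-able config section."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        prefix = prefix or f"material_{self.id}"
        cfg: dict = {"id": self.id}
        if self.dispersion is not None:
            d = self.dispersion
            cfg.update(a1=d.a1, a2=d.a2, a3=d.a3, a4=d.a4, a5=d.a5, a6=d.a6)
        for key, attr in [
            ("mu_a_csv", "mu_a"),
            ("rho_F_csv", "rho_F"),
            ("rho_R_csv", "rho_R"),
            ("mu_s_csv", "mu_s_tab"),
            ("g_csv", "g_tab"),
            ("n_csv", "n_tab"),
        ]:
            s = getattr(self, attr)
            if s is not None:
                fname = f"{prefix}_{attr}.csv"
                write_spectrum_csv(s, directory / fname)
                cfg[key] = fname
        return cfg

    @classmethod
    def from_config(cls, cfg: dict, directory: str | Path = ".") -> "Material":
        directory = Path(directory)
        disp = None
        if "a1" in cfg:
            disp = DispersionModel(
                cfg["a1"], cfg["a2"], cfg.get("a3", 0.0), cfg.get("a4", 0.0),
                cfg.get("a5", 1.0), cfg.get("a6", 0.0),
            )

        def load(key, scale_key=None):
            if key not in cfg:
                return None
            s = read_spectrum_csv(directory / cfg[key])
            if scale_key is not None and scale_key in cfg:
                s = build_conversion_cdf(s, cfg[scale_key])
            return s

        return cls(
            id=int(cfg["id"]),
            dispersion=disp,
            mu_a=load("mu_a_csv"),
            rho_F=load("rho_F_csv", "rho_F_scale"),
            rho_R=load("rho_R_csv", "rho_R_scale"),
            mu_s_tab=load("mu_s_csv"),
            g_tab=load("g_csv"),
            n_tab=load("n_csv"),
        )


def materials_to_json(materials: list[Material], path: str | Path) -> None:
    path = Path(path)
    cfg = [m.to_config(path.parent) for m in materials]
    path.write_text(json.dumps({"materials": cfg}, indent=2))
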