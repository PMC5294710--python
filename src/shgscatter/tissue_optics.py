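"""Bulk optical properties of tissue sections and their spectral analysis.

Collimated on-axis transmission through a thin slab gives the scattering
coefficient ``mu_s`` via Beer-Lambert (valid when absorption is negligible,
the usual regime for fibrillar tissue).  Together with the independently
measured anisotropy ``g`` this yields the reduced scattering coefficient

    mu_s' = mu_s * (1 - g)            [cm^-1]

whose spectral dependence follows a Whittle-Matern-motivated power law

    mu_s'(lambda) ~ lambda^(2m - 4)

where the shape factor ``m`` summarises the size distribution of sub-micron
refractive-index fluctuations (larger m <-> larger / more ordered
structures).  This module houses the property containers, the individual
measurement computations, and the log-log least-squares power-law fit.

Units: lengths in cm internally, wavelengths in nm; conversions happen at
the I/O boundary only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OpticalProperties",
    "ScatteringSpectrum",
    "PowerLawFit",
    "reduced_scattering",
    "mu_s_from_transmission",
    "refractive_index_from_tir",
    "fit_power_law",
    "read_scattering_csv",
    "spectrum_from_measurements",
]

#: Wavelengths (nm) at which collimated transmission is measured.
MEASUREMENT_WAVELENGTHS_NM = (390.0, 445.0, 494.0, 535.0, 780.0, 890.0, 988.0, 1070.0)

#: Default reference wavelength (nm) for power-law amplitudes: the shortest
#: measured wavelength, where spectral contrast between tissues is largest.
DEFAULT_REFERENCE_WAVELENGTH_NM = 390.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class OpticalProperties:
    """Per-wavelength bulk optical parameters of a tissue section.

    Parameters
    ----------
    wavelength : float
        Vacuum wavelength in nm.
    n : float
        Bulk refractive index (> 1 for condensed tissue).
    mu_a : float
        Absorption coefficient in cm^-1.  Defaults to 0: absorption is
        negligible compared to scattering in fibrillar tissue.
    mu_s : float
        Scattering coefficient in cm^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection), in (-1, 1).
    """

    wavelength: float
    n: float
    mu_s: float
    g: float
    mu_a: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 1.0:
            raise ValueError(f"refractive index must exceed 1, got {self.n}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be non-negative, got {self.mu_s}")
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be non-negative, got {self.mu_a}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), cm^-1."""
        return reduced_scattering(self.mu_s, self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, cm^-1."""
        return self.mu_a + self.mu_s

    def absorption_negligible(self, ratio: float = 0.01) -> bool:
        """Whether mu_a <= ratio * mu_s (the mu_a << mu_s regime)."""
        return self.mu_a <= ratio * self.mu_s

    def to_json_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength,
            "n": self.n,
            "mu_a_per_cm": self.mu_a,
            "mu_s_per_cm": self.mu_s,
            "g": self.g,
            "mu_s_prime_per_cm": self.mu_s_prime,
        }


@dataclass
class ScatteringSpectrum:
    """Wavelength-resolved reduced scattering coefficient.

    ``wavelengths`` must be strictly increasing (nm); ``mu_s_prime_values``
    are cm^-1.  Optional per-wavelength standard errors enable a weighted
    power-law fit.
    """

    wavelengths: np.ndarray
    mu_s_prime_values: np.ndarray
    standard_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mu_s_prime_values = np.asarray(self.mu_s_prime_values, dtype=float)
        if self.wavelengths.shape != self.mu_s_prime_values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.mu_s_prime_values < 0):
            raise ValueError("mu_s' values must be non-negative")
        if self.standard_errors is not None:
            self.standard_errors = np.asarray(self.standard_errors, dtype=float)
            if self.standard_errors.shape != self.wavelengths.shape:
                raise ValueError("standard_errors length mismatch")

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass
class PowerLawFit:
    """Result of fitting mu_s'(lambda) = amplitude * (lambda/ref)^(2m-4)."""

    m: float
    amplitude: float
    reference_wavelength: float
    residual_norm: float

    @property
    def exponent(self) -> float:
        """Spectral slope 2m - 4 implied by the shape factor."""
        return 2.0 * self.m - 4.0

    def predict(self, wavelengths: Sequence[float] | np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        return self.amplitude * (lam / self.reference_wavelength) ** self.exponent

    def to_json_dict(self) -> dict:
        return {
            "m_shape": self.m,
            "amplitude_per_cm": self.amplitude,
            "reference_wavelength_nm": self.reference_wavelength,
            "residual_norm": self.residual_norm,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Measurement computations
# ---------------------------------------------------------------------------

def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient mu_s' = mu_s (1 - g), cm^-1.

    The similarity relation merges scatterer density (mu_s) and the
    forward-peakedness of single scattering (g) into the transport-relevant
    coefficient.
    """
    if mu_s < 0:
        raise ValueError(f"mu_s must be non-negative, got {mu_s}")
    if not -1.0 < g < 1.0:
        raise ValueError(f"anisotropy g must lie in (-1, 1), got {g}")
    return mu_s * (1.0 - g)


def mu_s_from_transmission(transmitted_fraction: float, thickness: float) -> float:
    """Scattering coefficient from collimated on-axis transmission.

    Beer-Lambert: T = exp(-mu_s t) when mu_a << mu_s, so any photon removed
    from the collimated beam was removed by scattering.

    Parameters
    ----------
    transmitted_fraction : float
        On-axis transmitted intensity ratio, in (0, 1].
    thickness : float
        Slab thickness in cm.
    """
    if not 0.0 < transmitted_fraction <= 1.0:
        raise ValueError(
            f"transmitted fraction must be in (0, 1], got {transmitted_fraction}"
        )
    if thickness <= 0:
        raise ValueError(f"thickness must be positive, got {thickness}")
    return -math.log(transmitted_fraction) / thickness


def refractive_index_from_tir(critical_angle: float, n_reference: float) -> float:
    """Bulk refractive index from a total-internal-reflection threshold.

    With the sample against a higher-index reference medium, Snell's law at
    the critical angle gives n_sample = n_reference * sin(theta_c).
    """
    if not 0.0 < critical_angle <= math.pi / 2.0:
        raise ValueError(
            f"critical angle must be in (0, pi/2], got {critical_angle}"
        )
    if n_reference <= 1.0:
        raise ValueError(f"n_reference must exceed 1, got {n_reference}")
    n_sample = n_reference * math.sin(critical_angle)
    if n_sample > n_reference:
        raise ValueError("impossible geometry: sample index above reference")
    return n_sample


def fit_power_law(
    spectrum: ScatteringSpectrum,
    reference_wavelength: float = DEFAULT_REFERENCE_WAVELENGTH_NM,
    weighted: bool = False,
) -> PowerLawFit:
    """Fit the scattering power law mu_s'(lambda) ~ lambda^(2m-4).

    Linear least squares of ln mu_s' against ln lambda; the slope ``s`` maps
    to the shape factor m = (s + 4) / 2.  Exact for noise-free power-law
    data.  When ``weighted`` is true and per-wavelength standard errors are
    present, points are weighted by the inverse variance of ln mu_s'
    (delta-method: sigma_ln ~= sigma / mu_s').  Unweighted is the default:
    variance estimates from the usual three measurement locations are too
    noisy to weight by without destabilizing the slope.

    Returns
    -------
    PowerLawFit
        With the amplitude evaluated at ``reference_wavelength`` and
        ``residual_norm`` the RMS residual in log space.
    """
    if len(spectrum) < 3:
        raise ValueError("power-law fit needs at least 3 wavelengths")
    y = spectrum.mu_s_prime_values
    if np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive mu_s' values")
    x = np.log(spectrum.wavelengths / reference_wavelength)
    ly = np.log(y)
    if weighted and spectrum.standard_errors is not None:
        w = (y / spectrum.standard_errors) ** 2
    else:
        w = np.ones_like(ly)
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * ly) / W
    slope = np.sum(w * (x - xbar) * (ly - ybar)) / np.sum(w * (x - xbar) ** 2)
    intercept = ybar - slope * xbar
    resid = ly - (intercept + slope * x)
    residual_norm = float(np.sqrt(np.mean(resid**2)))
    return PowerLawFit(
        m=float((slope + 4.0) / 2.0),
        amplitude=float(np.exp(intercept)),
        reference_wavelength=float(reference_wavelength),
        residual_norm=residual_norm,
    )


# ---------------------------------------------------------------------------
# I/O boundary
# ---------------------------------------------------------------------------

def read_scattering_csv(path) -> pd.DataFrame:
    """Read a scattering-measurement table.

    Expected columns: ``sample_id``, ``wavelength_nm``,
    ``transmitted_fraction``, ``thickness_um``; optional
    ``critical_angle_deg`` and ``n_reference``, and optional ``g``.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "wavelength_nm", "transmitted_fraction", "thickness_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scattering CSV missing columns: {sorted(missing)}")
    return df


def spectrum_from_measurements(
    df: pd.DataFrame, g: float | None = None, sample_id=None
) -> ScatteringSpectrum:
    """Build a reduced-scattering spectrum from transmission measurements.

    Each row yields mu_s via Beer-Lambert; g (from the ``g`` column or the
    argument) converts to mu_s'.  Rows are averaged per wavelength when a
    sample was measured at several locations.
    """
    if sample_id is not None:
        df = df[df["sample_id"] == sample_id]
    if df.empty:
        raise ValueError("no measurement rows selected")
    records = []
    for _, row in df.iterrows():
        g_row = row["g"] if "g" in df.columns and not pd.isna(row.get("g")) else g
        if g_row is None:
            raise ValueError("anisotropy g required (column or argument)")
        mu_s = mu_s_from_transmission(
            float(row["transmitted_fraction"]), float(row["thickness_um"]) * 1e-4
        )
        records.append((float(row["wavelength_nm"]), reduced_scattering(mu_s, g_row)))
    tab = pd.DataFrame(records, columns=["wl", "msp"]).groupby("wl")["msp"]
    mean = tab.mean()
    counts = tab.count()
    sem = tab.sem()
    se = sem.to_numpy() if (counts > 1).all() else None
    return ScatteringSpectrum(
        wavelengths=mean.index.to_numpy(),
        mu_s_prime_values=mean.to_numpy(),
        standard_errors=se,
    )
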