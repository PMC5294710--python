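"""Inversion of measured depth responses into intrinsic SHG parameters.

The measured F/B-vs-depth curve mixes the intrinsic emission
directionality F_SHG/B_SHG with the scattering of SHG photons en route to
the detectors.  The intrinsic ratio is recovered by simulating the depth
response for a grid of candidate ratios under the sample's measured
optical properties and taking the chi-square best fit; the relative SHG
conversion efficiency is then the least-squares scale factor between the
measured absolute forward curve and a per-unit-efficiency simulation that
re-uses the fitted ratio.  Simulation libraries are cached in lookup
tables keyed by a fingerprint of the optical/geometric/numerical
configuration.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .depth_profiles import DepthResponse
from .photon_transport import (
    DepthResponseSim,
    DetectionGeometry,
    EmissionParams,
    SimulationConfig,
    TissueSlab,
    simulate_depth_response,
    simulation_fingerprint,
)
from .tissue_optics import OpticalProperties

logger = logging.getLogger(__name__)

__all__ = [
    "FBLookupTable",
    "ExtractionResult",
    "EfficiencyFit",
    "default_fb_grid",
    "build_fb_lookup",
    "extract_fb",
    "extract_conversion_efficiency",
    "extract_emission",
    "normalize_efficiency_table",
    "wavelength_sweep",
    "interpolate_properties",
]

#: Acceptance threshold on the chi-square goodness-of-fit p-value.
CHI2_ACCEPT_PVALUE = 0.05


def default_fb_grid() -> np.ndarray:
    """Intrinsic F/B candidate grid: 0.25 to 16 in 33 log-spaced steps."""
    return np.geomspace(0.25, 16.0, 33)


# ---------------------------------------------------------------------------
# Lookup tables
# ---------------------------------------------------------------------------

@dataclass
class FBLookupTable:
    """Library of simulated depth responses over a grid of F/B candidates.

    All entries share one (slab, geometry, config) fingerprint so a table
    can be cached and reused across samples with the same measured
    optical properties.
    """

    candidate_fb_values: np.ndarray
    responses: list[DepthResponseSim]
    fingerprint: str
    excitation_wavelength: float

    def __post_init__(self) -> None:
        self.candidate_fb_values = np.asarray(self.candidate_fb_values, dtype=float)
        if self.candidate_fb_values.size == 0:
            raise ValueError("empty candidate grid")
        if np.any(self.candidate_fb_values <= 0):
            raise ValueError("F/B candidates must be positive")
        if self.candidate_fb_values.size > 1 and np.any(
            np.diff(self.candidate_fb_values) <= 0
        ):
            raise ValueError("F/B candidates must be strictly increasing")
        if len(self.responses) != self.candidate_fb_values.size:
            raise ValueError("one response required per candidate")

    def to_dir(self, directory) -> None:
        """Persist as one CSV per candidate plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, resp in enumerate(self.responses):
            resp.to_frame().to_csv(directory / f"candidate_{i:03d}.csv", index=False)
        manifest = {
            "fingerprint": self.fingerprint,
            "excitation_wavelength_nm": self.excitation_wavelength,
            "candidate_fb_values": [float(v) for v in self.candidate_fb_values],
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_dir(cls, directory) -> "FBLookupTable":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        responses = []
        for i in range(len(manifest["candidate_fb_values"])):
            df = pd.read_csv(directory / f"candidate_{i:03d}.csv")
            responses.append(
                DepthResponseSim(
                    depths=df["depth_um"].to_numpy() * 1e-4,
                    forward_detected=df["forward"].to_numpy(),
                    backward_detected=df["backward"].to_numpy(),
                    measured_fb=df["fb_ratio"].to_numpy(),
                    normalized_forward=df["normalized_forward"].to_numpy(),
                )
            )
        return cls(
            candidate_fb_values=np.asarray(manifest["candidate_fb_values"]),
            responses=responses,
            fingerprint=manifest["fingerprint"],
            excitation_wavelength=manifest["excitation_wavelength_nm"],
        )


@dataclass
class ExtractionResult:
    """Best-fit intrinsic emission parameters at one excitation wavelength."""

    excitation_wavelength: float
    intrinsic_fb: float
    fb_uncertainty: float
    chi_square: float
    chi_square_pvalue: float
    accepted: bool
    relative_efficiency: float | None = None
    efficiency_shape_residual: float | None = None


@dataclass
class EfficiencyFit:
    """Least-squares conversion-efficiency scale with shape diagnostics."""

    efficiency: float
    shape_residual_rms: float


def build_fb_lookup(
    slab: TissueSlab,
    geometry: DetectionGeometry,
    config: SimulationConfig,
    fb_grid: Sequence[float] | np.ndarray | None = None,
    excitation_wavelength: float | None = None,
) -> FBLookupTable:
    """Simulate the depth response for every candidate intrinsic F/B.

    Every candidate uses the identical seed policy (common random
    numbers), so the chi-square surface over candidates is smooth rather
    than dominated by independent Monte Carlo noise.
    """
    fb_grid = default_fb_grid() if fb_grid is None else np.asarray(fb_grid, float)
    if excitation_wavelength is None:
        # largest wavelength whose half is also present = excitation
        wavelengths = sorted(slab.properties_by_wavelength)
        candidates = [w for w in wavelengths if w / 2.0 in slab.properties_by_wavelength]
        if not candidates:
            raise KeyError("slab lacks a matched excitation/SHG wavelength pair")
        excitation_wavelength = candidates[-1]
    responses = [
        simulate_depth_response(
            slab,
            EmissionParams(excitation_wavelength, float(fb), 1.0),
            geometry,
            config,
        )
        for fb in fb_grid
    ]
    return FBLookupTable(
        candidate_fb_values=fb_grid,
        responses=responses,
        fingerprint=simulation_fingerprint(slab, geometry, config),
        excitation_wavelength=float(excitation_wavelength),
    )


# ---------------------------------------------------------------------------
# F/B extraction
# ---------------------------------------------------------------------------

def _fb_sigma(measured: DepthResponse) -> np.ndarray:
    """Per-depth standard deviation of the measured F/B ratio.

    Uses replicate-field SEMs when available; otherwise propagates Poisson
    statistics of the two channel intensities:
    var(F/B) = (F/B)^2 (1/F + 1/B).
    """
    fb = measured.fb_ratio
    if measured.fb_se is not None and np.all(np.nan_to_num(measured.fb_se) > 0):
        return measured.fb_se
    with np.errstate(divide="ignore", invalid="ignore"):
        var = fb**2 * (1.0 / measured.forward + 1.0 / measured.backward)
    sigma = np.sqrt(var)
    sigma = np.where(np.isfinite(sigma) & (sigma > 0), sigma, np.nan)
    return sigma


def _interp_sim_curve(sim: DepthResponseSim, depths_um: np.ndarray, which: str) -> np.ndarray:
    sim_depths_um = sim.depths * 1e4
    lo, hi = sim_depths_um.min(), sim_depths_um.max()
    if depths_um.min() < lo - 1e-9 or depths_um.max() > hi + 1e-9:
        raise ValueError(
            f"measured depths [{depths_um.min()}, {depths_um.max()}] um exceed "
            f"the simulated span [{lo}, {hi}] um"
        )
    y = {"fb": sim.measured_fb, "forward": sim.forward_detected,
         "normalized_forward": sim.normalized_forward}[which]
    return np.interp(depths_um, sim_depths_um, y)


def _chi_square(measured: DepthResponse, sim: DepthResponseSim) -> float:
    """Pearson-style chi-square between measured and simulated F/B curves.

    The variance is the sum of the measurement variance (replicate SEMs or
    Poisson propagation) and the simulation's own Monte Carlo variance,
    estimated by Poisson propagation of the simulated channel weights —
    without the latter term a finite-photon library can never "fit" a
    high-count measurement.
    """
    fb_sim = _interp_sim_curve(sim, measured.depths, "fb")
    sigma = _fb_sigma(measured)
    f_sim = _interp_sim_curve(sim, measured.depths, "forward")
    b_sim = np.interp(measured.depths, sim.depths * 1e4, sim.backward_detected)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_sim = fb_sim**2 * (1.0 / f_sim + 1.0 / b_sim)
    var_sim = np.where(np.isfinite(var_sim), var_sim, np.inf)
    var_tot = np.nan_to_num(sigma, nan=np.inf) ** 2 + var_sim
    ok = (
        np.isfinite(measured.fb_ratio)
        & np.isfinite(fb_sim)
        & np.isfinite(var_tot)
        & (var_tot > 0)
    )
    if not np.any(ok):
        raise ValueError("no usable depth points for the chi-square")
    resid = (measured.fb_ratio[ok] - fb_sim[ok]) / np.sqrt(var_tot[ok])
    return float(np.sum(resid**2))


def extract_fb(measured: DepthResponse, table: FBLookupTable) -> ExtractionResult:
    """Best-fit intrinsic F/B by chi-square over the candidate library.

    The statistic is Sum_i (FB_meas,i - FB_sim,i)^2 / sigma_i^2 with
    per-depth sigmas from replicate fields when available, else Poisson
    propagation.  ``accepted`` mirrors a chi-square equivalence test:
    p-value >= 0.05 with dof = n_points - 1.  The uncertainty is the
    half-width of the contiguous candidate neighborhood within +1 of the
    minimum chi-square (the 68% confidence increment for one parameter).
    Exact ties report the lower candidate and widen the uncertainty to
    cover both.
    """
    if len(table.responses) == 0:
        raise RuntimeError("empty lookup table")
    chi2 = np.array([_chi_square(measured, r) for r in table.responses])
    best = int(np.argmin(chi2))  # argmin takes the first (lowest F/B) on ties
    chi2_min = float(chi2[best])
    ties = np.flatnonzero(chi2 == chi2_min)

    # contiguous neighborhood with chi2 <= chi2_min + 1
    lo = best
    while lo > 0 and chi2[lo - 1] <= chi2_min + 1.0:
        lo -= 1
    hi = max(best, int(ties[-1]))
    while hi < chi2.size - 1 and chi2[hi + 1] <= chi2_min + 1.0:
        hi += 1
    fb_vals = table.candidate_fb_values
    uncertainty = 0.5 * (fb_vals[hi] - fb_vals[lo])

    n_points = int(np.sum(np.isfinite(measured.fb_ratio)))
    dof = max(n_points - 1, 1)
    pvalue = float(stats.chi2.sf(chi2_min, dof))
    return ExtractionResult(
        excitation_wavelength=table.excitation_wavelength,
        intrinsic_fb=float(fb_vals[best]),
        fb_uncertainty=float(uncertainty),
        chi_square=chi2_min,
        chi_square_pvalue=pvalue,
        accepted=pvalue >= CHI2_ACCEPT_PVALUE,
    )


def extract_conversion_efficiency(
    measured: DepthResponse,
    slab: TissueSlab,
    geometry: DetectionGeometry,
    config: SimulationConfig,
    fitted_fb: float,
    excitation_wavelength: float | None = None,
) -> EfficiencyFit:
    """Relative SHG conversion efficiency from the forward attenuation.

    Simulates the expected detected forward curve per unit conversion
    efficiency (using the already-extracted intrinsic F/B and the optical
    properties at both wavelengths) and returns the least-squares scale
    factor between the measured absolute forward curve and that
    simulation.  The normalized curves' RMS mismatch is reported as a
    shape diagnostic.  Only ratios of efficiencies between samples are
    physically meaningful; the absolute scale folds in the detection
    calibration.
    """
    if excitation_wavelength is None:
        wavelengths = sorted(slab.properties_by_wavelength)
        candidates = [w for w in wavelengths if w / 2.0 in slab.properties_by_wavelength]
        if not candidates:
            raise KeyError("slab lacks a matched excitation/SHG wavelength pair")
        excitation_wavelength = candidates[-1]
    sim = simulate_depth_response(
        slab,
        EmissionParams(float(excitation_wavelength), float(fitted_fb), 1.0),
        geometry,
        config,
    )
    s = _interp_sim_curve(sim, measured.depths, "forward")
    m = measured.forward
    denom = float(np.sum(s * s))
    if denom <= 0:
        raise ValueError("simulated forward curve is identically zero")
    efficiency = float(np.sum(m * s) / denom)
    if np.max(m) > 0 and np.max(s) > 0:
        shape_resid = float(
            np.sqrt(np.mean((m / np.max(m) - s / np.max(s)) ** 2))
        )
    else:
        shape_resid = float("nan") if np.max(m) > 0 else 0.0
    return EfficiencyFit(efficiency=efficiency, shape_residual_rms=shape_resid)


def extract_emission(
    measured: DepthResponse,
    slab: TissueSlab,
    geometry: DetectionGeometry,
    config: SimulationConfig,
    fb_grid: Sequence[float] | None = None,
    table: FBLookupTable | None = None,
    refine: bool = False,
    excitation_wavelength: float | None = None,
) -> ExtractionResult:
    """One-call F/B + efficiency extraction, with optional grid refinement.

    When ``refine`` is set, a second candidate pass at half the grid step
    around the coarse minimum sharpens the F/B estimate.
    """
    if table is None:
        table = build_fb_lookup(slab, geometry, config, fb_grid, excitation_wavelength)
    result = extract_fb(measured, table)
    if refine:
        fb_vals = table.candidate_fb_values
        i = int(np.argmin(np.abs(fb_vals - result.intrinsic_fb)))
        lo = fb_vals[max(i - 1, 0)]
        hi = fb_vals[min(i + 1, fb_vals.size - 1)]
        fine = np.unique(np.geomspace(lo, hi, 5))
        fine_table = build_fb_lookup(
            slab, geometry, config, fine, table.excitation_wavelength
        )
        fine_result = extract_fb(measured, fine_table)
        if fine_result.chi_square <= result.chi_square:
            result = fine_result
    eff = extract_conversion_efficiency(
        measured, slab, geometry, config, result.intrinsic_fb,
        table.excitation_wavelength,
    )
    result.relative_efficiency = eff.efficiency
    result.efficiency_shape_residual = eff.shape_residual_rms
    return result


# ---------------------------------------------------------------------------
# Efficiency table normalization and the wavelength sweep
# ---------------------------------------------------------------------------

def normalize_efficiency_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize a per-sample x per-wavelength efficiency table.

    Divides every entry by the global maximum so the brightest
    sample/wavelength cell becomes exactly 1 (absolute conversion
    efficiencies are not obtainable; only the relative pattern matters).
    """
    if table.size == 0:
        raise ValueError("empty efficiency table")
    values = table.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("efficiencies must be non-negative")
    peak = np.nanmax(values)
    if not peak > 0:
        raise ValueError("degenerate normalization: all-zero efficiency table")
    return table / peak


def interpolate_properties(
    props_by_wavelength: Mapping[float, OpticalProperties], wavelength: float
) -> OpticalProperties:
    """Optical properties at an arbitrary wavelength.

    mu_s is interpolated log-linearly in lambda (consistent with power-law
    scattering); g, n, and mu_a linearly.  Outside the measured range the
    nearest trend is extrapolated.
    """
    wls = np.array(sorted(props_by_wavelength))
    if wls.size < 2:
        raise ValueError("need at least two measured wavelengths to interpolate")
    props = [props_by_wavelength[w] for w in wls]
    x = np.log(wls)
    xq = math.log(wavelength)

    def lin(vals):
        return float(np.interp(xq, x, vals))

    def lin_extrap(vals):
        if xq < x[0]:
            slope = (vals[1] - vals[0]) / (x[1] - x[0])
            return float(vals[0] + slope * (xq - x[0]))
        if xq > x[-1]:
            slope = (vals[-1] - vals[-2]) / (x[-1] - x[-2])
            return float(vals[-1] + slope * (xq - x[-1]))
        return lin(vals)

    log_mu_s = np.log([max(p.mu_s, 1e-12) for p in props])
    mu_s = math.exp(lin_extrap(log_mu_s))
    g = float(np.clip(lin_extrap([p.g for p in props]), -0.999, 0.999))
    n = lin_extrap([p.n for p in props])
    mu_a = max(lin_extrap([p.mu_a for p in props]), 0.0)
    return OpticalProperties(wavelength=wavelength, n=n, mu_s=mu_s, g=g, mu_a=mu_a)


def wavelength_sweep(
    responses: Mapping[float, DepthResponse],
    base_properties: Mapping[float, OpticalProperties],
    thickness: float,
    geometry: DetectionGeometry,
    config: SimulationConfig,
    fb_grid: Sequence[float] | None = None,
    refine: bool = False,
) -> dict[float, ExtractionResult]:
    """Extract emission parameters at each measured excitation wavelength.

    Optical properties at each excitation and SHG wavelength are
    interpolated from the measured set.  Wavelengths whose extraction
    fails are skipped with a logged warning, so a partial sweep still
    yields a usable feature vector.
    """
    results: dict[float, ExtractionResult] = {}
    for wl in sorted(responses):
        try:
            slab = TissueSlab(
                thickness=thickness,
                properties_by_wavelength={
                    wl: interpolate_properties(base_properties, wl),
                    wl / 2.0: interpolate_properties(base_properties, wl / 2.0),
                },
            )
            results[wl] = extract_emission(
                responses[wl], slab, geometry, config,
                fb_grid=fb_grid, refine=refine, excitation_wavelength=wl,
            )
        except (KeyError, ValueError) as exc:
            logger.warning("skipping %s nm: %s", wl, exc)
    if not responses:
        logger.warning("empty wavelength list: nothing to extract")
    return results
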