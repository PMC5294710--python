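"""Ground-truth generators for every input the pipeline consumes.

No per-sample ovarian measurements are publicly deposited, so testing and
demonstration run on synthetic data: transmission spectra drawn from a
preset power law, two-channel image stacks whose per-slice totals follow
the Monte Carlo forward model with Poisson pixel noise on a fibrous
texture, and labeled feature cohorts for the classifier.  Five built-in
tissue presets (normal, benign, LGS, endometrioid, HGS) encode the
qualitative between-tissue orderings of the published study — HGS the
strongest scatterer and most efficient SHG converter with the lowest
emission directionality, benign the highest directionality and lowest
shape factor, endometrioid the weakest scatterer — with numeric anchors
that are package constants, not measured data.  Every generator writes
its ground truth alongside its data and is deterministic under a fixed
seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .depth_profiles import ImageStackPair
from .photon_transport import (
    DetectionGeometry,
    EmissionParams,
    SimulationConfig,
    TissueSlab,
    simulate_depth_response,
)
from .tissue_optics import OpticalProperties

__all__ = [
    "TissuePreset",
    "SyntheticSample",
    "builtin_presets",
    "generate_scattering_measurements",
    "generate_depth_stacks",
    "generate_feature_cohort",
    "write_sample",
]

#: Excitation wavelengths of the SHG sweep (nm).
EXCITATION_GRID = (780.0, 890.0, 988.0, 1070.0, 1160.0)

#: Wavelengths of the collimated-transmission measurements (nm).
SCATTERING_GRID = (390.0, 445.0, 494.0, 535.0, 780.0, 890.0, 988.0, 1070.0)

#: Wavelength range used for the shape-factor fit (nm): the SHG band.
M_FIT_RANGE = (390.0, 535.0)

#: Default fractional noise of a collimated transmission reading.
DEFAULT_TRANSMISSION_NOISE_CV = 0.02

#: Default measurement locations per specimen.
DEFAULT_N_LOCATIONS = 3

#: Forward/backward detector gain ratio baked into generated stacks.
DEFAULT_DETECTOR_CALIBRATION = 1.5


@dataclass
class TissuePreset:
    """Ground-truth description of one synthetic tissue type.

    ``mus_prime_390`` anchors the reduced-scattering power law
    mu_s'(lambda) = mus_prime_390 (lambda/390)^(2m-4); ``fb_curve`` and
    ``efficiency_curve`` give the intrinsic emission directionality and
    relative conversion efficiency per excitation wavelength.
    """

    name: str
    m_shape: float
    mus_prime_390: float  # cm^-1
    g: float
    n: float
    fb_curve: Mapping[float, float]
    efficiency_curve: Mapping[float, float]
    thickness_um: float = 100.0

    def __post_init__(self) -> None:
        if self.mus_prime_390 <= 0 or self.m_shape <= 0 or self.thickness_um <= 0:
            raise ValueError("preset parameters must be positive")
        self.fb_curve = dict(self.fb_curve)
        self.efficiency_curve = dict(self.efficiency_curve)

    def mu_s_prime(self, wavelength: float) -> float:
        """Reduced scattering at a wavelength from the preset power law."""
        return self.mus_prime_390 * (wavelength / 390.0) ** (2.0 * self.m_shape - 4.0)

    def mu_s(self, wavelength: float) -> float:
        return self.mu_s_prime(wavelength) / (1.0 - self.g)

    def optical_properties(self, wavelength: float) -> OpticalProperties:
        return OpticalProperties(
            wavelength=wavelength, n=self.n, mu_s=self.mu_s(wavelength), g=self.g
        )

    def slab(self, excitation_wavelength: float) -> TissueSlab:
        """Slab with properties at the excitation and SHG wavelengths."""
        return TissueSlab(
            thickness=self.thickness_um * 1e-4,
            properties_by_wavelength={
                excitation_wavelength: self.optical_properties(excitation_wavelength),
                excitation_wavelength / 2.0: self.optical_properties(
                    excitation_wavelength / 2.0
                ),
            },
        )

    def ground_truth_dict(self) -> dict:
        return {
            "name": self.name,
            "m_shape": self.m_shape,
            "mus_prime_390_per_cm": self.mus_prime_390,
            "g": self.g,
            "n": self.n,
            "fb_curve": {str(k): v for k, v in self.fb_curve.items()},
            "efficiency_curve": {str(k): v for k, v in self.efficiency_curve.items()},
            "thickness_um": self.thickness_um,
        }


@dataclass
class SyntheticSample:
    """Paths and ground truth of one generated sample directory."""

    preset_name: str
    seed: int
    directory: Path
    stack_paths: dict
    transmission_csv: Path
    ground_truth_json: Path


def builtin_presets() -> dict[str, TissuePreset]:
    """The five tissue presets.

    Shape factors m follow the published per-tissue fits (benign 1.01 <
    HGS 1.17 < normal 1.32 < endometrioid 1.40 ~ LGS 1.41).  Scattering
    anchors put HGS highest and endometrioid lowest; intrinsic F/B rises
    with wavelength for every tissue, most weakly for HGS, and at 988 nm
    orders benign > LGS > normal > endometrioid > HGS; conversion
    efficiency peaks for HGS (maximum at 890 nm) and falls with
    wavelength for HGS while rising for the others, most steeply for LGS.
    The numeric anchors are synthetic package constants chosen to honor
    those orderings.
    """
    ex = EXCITATION_GRID

    def curve(vals):
        return dict(zip(ex, vals))

    presets = {
        "normal": TissuePreset(
            name="normal", m_shape=1.32, mus_prime_390=22.0, g=0.90, n=1.40,
            fb_curve=curve([2.8, 3.6, 4.4, 5.2, 6.0]),
            efficiency_curve=curve([0.30, 0.33, 0.36, 0.40, 0.44]),
        ),
        "benign": TissuePreset(
            name="benign", m_shape=1.01, mus_prime_390=19.0, g=0.90, n=1.40,
            fb_curve=curve([5.0, 6.5, 8.0, 9.5, 11.0]),
            efficiency_curve=curve([0.26, 0.30, 0.34, 0.38, 0.42]),
        ),
        "LGS": TissuePreset(
            name="LGS", m_shape=1.41, mus_prime_390=16.5, g=0.90, n=1.40,
            fb_curve=curve([3.5, 4.8, 6.0, 7.2, 8.5]),
            efficiency_curve=curve([0.20, 0.28, 0.38, 0.50, 0.62]),
        ),
        "endometrioid": TissuePreset(
            name="endometrioid", m_shape=1.40, mus_prime_390=11.0, g=0.90, n=1.40,
            fb_curve=curve([2.2, 2.7, 3.1, 3.5, 3.9]),
            efficiency_curve=curve([0.24, 0.27, 0.30, 0.33, 0.36]),
        ),
        "HGS": TissuePreset(
            name="HGS", m_shape=1.17, mus_prime_390=30.0, g=0.90, n=1.40,
            fb_curve=curve([1.8, 2.0, 2.2, 2.4, 2.6]),
            efficiency_curve=curve([0.95, 1.00, 0.90, 0.80, 0.72]),
        ),
    }
    return presets


# ---------------------------------------------------------------------------
# Scattering measurements
# ---------------------------------------------------------------------------

def generate_scattering_measurements(
    preset: TissuePreset,
    wavelengths: Sequence[float] = SCATTERING_GRID,
    noise_cv: float = DEFAULT_TRANSMISSION_NOISE_CV,
    seed: int = 0,
    n_locations: int = DEFAULT_N_LOCATIONS,
    thickness_um: float = 50.0,
    sample_id: str = "synthetic",
) -> pd.DataFrame:
    """Synthetic collimated-transmission rows for one specimen.

    Each row: T = exp(-mu_s t) times multiplicative log-normal noise with
    coefficient of variation ``noise_cv`` (mean-one), one row per
    wavelength per measurement location (thin 50-um sections, as used for
    the scattering measurements).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    t_cm = thickness_um * 1e-4
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    rows = []
    for wl in wavelengths:
        if not 200.0 <= wl <= 1300.0:
            _warnings.warn(f"wavelength {wl} nm outside the 200-1300 nm range")
        mu_s = preset.mu_s(wl)
        t_clean = math.exp(-mu_s * t_cm)
        for loc in range(n_locations):
            noise = (
                math.exp(sigma * rng.standard_normal() - sigma**2 / 2.0)
                if sigma > 0
                else 1.0
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "location": loc,
                    "wavelength_nm": wl,
                    "transmitted_fraction": min(t_clean * noise, 1.0),
                    "thickness_um": thickness_um,
                    "g": preset.g,
                    "n": preset.n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def _fiber_texture(shape, rng, orientation_deg=30.0, sigma=2.0):
    """Oriented band-pass filtered noise as a lightweight fiber surrogate.

    Mean-one positive field; sufficient for intensity-integral and
    diameter-phantom purposes, not a biophysical fiber model.
    """
    noise = rng.standard_normal(shape)
    smooth_along = (sigma * 3.0, sigma * 0.8)
    tex = ndimage.gaussian_filter(noise, smooth_along)
    tex = ndimage.rotate(tex, orientation_deg, reshape=False, mode="reflect")
    tex = tex - tex.min() + 0.25
    return tex / tex.mean()


def generate_depth_stacks(
    preset: TissuePreset,
    excitation_wavelength: float,
    image_shape: tuple[int, int] = (32, 32),
    z_step_um: float = 10.0,
    photon_scale: float = 2.0e5,
    seed: int = 0,
    geometry: DetectionGeometry | None = None,
    n_photons: int = 20_000,
    detector_calibration: float = DEFAULT_DETECTOR_CALIBRATION,
) -> tuple[ImageStackPair, dict]:
    """Synthetic two-channel image stack for one field of view.

    Per-slice expected channel totals come from the Monte Carlo forward
    model under the preset's ground truth (intrinsic F/B, efficiency,
    optical properties at both wavelengths); pixel intensities are Poisson
    draws around a fibrous texture scaled to those totals, and the forward
    channel carries the detector gain ratio, recorded in the returned
    ground-truth dict.

    ``photon_scale`` converts the per-launched-photon detected fraction
    into expected detected photon counts per slice.
    """
    if photon_scale <= 0:
        raise ValueError("photon_scale must be positive")
    if z_step_um <= 0:
        raise ValueError("z_step must be positive")
    geometry = geometry or DetectionGeometry()
    rng = np.random.default_rng(seed)

    depths_um = np.arange(0.0, preset.thickness_um + z_step_um / 2.0, z_step_um)
    config = SimulationConfig(
        depth_grid=depths_um * 1e-4,
        n_photons=n_photons,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    fb = preset.fb_curve[excitation_wavelength]
    eff = preset.efficiency_curve[excitation_wavelength]
    sim = simulate_depth_response(
        preset.slab(excitation_wavelength),
        EmissionParams(excitation_wavelength, fb, eff),
        geometry,
        config,
    )
    # expected detected photons per slice
    exp_fwd = photon_scale * sim.forward_detected / config.n_photons
    exp_bwd = photon_scale * sim.backward_detected / config.n_photons

    npix = image_shape[0] * image_shape[1]
    fwd_stack = np.empty((depths_um.size, *image_shape))
    bwd_stack = np.empty_like(fwd_stack)
    for i in range(depths_um.size):
        tex = _fiber_texture(image_shape, rng)
        fwd_stack[i] = rng.poisson(exp_fwd[i] / npix * tex) * detector_calibration
        bwd_stack[i] = rng.poisson(exp_bwd[i] / npix * tex)

    pair = ImageStackPair(
        forward_stack=fwd_stack,
        backward_stack=bwd_stack,
        z_step=z_step_um,
        excitation_wavelength=excitation_wavelength,
        detector_calibration=detector_calibration,
    )
    truth = {
        "preset": preset.ground_truth_dict(),
        "excitation_wavelength_nm": excitation_wavelength,
        "intrinsic_fb": fb,
        "relative_efficiency": eff,
        "photon_scale": photon_scale,
        "detector_calibration": detector_calibration,
        "expected_forward_totals": exp_fwd.tolist(),
        "expected_backward_totals": exp_bwd.tolist(),
        "seed": seed,
    }
    return pair, truth


# ---------------------------------------------------------------------------
# Feature cohorts
# ---------------------------------------------------------------------------

def _preset_feature_vector(preset: TissuePreset) -> dict[str, float]:
    """Named metric vector from preset ground truth.

    Wavelength dependence is encoded as the value at 988 nm plus the
    least-squares slope across the sweep (per 100 nm).
    """
    def slope(curve: Mapping[float, float]) -> float:
        wl = np.array(sorted(curve))
        y = np.array([curve[w] for w in wl])
        return float(np.polyfit(wl / 100.0, y, 1)[0])

    feats = {
        "fb_988": preset.fb_curve[988.0],
        "fb_slope": slope(preset.fb_curve),
        "eff_988": preset.efficiency_curve[988.0],
        "eff_slope": slope(preset.efficiency_curve),
        "m_shape": preset.m_shape,
    }
    for wl in (390.0, 445.0, 494.0, 535.0):
        feats[f"mus_prime_{int(wl)}"] = preset.mu_s_prime(wl)
    return feats


def generate_feature_cohort(
    presets: Mapping[str, TissuePreset],
    n_per_class: int = 4,
    between_class_scale: float = 1.0,
    within_class_cv: float = 0.10,
    seed: int = 0,
):
    """Labeled per-sample feature table drawn around preset ground truth.

    Class means are the preset feature vectors, optionally shrunk toward
    the grand mean by ``between_class_scale`` (0 makes all classes
    identical — the chance-level control); samples get multiplicative
    Gaussian noise with coefficient of variation ``within_class_cv``.
    Per-class RNG streams are derived from (seed, class index), so class
    means and the first draws are stable when n_per_class grows.
    """
    from .classification import FeatureTable

    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    names = list(presets)
    vectors = {nm: _preset_feature_vector(presets[nm]) for nm in names}
    feature_names = list(next(iter(vectors.values())))
    grand = np.mean([[v[f] for f in feature_names] for v in vectors.values()], axis=0)

    rows = []
    for ci, nm in enumerate(names):
        mean = np.array([vectors[nm][f] for f in feature_names])
        mean = grand + between_class_scale * (mean - grand)
        rng = np.random.default_rng([seed, ci])
        for si in range(n_per_class):
            noise = 1.0 + within_class_cv * rng.standard_normal(mean.size)
            row = {"sample_id": f"{nm}_{si}", "tissue_label": nm}
            row.update(dict(zip(feature_names, mean * noise)))
            rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Sample directories
# ---------------------------------------------------------------------------

def write_sample(
    preset: TissuePreset,
    directory,
    seed: int = 0,
    excitation_wavelengths: Sequence[float] = (988.0,),
    **stack_kwargs,
) -> SyntheticSample:
    """Emit a complete synthetic sample directory.

    Contents: per-wavelength forward/backward TIFF stacks, a YAML
    manifest, the transmission CSV, and the ground-truth JSON.
    """
    import tifffile
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack_paths = {}
    truths = {}
    manifest_stacks = []
    for wi, wl in enumerate(excitation_wavelengths):
        pair, truth = generate_depth_stacks(
            preset, wl, seed=seed + 1000 * wi, **stack_kwargs
        )
        fpath = directory / f"forward_{int(wl)}nm.tif"
        bpath = directory / f"backward_{int(wl)}nm.tif"
        tifffile.imwrite(
            fpath, pair.forward_stack.astype(np.float32), photometric="minisblack"
        )
        tifffile.imwrite(
            bpath, pair.backward_stack.astype(np.float32), photometric="minisblack"
        )
        stack_paths[wl] = {"forward": fpath, "backward": bpath}
        truths[str(wl)] = truth
        manifest_stacks.append(
            {
                "excitation_wavelength_nm": float(wl),
                "forward": fpath.name,
                "backward": bpath.name,
                "z_step_um": pair.z_step,
                "detector_calibration": pair.detector_calibration,
            }
        )
    trans = generate_scattering_measurements(
        preset, seed=seed + 77, sample_id=preset.name
    )
    trans_path = directory / "transmission.csv"
    trans.to_csv(trans_path, index=False)
    truth_path = directory / "ground_truth.json"
    truth_path.write_text(json.dumps(truths, indent=2))
    manifest = {
        "sample_id": preset.name,
        "tissue_label": preset.name,
        "seed": seed,
        "stacks": manifest_stacks,
        "transmission_csv": trans_path.name,
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return SyntheticSample(
        preset_name=preset.name,
        seed=seed,
        directory=directory,
        stack_paths=stack_paths,
        transmission_csv=trans_path,
        ground_truth_json=truth_path,
    )
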