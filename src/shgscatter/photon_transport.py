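"""Monte Carlo transport of SHG photons in a turbid tissue slab.

SHG photons are created at the laser focus at a known depth inside a thin
tissue section, directed predominantly forward or backward according to the
intrinsic emission directionality F_SHG/B_SHG set by fibril-scale
phasematching.  On their way out they are multiply scattered, so the ratio
*measured* at the detectors differs from the intrinsic ratio in a
depth-dependent way.  This module is the forward model of that process —
a weighted-photon random walk in the MCML tradition (exponential free
paths, Henyey-Greenstein deflections, Russian-roulette termination,
Fresnel-governed boundaries, NA-bounded angular acceptance at the two
detectors) — used both to generate synthetic depth responses and as the
simulation library against which measured curves are inverted.

Conventions
-----------
z = 0 at the top (objective-side) surface, increasing toward the condenser.
"Forward" detection = exit through the bottom face within the condenser
acceptance cone; "backward" = exit through the top face within the
objective acceptance cone.  Excitation delivery to the focus is ballistic
with SHG generation proportional to intensity squared, i.e. a focal source
weight exp(-2 mu_s,ex z).  All lengths are cm.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tissue_optics import OpticalProperties

__all__ = [
    "TissueSlab",
    "DetectionGeometry",
    "EmissionParams",
    "SimulationConfig",
    "PhotonTally",
    "DepthResponseSim",
    "sample_free_path",
    "sample_hg_deflection",
    "ballistic_focal_weight",
    "propagate_shg_photons",
    "simulate_depth_response",
    "collimated_transmission",
    "normalize_topk",
]

# Roulette defaults follow the classic MCML settings.
ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1

#: Refractive index of the water-immersion / aqueous mounting medium.
N_WATER = 1.33

#: Slices used by the "average maximum" normalization of forward curves.
NORMALIZATION_TOP_K = 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TissueSlab:
    """A homogeneous tissue section with per-wavelength optical properties.

    The sections are thin uniform slabs cut en face, so the model geometry
    is a single homogeneous layer bounded by immersion water above and
    aqueous mounting medium below.
    """

    thickness: float  # cm
    properties_by_wavelength: Mapping[float, OpticalProperties]
    n_surround_top: float = N_WATER
    n_surround_bottom: float = N_WATER

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")
        self.properties_by_wavelength = dict(self.properties_by_wavelength)

    def properties(self, wavelength: float) -> OpticalProperties:
        try:
            return self.properties_by_wavelength[wavelength]
        except KeyError:
            raise KeyError(
                f"no optical properties at {wavelength} nm; available: "
                f"{sorted(self.properties_by_wavelength)}"
            ) from None

    def fingerprint_dict(self) -> dict:
        return {
            "thickness_cm": self.thickness,
            "n_surround_top": self.n_surround_top,
            "n_surround_bottom": self.n_surround_bottom,
            "properties": {
                str(wl): p.to_json_dict()
                for wl, p in sorted(self.properties_by_wavelength.items())
            },
        }


@dataclass
class DetectionGeometry:
    """Numerical apertures of the epi (backward) and trans (forward) paths.

    Acceptance half-angles are defined in the immersion medium:
    sin(theta_acc) = NA / n_immersion.  ``na_excitation`` sets the focusing
    half-angle of the excitation cone, which is also the assumed angular
    half-width of the SHG emission lobes.
    """

    na_backward: float = 0.8
    na_forward: float = 0.9
    n_immersion: float = N_WATER
    na_excitation: float = 0.8

    def __post_init__(self) -> None:
        for na in (self.na_backward, self.na_forward, self.na_excitation):
            if not 0.0 < na < self.n_immersion:
                raise ValueError(
                    f"NA must lie in (0, n_immersion={self.n_immersion}), got {na}"
                )

    def fingerprint_dict(self) -> dict:
        return {
            "na_backward": self.na_backward,
            "na_forward": self.na_forward,
            "n_immersion": self.n_immersion,
            "na_excitation": self.na_excitation,
        }


@dataclass
class EmissionParams:
    """Intrinsic SHG emission parameters at one excitation wavelength."""

    excitation_wavelength: float  # nm
    intrinsic_fb: float  # forward/backward creation ratio, > 0
    relative_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.intrinsic_fb <= 0:
            raise ValueError(f"intrinsic F/B must be positive, got {self.intrinsic_fb}")
        if self.relative_efficiency < 0:
            raise ValueError("relative efficiency must be non-negative")

    @property
    def shg_wavelength(self) -> float:
        """SHG emission wavelength: half the excitation wavelength (nm)."""
        return self.excitation_wavelength / 2.0


@dataclass
class SimulationConfig:
    """Numerical settings of one depth-response simulation."""

    depth_grid: Sequence[float]  # cm
    n_photons: int = 100_000
    rng_seed: int = 0
    roulette_threshold: float = ROULETTE_THRESHOLD
    roulette_survival: float = ROULETTE_SURVIVAL

    def __post_init__(self) -> None:
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        if self.n_photons < 1:
            raise ValueError("n_photons must be at least 1")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette survival must be in (0, 1)")

    def validate_depths(self, slab: TissueSlab) -> None:
        if self.depth_grid.size == 0:
            raise ValueError("depth grid is empty")
        if np.any(self.depth_grid < 0) or np.any(self.depth_grid > slab.thickness):
            raise ValueError("depth grid must lie within [0, slab thickness]")

    def fingerprint_dict(self) -> dict:
        return {
            "depth_grid_cm": [float(d) for d in self.depth_grid],
            "n_photons": int(self.n_photons),
            "rng_seed": int(self.rng_seed),
            "roulette_threshold": self.roulette_threshold,
            "roulette_survival": self.roulette_survival,
        }


@dataclass
class PhotonTally:
    """Weight bookkeeping for one launch batch.

    detected_forward + detected_backward + escaped_undetected + absorbed
    equals launched to floating tolerance: roulette kills and the matching
    survival boosts are both routed through the absorbed sink, so the audit
    is exact rather than exact only in expectation.
    """

    detected_forward: float = 0.0
    detected_backward: float = 0.0
    escaped_undetected: float = 0.0
    absorbed: float = 0.0
    launched: float = 0.0

    def conservation_error(self) -> float:
        """Relative discrepancy of the weight audit."""
        total = (
            self.detected_forward
            + self.detected_backward
            + self.escaped_undetected
            + self.absorbed
        )
        return abs(total - self.launched) / max(self.launched, 1e-300)


@dataclass
class DepthResponseSim:
    """Simulated two-channel response on a focal-depth grid."""

    depths: np.ndarray  # cm
    forward_detected: np.ndarray
    backward_detected: np.ndarray
    measured_fb: np.ndarray
    normalized_forward: np.ndarray
    tallies: list = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_um": self.depths * 1e4,
                "forward": self.forward_detected,
                "backward": self.backward_detected,
                "fb_ratio": self.measured_fb,
                "normalized_forward": self.normalized_forward,
            }
        )


def normalize_topk(curve: np.ndarray, k: int = NORMALIZATION_TOP_K) -> np.ndarray:
    """Self-normalize a curve by the mean of its k largest values.

    The "average maximum" estimator: robust to a single bright outlier
    slice while pinning the curve maximum near 1.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("cannot normalize an empty curve")
    k = min(k, curve.size)
    top = np.sort(curve)[-k:]
    denom = float(np.mean(top))
    if denom <= 0:
        raise ValueError("degenerate normalization: non-positive average maximum")
    return curve / denom


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def sample_free_path(mu_t, uniform_draw):
    """Exponential free path -ln(u)/mu_t (cm); accepts arrays."""
    mu_t_arr = np.asarray(mu_t, dtype=float)
    if np.any(mu_t_arr <= 0):
        raise ValueError("mu_t must be positive")
    u = np.asarray(uniform_draw, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("uniform draw must lie in (0, 1)")
    out = -np.log(u) / mu_t_arr
    if np.isscalar(uniform_draw) and np.isscalar(mu_t):
        return float(out)
    return out


def sample_hg_deflection(g, uniform_draw):
    """Deflection cosine from the Henyey-Greenstein inverse CDF.

    Standard MCML sampling: for g != 0,
        cos(theta) = (1 + g^2 - ((1 - g^2)/(1 - g + 2 g u))^2) / (2 g),
    and the isotropic branch 2u - 1 for g = 0.  Accepts arrays of draws.
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"anisotropy g must lie in (-1, 1), got {g}")
    u = np.asarray(uniform_draw, dtype=float)
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        term = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - term * term) / (2.0 * g)
        out = np.clip(out, -1.0, 1.0)
    if np.isscalar(uniform_draw):
        return float(out)
    return out


def ballistic_focal_weight(
    slab: TissueSlab, depth: float, excitation_wavelength: float
) -> float:
    """Relative SHG source strength at a focal depth.

    Excitation reaches the focus ballistically and SHG is quadratic in the
    excitation intensity, so the source weight decays as
    exp(-2 mu_s(lambda_ex) z).
    """
    if not 0.0 <= depth <= slab.thickness:
        raise ValueError(f"depth {depth} outside slab [0, {slab.thickness}]")
    props = slab.properties(excitation_wavelength)
    return math.exp(-2.0 * props.mu_s * depth)


# ---------------------------------------------------------------------------
# Random-walk kernel
# ---------------------------------------------------------------------------

def _fresnel_reflectance(cos_i: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance for internal incidence cosines.

    Returns 1 beyond the TIR angle.
    """
    if n1 == n2:
        return np.zeros_like(np.asarray(cos_i, dtype=float))
    cos_i = np.clip(np.asarray(cos_i, dtype=float), 0.0, 1.0)
    sin_i = np.sqrt(1.0 - cos_i * cos_i)
    sin_t = n1 / n2 * sin_i
    ok = sin_t < 1.0
    cos_t = np.sqrt(1.0 - np.minimum(sin_t, 1.0) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
        rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
        R = np.where(ok, 0.5 * (rs * rs + rp * rp), 1.0)
    return np.clip(np.nan_to_num(R, nan=1.0), 0.0, 1.0)


def _walk(
    z0: np.ndarray,
    uz0: np.ndarray,
    w0: np.ndarray,
    slab: TissueSlab,
    props: OpticalProperties,
    geometry: DetectionGeometry,
    rng: np.random.Generator,
    roulette_threshold: float = ROULETTE_THRESHOLD,
    roulette_survival: float = ROULETTE_SURVIVAL,
):
    """Random-walk a photon batch to termination.

    Only (z, uz, weight) are tracked: the tally depends on exit face and
    exit angle alone, and the walk is azimuthally symmetric, so the
    marginal direction update
        uz' = uz cos(theta_d) + sqrt(1-uz^2) sin(theta_d) cos(phi)
    is statistically exact.

    Returns (PhotonTally, unscattered_transmitted_weight).
    """
    z = np.array(z0, dtype=float)
    uz = np.array(uz0, dtype=float)
    w = np.array(w0, dtype=float)
    n = z.size
    n_scat = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)

    mu_s, mu_a, g, n_tis = props.mu_s, props.mu_a, props.g, props.n
    mu_t = mu_s + mu_a
    transparent = mu_t <= 0.0
    thickness = slab.thickness
    sin_acc_f = geometry.na_forward / geometry.n_immersion
    sin_acc_b = geometry.na_backward / geometry.n_immersion

    tally = PhotonTally(launched=float(np.sum(w)))
    unscattered_transmitted = 0.0

    for _ in range(100_000):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        zi = z[idx].copy()
        uzi = uz[idx].copy()
        wi = w[idx].copy()
        nsi = n_scat[idx].copy()
        live = np.ones(idx.size, dtype=bool)

        if transparent:
            # geometric flight to a face; direction-less photons cannot exit
            stuck = np.abs(uzi) < 1e-12
            tally.escaped_undetected += float(np.sum(wi[stuck]))
            live[stuck] = False
            step = np.full(idx.size, np.inf)
        else:
            step = -np.log(rng.random(idx.size)) / mu_t

        # Flight with boundary handling: reflected photons keep the unused
        # remainder of the sampled step (MCML convention).
        for _bounce in range(400):
            lm = np.flatnonzero(live & (step > 0))
            if lm.size == 0:
                break
            with np.errstate(invalid="ignore"):
                z_new = zi[lm] + step[lm] * uzi[lm]
            hit_top = z_new < 0.0
            hit_bot = z_new > thickness
            interior = ~(hit_top | hit_bot)
            zi[lm[interior]] = z_new[interior]
            step[lm[interior]] = 0.0
            hits = lm[~interior]
            if hits.size == 0:
                break
            is_top = hit_top[~interior]
            boundary_z = np.where(is_top, 0.0, thickness)
            d = (boundary_z - zi[hits]) / uzi[hits]
            step[hits] = np.where(
                np.isfinite(step[hits]), step[hits] - d, np.inf
            )
            zi[hits] = boundary_z
            n_out = np.where(is_top, slab.n_surround_top, slab.n_surround_bottom)
            cos_i = np.abs(uzi[hits])
            R = np.empty(hits.size)
            for nv in np.unique(n_out):
                sel = n_out == nv
                R[sel] = _fresnel_reflectance(cos_i[sel], n_tis, float(nv))
            reflect = rng.random(hits.size) < R
            uzi[hits[reflect]] = -uzi[hits[reflect]]
            tr = ~reflect
            tr_idx = hits[tr]
            if tr_idx.size:
                is_top_tr = is_top[tr]
                sin_i = np.sqrt(np.clip(1.0 - cos_i[tr] ** 2, 0.0, 1.0))
                sin_exit = n_tis / n_out[tr] * sin_i
                acc = np.where(is_top_tr, sin_acc_b, sin_acc_f)
                detected = sin_exit <= acc + 1e-12
                w_tr = wi[tr_idx]
                fwd = ~is_top_tr
                tally.detected_forward += float(np.sum(w_tr[detected & fwd]))
                tally.detected_backward += float(np.sum(w_tr[detected & is_top_tr]))
                tally.escaped_undetected += float(np.sum(w_tr[~detected]))
                unscattered_transmitted += float(np.sum(w_tr[fwd & (nsi[tr_idx] == 0)]))
                live[tr_idx] = False
                step[tr_idx] = 0.0
        else:  # pragma: no cover - pathological bounce count
            raise RuntimeError("photon exceeded boundary-bounce limit")

        if transparent:
            if np.any(live):  # pragma: no cover - guarded by stuck check
                raise RuntimeError("transparent-slab photon failed to exit")
            z[idx], uz[idx], w[idx], n_scat[idx] = zi, uzi, wi, nsi
            active[idx] = live
            break

        # Interaction for photons that completed the step inside the slab:
        # deposit absorbed weight, roulette small weights, then scatter.
        al = np.flatnonzero(live)
        if al.size:
            if mu_a > 0.0:
                dw = wi[al] * (mu_a / mu_t)
                tally.absorbed += float(np.sum(dw))
                wi[al] -= dw
            small = al[wi[al] < roulette_threshold]
            if small.size:
                survive = rng.random(small.size) < roulette_survival
                kill = small[~survive]
                keep = small[survive]
                tally.absorbed += float(np.sum(wi[kill]))
                tally.absorbed -= float(
                    np.sum(wi[keep] * (1.0 / roulette_survival - 1.0))
                )
                wi[keep] /= roulette_survival
                wi[kill] = 0.0
                live[kill] = False
            al = np.flatnonzero(live)
        if al.size:
            cos_d = sample_hg_deflection(g, rng.random(al.size))
            cos_phi = np.cos(2.0 * np.pi * rng.random(al.size))
            sin_d = np.sqrt(np.clip(1.0 - cos_d**2, 0.0, 1.0))
            sin_th = np.sqrt(np.clip(1.0 - uzi[al] ** 2, 0.0, 1.0))
            uzi[al] = np.clip(uzi[al] * cos_d + sin_th * sin_d * cos_phi, -1.0, 1.0)
            nsi[al] += 1

        z[idx], uz[idx], w[idx], n_scat[idx] = zi, uzi, wi, nsi
        active[idx] = live
    else:  # pragma: no cover - pathological walk length
        raise RuntimeError("photon walk exceeded iteration limit")

    return tally, unscattered_transmitted


# ---------------------------------------------------------------------------
# SHG launches
# ---------------------------------------------------------------------------

def _launch_directions(
    n_photons: int,
    intrinsic_fb: float,
    sin_cone: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial direction cosines for an SHG photon batch.

    The launch-direction split is stratified: exactly
    round(n * fb/(1+fb)) photons go forward, the rest backward, which
    removes binomial noise from the intrinsic ratio and makes the
    ballistic limit exact per batch.  Within each lobe, directions are
    uniform in solid angle inside a cone of half-angle asin(sin_cone)
    about the axis.
    """
    frac_f = intrinsic_fb / (1.0 + intrinsic_fb)
    n_f = int(round(n_photons * frac_f))
    n_f = min(max(n_f, 1), n_photons - 1) if 0 < frac_f < 1 else n_f
    cos_cone = math.sqrt(1.0 - sin_cone**2)
    # uniform in solid angle within the cone: cos(theta) ~ U[cos_cone, 1]
    mu = cos_cone + (1.0 - cos_cone) * rng.random(n_photons)
    uz = np.empty(n_photons)
    uz[:n_f] = mu[:n_f]
    uz[n_f:] = -mu[n_f:]
    return uz


def propagate_shg_photons(
    slab: TissueSlab,
    depth: float,
    emission: EmissionParams,
    geometry: DetectionGeometry,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PhotonTally:
    """Launch one batch of SHG photons at a focal depth and tally exits.

    Photons are created at depth ``z`` with unit weight, split between the
    forward and backward emission lobes according to ``intrinsic_fb``, and
    random-walked to termination at the SHG wavelength's optical
    properties.
    """
    if not 0.0 <= depth <= slab.thickness:
        raise ValueError(f"depth {depth} outside slab [0, {slab.thickness}]")
    props = slab.properties(emission.shg_wavelength)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    sin_cone = geometry.na_excitation / props.n
    uz = _launch_directions(config.n_photons, emission.intrinsic_fb, sin_cone, rng)
    z = np.full(config.n_photons, float(depth))
    w = np.ones(config.n_photons)
    tally, _ = _walk(
        z, uz, w, slab, props, geometry, rng,
        config.roulette_threshold, config.roulette_survival,
    )
    return tally


def simulate_depth_response(
    slab: TissueSlab,
    emission: EmissionParams,
    geometry: DetectionGeometry,
    config: SimulationConfig,
) -> DepthResponseSim:
    """Simulate the two-channel depth response of a tissue section.

    At each focal depth the detected forward / backward weights are the
    per-batch detected weights scaled by the relative conversion
    efficiency and the ballistic focal excitation weight
    exp(-2 mu_s,ex z).  The per-depth RNG stream is derived
    deterministically from (rng_seed, depth index), so results are
    bitwise-reproducible and independent of any parallel scheduling.
    """
    config.validate_depths(slab)
    # fail fast if either wavelength's properties are missing
    slab.properties(emission.excitation_wavelength)
    slab.properties(emission.shg_wavelength)

    depths = np.asarray(config.depth_grid, dtype=float)
    fwd = np.empty(depths.size)
    bwd = np.empty(depths.size)
    tallies = []
    for i, d in enumerate(depths):
        rng = np.random.default_rng([int(config.rng_seed), i])
        tally = propagate_shg_photons(slab, float(d), emission, geometry, config, rng)
        scale = emission.relative_efficiency * ballistic_focal_weight(
            slab, float(d), emission.excitation_wavelength
        )
        fwd[i] = scale * tally.detected_forward
        bwd[i] = scale * tally.detected_backward
        tallies.append(tally)
    with np.errstate(divide="ignore", invalid="ignore"):
        fb = np.where(bwd > 0, fwd / np.where(bwd > 0, bwd, 1.0), np.nan)
    if np.all(fwd == 0):
        norm = np.zeros_like(fwd)
    else:
        norm = normalize_topk(fwd)
    return DepthResponseSim(
        depths=depths,
        forward_detected=fwd,
        backward_detected=bwd,
        measured_fb=fb,
        normalized_forward=norm,
        tallies=tallies,
    )


def collimated_transmission(
    mu_s: float,
    thickness: float,
    n_photons: int,
    seed: int = 0,
    g: float = 0.9,
    n_tissue: float = N_WATER,
) -> float:
    """Monte Carlo estimate of the unscattered collimated transmission.

    Photons are launched at the top surface travelling straight down
    through an index-matched slab; the returned fraction of photons that
    exit the bottom face without a single scattering event is the
    Beer-Lambert oracle exp(-mu_s t).
    """
    props = OpticalProperties(wavelength=500.0, n=n_tissue, mu_s=mu_s, g=g)
    slab = TissueSlab(
        thickness=thickness,
        properties_by_wavelength={500.0: props},
        n_surround_top=n_tissue,
        n_surround_bottom=n_tissue,
    )
    geometry = DetectionGeometry(n_immersion=n_tissue, na_forward=n_tissue * 0.999,
                                 na_backward=n_tissue * 0.999,
                                 na_excitation=n_tissue * 0.5)
    rng = np.random.default_rng(seed)
    z = np.zeros(n_photons)
    uz = np.ones(n_photons)
    w = np.ones(n_photons)
    _, unscattered = _walk(z, uz, w, slab, props, geometry, rng)
    return unscattered / n_photons


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def simulation_fingerprint(
    slab: TissueSlab, geometry: DetectionGeometry, config: SimulationConfig
) -> str:
    """Stable hash identifying a (slab, geometry, config) combination."""
    payload = {
        "slab": slab.fingerprint_dict(),
        "geometry": geometry.fingerprint_dict(),
        "config": config.fingerprint_dict(),
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
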