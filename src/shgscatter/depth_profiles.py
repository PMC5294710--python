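"""From two-channel SHG image stacks to measured depth-response curves.

The microscope records, at each focal depth, a forward-detected (condenser)
and a backward-detected (objective) image of the same field.  Integrating
each slice over the field of view, correcting the forward channel by the
detector calibration factor, and averaging over fields of view yields the
measured F/B-vs-depth curve and the self-normalized forward attenuation
curve consumed by the Monte Carlo inversion.  A thresholded line-profile
estimator of collagen fiber diameter is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .photon_transport import NORMALIZATION_TOP_K, normalize_topk

__all__ = [
    "ImageStackPair",
    "DepthResponse",
    "integrate_stack",
    "compute_depth_response",
    "trim_to_surface",
    "normalize_attenuation",
    "estimate_fiber_diameter",
    "read_stack_pair",
]

#: A slice is called "at the surface" once it exceeds this fraction of the
#: stack maximum (sections sit in mounting medium above the tissue).
SURFACE_THRESHOLD_FRACTION = 0.1


@dataclass
class ImageStackPair:
    """One field of view: forward and backward stacks plus acquisition meta.

    ``detector_calibration`` is the forward/backward channel gain ratio
    measured with two-photon fluorescent beads; dividing the forward
    channel by it puts both channels on one intensity scale.
    """

    forward_stack: np.ndarray  # (z, y, x)
    backward_stack: np.ndarray
    z_step: float  # um
    excitation_wavelength: float  # nm
    detector_calibration: float = 1.0

    def __post_init__(self) -> None:
        self.forward_stack = np.asarray(self.forward_stack, dtype=float)
        self.backward_stack = np.asarray(self.backward_stack, dtype=float)
        if self.forward_stack.shape != self.backward_stack.shape:
            raise ValueError(
                f"stack shapes differ: {self.forward_stack.shape} vs "
                f"{self.backward_stack.shape}"
            )
        if self.forward_stack.ndim != 3:
            raise ValueError("stacks must be 3-D (z, y, x)")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if self.detector_calibration <= 0:
            raise ValueError("detector calibration must be positive")
        if np.any(self.forward_stack < 0) or np.any(self.backward_stack < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class DepthResponse:
    """Measured two-channel response versus depth (um from the top surface).

    ``fb_ratio`` is defined only where the backward channel is positive
    (NaN elsewhere).  Standard errors are per-depth SEMs across fields of
    view; None when only one field was acquired.
    """

    depths: np.ndarray  # um
    forward: np.ndarray
    backward: np.ndarray
    fb_ratio: np.ndarray
    normalized_forward: np.ndarray | None = None
    n_fields: int = 1
    forward_se: np.ndarray | None = None
    backward_se: np.ndarray | None = None
    fb_se: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "depth_um": self.depths,
            "forward": self.forward,
            "backward": self.backward,
            "fb_ratio": self.fb_ratio,
        }
        if self.normalized_forward is not None:
            data["normalized_forward"] = self.normalized_forward
        if self.fb_se is not None:
            data["fb_se"] = self.fb_se
        return pd.DataFrame(data)


def integrate_stack(pair: ImageStackPair) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice channel totals, calibration-corrected.

    Sums each slice over (y, x) and divides the forward totals by the
    detector calibration so both channels share one intensity scale.
    """
    if pair.forward_stack.size == 0:
        raise ValueError("empty stack")
    fwd = pair.forward_stack.sum(axis=(1, 2)) / pair.detector_calibration
    bwd = pair.backward_stack.sum(axis=(1, 2))
    return fwd, bwd


def compute_depth_response(pairs: Sequence[ImageStackPair]) -> DepthResponse:
    """Average the integrated depth curves over fields of view.

    All fields must share the z-step and excitation wavelength.  The F/B
    curve is formed from the mean channels; the per-depth SEM of the
    per-field F/B ratios is retained as the variance model for the
    inversion chi-square.
    """
    if not pairs:
        raise ValueError("at least one field of view required")
    z_steps = {p.z_step for p in pairs}
    if len(z_steps) != 1:
        raise ValueError(f"inconsistent z-steps across fields: {sorted(z_steps)}")
    wavelengths = {p.excitation_wavelength for p in pairs}
    if len(wavelengths) != 1:
        raise ValueError("inconsistent excitation wavelengths across fields")
    n_slices = {p.forward_stack.shape[0] for p in pairs}
    if len(n_slices) != 1:
        raise ValueError("inconsistent slice counts across fields")

    curves = [integrate_stack(p) for p in pairs]
    fwd_all = np.stack([c[0] for c in curves])  # (fields, z)
    bwd_all = np.stack([c[1] for c in curves])
    fwd = fwd_all.mean(axis=0)
    bwd = bwd_all.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fb = np.where(bwd > 0, fwd / np.where(bwd > 0, bwd, 1.0), np.nan)
        fb_fields = np.where(
            bwd_all > 0, fwd_all / np.where(bwd_all > 0, bwd_all, 1.0), np.nan
        )
    n_fields = len(pairs)
    if n_fields > 1:
        fwd_se = fwd_all.std(axis=0, ddof=1) / math.sqrt(n_fields)
        bwd_se = bwd_all.std(axis=0, ddof=1) / math.sqrt(n_fields)
        fb_se = np.nanstd(fb_fields, axis=0, ddof=1) / math.sqrt(n_fields)
    else:
        fwd_se = bwd_se = fb_se = None
    depths = np.arange(fwd.size) * pairs[0].z_step
    return DepthResponse(
        depths=depths,
        forward=fwd,
        backward=bwd,
        fb_ratio=fb,
        n_fields=n_fields,
        forward_se=fwd_se,
        backward_se=bwd_se,
        fb_se=fb_se,
    )


def trim_to_surface(
    response: DepthResponse,
    threshold_fraction: float = SURFACE_THRESHOLD_FRACTION,
) -> DepthResponse:
    """Drop leading mounting-medium slices and re-zero the depth axis.

    The surface slice is the first whose forward intensity exceeds
    ``threshold_fraction`` of the curve maximum.
    """
    peak = float(np.max(response.forward))
    if peak <= 0:
        raise ValueError("all-zero forward curve: cannot locate surface")
    start = int(np.argmax(response.forward > threshold_fraction * peak))

    def cut(a):
        return None if a is None else a[start:]

    return DepthResponse(
        depths=response.depths[start:] - response.depths[start],
        forward=response.forward[start:],
        backward=response.backward[start:],
        fb_ratio=response.fb_ratio[start:],
        normalized_forward=cut(response.normalized_forward),
        n_fields=response.n_fields,
        forward_se=cut(response.forward_se),
        backward_se=cut(response.backward_se),
        fb_se=cut(response.fb_se),
    )


def normalize_attenuation(
    response: DepthResponse, k: int = NORMALIZATION_TOP_K
) -> DepthResponse:
    """Populate the self-normalized forward attenuation curve.

    Normalizes by the "average maximum": the mean of the k largest forward
    values, robust against a single noisy bright slice.
    """
    if response.forward.size == 0:
        raise ValueError("empty forward curve")
    if np.max(response.forward) <= 0:
        raise ValueError("degenerate normalization: all-zero forward curve")
    return replace(response, normalized_forward=normalize_topk(response.forward, k))


# ---------------------------------------------------------------------------
# Fiber diameter
# ---------------------------------------------------------------------------

def _local_orientations(image: np.ndarray, sigma: float) -> np.ndarray:
    """Per-pixel gradient orientation from the smoothed structure tensor.

    Returns the angle (radians) of the dominant *gradient* direction,
    i.e. the direction across a locally oriented fiber.
    """
    gy = ndimage.sobel(image, axis=0, mode="reflect")
    gx = ndimage.sobel(image, axis=1, mode="reflect")
    jxx = ndimage.gaussian_filter(gx * gx, sigma, mode="reflect")
    jyy = ndimage.gaussian_filter(gy * gy, sigma, mode="reflect")
    jxy = ndimage.gaussian_filter(gx * gy, sigma, mode="reflect")
    return 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)


def estimate_fiber_diameter(
    image: np.ndarray,
    intensity_threshold: float,
    n_profiles: int = 50,
    pixel_size_um: float = 1.0,
    seed: int = 0,
    tensor_sigma: float = 3.0,
    profile_step_px: float = 0.5,
) -> tuple[float, float]:
    """Fiber diameter from thresholded line profiles across fibers.

    Binarizes the image at ``intensity_threshold``, seeds ``n_profiles``
    points on the foreground, orients each profile along the local
    dominant gradient direction (structure tensor, i.e. perpendicular to
    the fiber axis), and measures the contiguous above-threshold run
    length through the seed point.

    Returns
    -------
    (mean_diameter_um, standard_error_um)
    """
    img = np.asarray(image, dtype=float)
    fg = img > intensity_threshold
    if not np.any(fg):
        raise ValueError("no pixels above the intensity threshold")
    rng = np.random.default_rng(seed)
    ys, xs = np.nonzero(fg)
    pick = rng.integers(0, ys.size, size=n_profiles)
    angles = _local_orientations(img, tensor_sigma)

    half_len = max(img.shape) / 2.0
    t = np.arange(-half_len, half_len + profile_step_px / 2.0, profile_step_px)
    center = int(np.argmin(np.abs(t)))

    widths = []
    for y0, x0 in zip(ys[pick], xs[pick]):
        a = angles[y0, x0]
        dy, dx = math.sin(a), math.cos(a)
        yy = np.floor(y0 + t * dy + 0.5).astype(int)
        xx = np.floor(x0 + t * dx + 0.5).astype(int)
        inside = (yy >= 0) & (yy < img.shape[0]) & (xx >= 0) & (xx < img.shape[1])
        above = np.zeros(t.size, dtype=bool)
        above[inside] = fg[yy[inside], xx[inside]]
        if not above[center]:
            continue
        lo = center
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = center
        while hi < above.size - 1 and above[hi + 1]:
            hi += 1
        widths.append((hi - lo + 1) * profile_step_px * pixel_size_um)
    if not widths:
        raise ValueError("no valid profiles through foreground pixels")
    widths = np.asarray(widths)
    se = float(widths.std(ddof=1) / math.sqrt(widths.size)) if widths.size > 1 else 0.0
    return float(widths.mean()), se


# ---------------------------------------------------------------------------
# I/O boundary
# ---------------------------------------------------------------------------

def read_stack_pair(
    forward_path,
    backward_path,
    z_step: float,
    excitation_wavelength: float,
    detector_calibration: float = 1.0,
) -> ImageStackPair:
    """Load a forward/backward multi-page TIFF pair."""
    import tifffile

    return ImageStackPair(
        forward_stack=tifffile.imread(forward_path),
        backward_stack=tifffile.imread(backward_path),
        z_step=z_step,
        excitation_wavelength=excitation_wavelength,
        detector_calibration=detector_calibration,
    )
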