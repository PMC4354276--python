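"""Gabor mathematics, unit conversions and grayscale image composition.

A Gabor patch is a sinusoidal luminance carrier multiplied by an isotropic
2-D Gaussian envelope.  All geometry is expressed in degrees of visual
angle; luminance is modelled on a normalized [0, 1] scale with a mean
(background) level of 0.5.  Orientation is measured in degrees clockwise
from vertical, so an orientation of 0 is a vertically striped patch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "GaborSpec",
    "DisplayGeometry",
    "StimulusFrame",
    "bandwidth_to_sigma",
    "sigma_to_bandwidth",
    "wavelength_deg",
    "render_gabor",
    "compose_frame",
]

# Half-amplitude half-width of a unit-variance Gaussian in the frequency
# domain: sqrt(2 ln 2) / (2 pi).  Relates octave bandwidth to envelope SD.
_K = math.sqrt(2.0 * math.log(2.0)) / (2.0 * math.pi)


@dataclass(frozen=True)
class GaborSpec:
    """One Gabor element.

    Parameters
    ----------
    center_x, center_y : float
        Position in degrees of visual angle relative to fixation.
        Positive x is rightward, positive y is downward (screen convention).
    orientation : float
        Degrees clockwise from vertical, conventionally in [-90, 90).
    spatial_frequency : float
        Carrier frequency in cycles per degree (cpd); must be > 0.
    sigma : float
        Standard deviation of the Gaussian envelope in degrees; must be > 0.
    phase : float
        Carrier phase in radians; 0 gives an even-symmetric (cosine) patch.
    contrast : float
        Michelson contrast in [0, 1].
    """

    center_x: float = 0.0
    center_y: float = 0.0
    orientation: float = 0.0
    spatial_frequency: float = 3.0
    sigma: float = 0.16
    phase: float = 0.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.spatial_frequency <= 0:
            raise ValueError(
                f"spatial_frequency must be > 0, got {self.spatial_frequency}"
            )
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must lie in [0, 1], got {self.contrast}")


@dataclass(frozen=True)
class DisplayGeometry:
    """Canvas size and the degree-to-pixel mapping.

    The default 49 px/deg corresponds to a 1600-px-wide display of about
    40 cm viewed from 70 cm.  Mean luminance is fixed at 0.5 on the
    normalized scale; photometric calibration is out of scope.
    """

    width_px: int = 1600
    height_px: int = 1200
    pixels_per_degree: float = 49.0
    mean_luminance: float = 0.5

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be > 0")
        if not 0.0 < self.mean_luminance < 1.0:
            raise ValueError("mean_luminance must lie strictly inside (0, 1)")

    def deg_to_px(self, deg: float) -> float:
        return deg * self.pixels_per_degree

    @property
    def center_px(self) -> tuple[float, float]:
        """(x, y) pixel coordinates of fixation (canvas center)."""
        return (self.width_px / 2.0, self.height_px / 2.0)


@dataclass
class StimulusFrame:
    """A rendered display: the image plus everything needed to re-render it."""

    image: np.ndarray
    elements: list[GaborSpec]
    geometry: DisplayGeometry
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path, bit_depth: int = 8) -> None:
        """Write the frame as a grayscale PNG with a JSON metadata sidecar."""
        from PIL import Image

        path = Path(path)
        if bit_depth == 8:
            arr = np.round(self.image * 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(path)
        elif bit_depth == 16:
            arr = np.round(self.image * 65535).astype(np.uint16)
            Image.fromarray(arr, mode="I;16").save(path)
        else:
            raise ValueError("bit_depth must be 8 or 16")
        sidecar = {
            "label": self.label,
            "geometry": asdict(self.geometry),
            "elements": [asdict(e) for e in self.elements],
            "metadata": self.metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def bandwidth_to_sigma(bandwidth_octaves: float, spatial_frequency: float) -> float:
    """Envelope SD (degrees) from half-amplitude full bandwidth (octaves).

    For a Gabor with carrier frequency ``f`` and envelope SD ``sigma`` the
    spectral envelope is Gaussian with SD ``1 / (2 pi sigma)``; the
    half-amplitude full bandwidth ``b`` in octaves therefore satisfies

        sigma = k (2**b + 1) / (f (2**b - 1)),  k = sqrt(2 ln 2) / (2 pi).

    Examples
    --------
    >>> round(bandwidth_to_sigma(1.14, 3.0), 3)
    0.166
    """
    if bandwidth_octaves <= 0:
        raise ValueError("bandwidth_octaves must be > 0")
    if spatial_frequency <= 0:
        raise ValueError("spatial_frequency must be > 0")
    r = 2.0**bandwidth_octaves
    return _K * (r + 1.0) / (spatial_frequency * (r - 1.0))


def sigma_to_bandwidth(sigma: float, spatial_frequency: float) -> float:
    """Inverse of :func:`bandwidth_to_sigma`.

    Requires ``sigma * f * 2 pi > sqrt(2 ln 2)``, i.e. the low-frequency
    half-amplitude point must be positive; otherwise the bandwidth is
    infinite and a ``ValueError`` is raised.
    """
    if sigma <= 0 or spatial_frequency <= 0:
        raise ValueError("sigma and spatial_frequency must be > 0")
    # sigma = k (r+1)/(f (r-1))  =>  r = (sigma f + k) / (sigma f - k)
    denom = sigma * spatial_frequency - _K
    if denom <= 0:
        raise ValueError(
            "bandwidth undefined: sigma * spatial_frequency must exceed "
            f"{_K:.6f} deg*cpd"
        )
    r = (sigma * spatial_frequency + _K) / denom
    return math.log2(r)


def wavelength_deg(spatial_frequency: float) -> float:
    """Carrier wavelength lambda in degrees: one full cycle, 1/f."""
    if spatial_frequency <= 0:
        raise ValueError("spatial_frequency must be > 0")
    return 1.0 / spatial_frequency


# Patch support half-width in units of sigma.  Beyond 4 sigma the envelope
# is < 3.4e-4, visually lossless, and keeps composition O(n elements).
PATCH_SUPPORT_SIGMA = 4.0


def render_gabor(
    spec: GaborSpec, geometry: DisplayGeometry
) -> tuple[np.ndarray, int, int]:
    """Render one Gabor patch.

    Returns ``(patch, row0, col0)`` where ``patch`` is the luminance image
    of the element over its +/-4 sigma support and ``(row0, col0)`` is the
    top-left pixel of the patch on the canvas (possibly out of bounds;
    clipping happens at composition).

    The patch value at pixel offset (dx, dy) degrees from the element
    center is

        L = mean + contrast * mean * exp(-(dx^2+dy^2)/(2 sigma^2))
                 * cos(2 pi f u + phase),

    with ``u`` the coordinate along the modulation axis (perpendicular to
    the stripes).  Rendering is deterministic.
    """
    ppd = geometry.pixels_per_degree
    half = int(math.ceil(PATCH_SUPPORT_SIGMA * spec.sigma * ppd))
    cx_px, cy_px = geometry.center_px
    # element center in pixel coordinates
    ex = cx_px + geometry.deg_to_px(spec.center_x)
    ey = cy_px + geometry.deg_to_px(spec.center_y)
    col0 = int(round(ex)) - half
    row0 = int(round(ey)) - half
    n = 2 * half + 1
    cols = (np.arange(col0, col0 + n) - ex) / ppd  # degrees
    rows = (np.arange(row0, row0 + n) - ey) / ppd
    dx, dy = np.meshgrid(cols, rows)
    theta = math.radians(spec.orientation)
    # orientation 0: vertical stripes, modulation along x; rotating the
    # patch clockwise rotates the modulation axis with it (y is downward).
    u = dx * math.cos(theta) + dy * math.sin(theta)
    envelope = np.exp(-(dx**2 + dy**2) / (2.0 * spec.sigma**2))
    carrier = np.cos(2.0 * math.pi * spec.spatial_frequency * u + spec.phase)
    mean = geometry.mean_luminance
    patch = mean + spec.contrast * mean * envelope * carrier
    return patch, row0, col0


def compose_frame(
    elements: list[GaborSpec],
    geometry: DisplayGeometry,
    label: str = "",
    metadata: dict | None = None,
) -> StimulusFrame:
    """Compose Gabor elements onto a uniform mean-luminance canvas.

    Deviations from the mean add linearly where elements overlap; the
    result is clipped to [0, 1] at the end.  An empty element list yields
    a uniform background.
    """
    mean = geometry.mean_luminance
    canvas = np.full((geometry.height_px, geometry.width_px), mean, dtype=np.float64)
    for spec in elements:
        patch, row0, col0 = render_gabor(spec, geometry)
        n = patch.shape[0]
        r0, r1 = max(row0, 0), min(row0 + n, geometry.height_px)
        c0, c1 = max(col0, 0), min(col0 + n, geometry.width_px)
        if r0 >= r1 or c0 >= c1:
            continue  # entirely off-canvas
        canvas[r0:r1, c0:c1] += (
            patch[r0 - row0 : r1 - row0, c0 - col0 : c1 - col0] - mean
        )
    np.clip(canvas, 0.0, 1.0, out=canvas)
    return StimulusFrame(
        image=canvas,
        elements=list(elements),
        geometry=geometry,
        label=label,
        metadata=metadata or {},
    )
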