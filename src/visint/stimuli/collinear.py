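"""Collinear-facilitation displays: a central low-contrast vertical target
flanked above and below by two high-contrast Gabors.

The flankers sit at +/- ``separation_lambda`` carrier wavelengths from the
target along the vertical axis and share one orientation offset (both
rotated the same signed amount from vertical).  The baseline condition has
no flankers.  The target-absent interval of a 2IFC trial is the same frame
with target contrast 0, which for the baseline condition means a blank
background.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    DisplayGeometry,
    GaborSpec,
    StimulusFrame,
    compose_frame,
    wavelength_deg,
)

__all__ = ["BASELINE", "CF_OFFSETS", "CollinearCondition", "build_cf_display"]

#: Distinguished flanker-offset value for the no-flanker condition.
BASELINE = "baseline"

#: The four flanker orientation offsets of the experimental conditions.
CF_OFFSETS = (0, 15, 30, 45)


@dataclass(frozen=True)
class CollinearCondition:
    """One of the five display conditions.

    ``flanker_offset`` is an orientation offset in degrees (0, 15, 30 or
    45) or the string ``"baseline"`` for the no-flanker condition.
    """

    flanker_offset: int | str = 0
    flanker_contrast: float = 0.60
    separation_lambda: float = 3.0

    def __post_init__(self) -> None:
        if self.flanker_offset != BASELINE and self.flanker_offset not in CF_OFFSETS:
            raise ValueError(
                f"flanker_offset must be one of {CF_OFFSETS} or {BASELINE!r}, "
                f"got {self.flanker_offset!r}"
            )
        if self.separation_lambda <= 0:
            raise ValueError("separation_lambda must be > 0")

    @property
    def is_baseline(self) -> bool:
        return self.flanker_offset == BASELINE


def build_cf_display(
    condition: CollinearCondition,
    target_contrast: float,
    geometry: DisplayGeometry | None = None,
    gabor_template: GaborSpec | None = None,
    render: bool = True,
) -> StimulusFrame:
    """Build one collinear-facilitation display.

    The target Gabor is always vertical (orientation 0) at fixation; the
    two flankers are centered at (0, +/- separation_lambda * lambda)
    degrees with orientation equal to the condition's offset.  Passing
    ``target_contrast=0`` produces the target-absent interval: the target
    element contributes nothing to the image.

    Parameters
    ----------
    gabor_template : GaborSpec, optional
        Carries the shared Gabor parameters (spatial frequency, sigma,
        phase).  Default: 3.0 cpd, sigma 0.16 deg, phase 0.
    render : bool
        If False the returned frame has a 1x1 placeholder image; the
        element list and geometry are always complete.
    """
    if not 0.0 <= target_contrast <= 1.0:
        raise ValueError("target_contrast must lie in [0, 1]")
    geometry = geometry or DisplayGeometry()
    template = gabor_template or GaborSpec(spatial_frequency=3.0, sigma=0.16)

    def gabor(cx: float, cy: float, ori: float, contrast: float) -> GaborSpec:
        return GaborSpec(
            center_x=cx,
            center_y=cy,
            orientation=ori,
            spatial_frequency=template.spatial_frequency,
            sigma=template.sigma,
            phase=template.phase,
            contrast=contrast,
        )

    elements = [gabor(0.0, 0.0, 0.0, target_contrast)]
    if not condition.is_baseline:
        sep = condition.separation_lambda * wavelength_deg(
            template.spatial_frequency
        )
        offset = float(condition.flanker_offset)
        for sign in (-1.0, 1.0):
            elements.append(
                gabor(0.0, sign * sep, offset, condition.flanker_contrast)
            )
    # a zero-contrast target adds nothing: drop it so the target-absent
    # frame's element list reflects what is actually displayed
    elements = [e for e in elements if e.contrast > 0]

    label = f"cf-{condition.flanker_offset}-c{target_contrast:g}"
    if render:
        frame = compose_frame(elements, geometry, label=label)
    else:
        import numpy as np

        frame = StimulusFrame(
            image=np.full((1, 1), geometry.mean_luminance),
            elements=elements,
            geometry=geometry,
            label=label,
        )
    frame.metadata.update(
        {
            "condition": condition.flanker_offset,
            "target_contrast": target_contrast,
            "flanker_contrast": None
            if condition.is_baseline
            else condition.flanker_contrast,
            "separation_lambda": condition.separation_lambda,
        }
    )
    return frame
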