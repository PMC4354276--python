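"""Contour-integration displays: a 33 x 24 grid of randomly oriented,
positionally perturbed Gabors with an embedded contour of co-oriented
elements (two vertical lines, a closed square, or an open "windmill").

Every cell of the invisible grid holds exactly one Gabor at 100% Michelson
contrast.  Background Gabors are jittered in position (integer pixel
perturbation per axis) and uniformly random in orientation.  Contour
Gabors sit exactly at their cell centers; in the target interval their
orientation is the contour's base orientation plus a uniform jitter draw,
while in the comparison (contour-absent) interval it is uniform on
[-90, 90) like the background.  Target and comparison intervals built from
the same seed share the identical background realization, so the two
frames differ only in the contour-cell orientations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .core import DisplayGeometry, GaborSpec, StimulusFrame, compose_frame

__all__ = [
    "JITTER_LEVELS",
    "SHAPES",
    "ContourShape",
    "GridLayout",
    "JitterCondition",
    "contour_cell_map",
    "jitter_draw",
    "build_ci_display",
]

#: The seven orientation-jitter range maxima (degrees).
JITTER_LEVELS = (0, 15, 30, 45, 60, 75, 90)

#: Contour shape names.
SHAPES = ("lines", "square", "windmill")

#: Gabor parameters shared by all contour-display elements: 4.6 cpd
#: carrier, 0.1 deg envelope SD (1.2 octave bandwidth), full contrast.
CI_GABOR = GaborSpec(spatial_frequency=4.6, sigma=0.1, contrast=1.0)


@dataclass(frozen=True)
class GridLayout:
    """The invisible grid that tiles the display: 33 columns x 24 rows,
    one Gabor per cell, background positions perturbed by up to
    ``perturbation_max`` integer pixels per axis."""

    columns: int = 33
    rows: int = 24
    perturbation_max: int = 11

    @property
    def n_cells(self) -> int:
        return self.columns * self.rows

    def cell_center_px(
        self, row: int, col: int, geometry: DisplayGeometry
    ) -> tuple[float, float]:
        """(x, y) pixel coordinates of a cell center."""
        cw = geometry.width_px / self.columns
        ch = geometry.height_px / self.rows
        return ((col + 0.5) * cw, (row + 0.5) * ch)


@dataclass(frozen=True)
class JitterCondition:
    """One of the seven orientation-jitter ranges; draws are uniform on
    [-jitter_max, +jitter_max] degrees."""

    jitter_max: int = 0

    def __post_init__(self) -> None:
        if self.jitter_max not in JITTER_LEVELS:
            raise ValueError(
                f"jitter_max must be one of {JITTER_LEVELS}, got {self.jitter_max}"
            )


@dataclass(frozen=True)
class ContourShape:
    """A contour: its name and the (row, col, base orientation) cells."""

    name: str
    cells: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        rc = [(r, c) for r, c, _ in self.cells]
        if len(set(rc)) != len(rc):
            raise ValueError("contour cells must be distinct grid cells")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _load_windmill() -> tuple[tuple[int, int, float], ...]:
    text = (
        resources.files("visint.data").joinpath("windmill_cells.txt").read_text()
    )
    cells = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        r, c, ori = line.split()
        cells.append((int(r), int(c), float(ori)))
    return tuple(cells)


def contour_cell_map(
    shape: str, grid: GridLayout | None = None, geometry: DisplayGeometry | None = None
) -> ContourShape:
    """Cell map for one of the three contour shapes.

    * ``lines``: two vertical runs of 10 cells whose columns are nearest
      to +/-5 deg horizontal eccentricity, vertically centered; base
      orientation 0 (vertical).
    * ``square``: the same two vertical runs (identical cells), joined
      above and below by horizontal runs of 9 cells (base orientation 90)
      and 4 corner cells at +/-45 deg, 42 cells total.
    * ``windmill``: four straight 10-cell arms in an open pinwheel layout
      plus 2 filler cells, 42 cells total; the exact cell list is frozen
      in a packaged fixture file.
    """
    grid = grid or GridLayout()
    geometry = geometry or DisplayGeometry()
    if shape not in SHAPES:
        raise ValueError(f"shape must be one of {SHAPES}, got {shape!r}")
    if shape == "windmill":
        cells = _load_windmill()
        for r, c, _ in cells:
            if not (0 <= r < grid.rows and 0 <= c < grid.columns):
                raise ValueError("windmill contour does not fit this grid")
        return ContourShape("windmill", cells)

    # column whose center is nearest to +/-5 deg from fixation
    cw = geometry.width_px / grid.columns
    cx = geometry.width_px / 2.0
    ecc_px = geometry.deg_to_px(5.0)
    col_centers = (np.arange(grid.columns) + 0.5) * cw
    left_col = int(np.argmin(np.abs(col_centers - (cx - ecc_px))))
    right_col = int(np.argmin(np.abs(col_centers - (cx + ecc_px))))
    if left_col == right_col:
        raise ValueError("grid too coarse to place the contour columns")
    top = (grid.rows - 10) // 2  # 10-cell runs, vertically centered
    rows10 = range(top, top + 10)
    lines = [(r, left_col, 0.0) for r in rows10] + [
        (r, right_col, 0.0) for r in rows10
    ]
    if shape == "lines":
        return ContourShape("lines", tuple(lines))

    # square: horizontal rows one cell above/below the vertical runs,
    # corners continue the contour direction
    row_top, row_bot = top - 1, top + 10
    if row_top < 0 or row_bot >= grid.rows:
        raise ValueError("grid too coarse to place the square contour")
    horiz = [
        (row, c, 90.0)
        for row in (row_top, row_bot)
        for c in range(left_col + 1, right_col)
    ]
    if len(horiz) != 18:
        raise ValueError("grid too coarse to place the square contour")
    corners = [
        (row_top, left_col, 45.0),
        (row_top, right_col, -45.0),
        (row_bot, left_col, -45.0),
        (row_bot, right_col, 45.0),
    ]
    return ContourShape("square", tuple(lines + horiz + corners))


def jitter_draw(
    jitter_max: float, rng: np.random.Generator, size: int | None = None
):
    """Uniform orientation-jitter draw on [-jitter_max, +jitter_max] deg."""
    if not 0 <= jitter_max <= 90:
        raise ValueError("jitter_max must lie in [0, 90]")
    if jitter_max == 0:
        return 0.0 if size is None else np.zeros(size)
    return rng.uniform(-jitter_max, jitter_max, size=size)


def _wrap_orientation(theta):
    """Wrap orientation(s) to [-90, 90) (orientation is defined mod 180)."""
    return (np.asarray(theta) + 90.0) % 180.0 - 90.0


def build_ci_display(
    shape: str,
    jitter: int | JitterCondition,
    is_target: bool,
    seed: int | np.random.SeedSequence,
    geometry: DisplayGeometry | None = None,
    grid: GridLayout | None = None,
    render: bool = True,
) -> StimulusFrame:
    """Build one contour-integration display interval.

    ``is_target`` selects the interval: True embeds the jittered contour,
    False yields the comparison display whose contour cells are oriented
    uniformly at random.  Both intervals of a trial should be built with
    the same ``seed``: the background realization is then identical and
    only the contour-cell orientations differ.
    """
    geometry = geometry or DisplayGeometry()
    grid = grid or GridLayout()
    if isinstance(jitter, int):
        jitter = JitterCondition(jitter)
    cmap = contour_cell_map(shape, grid, geometry)
    contour_cells = {(r, c): ori for r, c, ori in cmap.cells}

    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    bg_ss, tgt_ss, cmp_ss = ss.spawn(3)
    bg_rng = np.random.default_rng(bg_ss)
    contour_rng = np.random.default_rng(tgt_ss if is_target else cmp_ss)

    ppd = geometry.pixels_per_degree
    cx_px, cy_px = geometry.center_px
    elements: list[GaborSpec] = []
    membership: list[bool] = []
    # background draws consumed in a fixed cell order so target/comparison
    # pairs share the realization exactly
    for row in range(grid.rows):
        for col in range(grid.columns):
            x_px, y_px = grid.cell_center_px(row, col, geometry)
            on_contour = (row, col) in contour_cells
            if on_contour:
                # consume the background draws anyway to keep the stream
                # aligned between displays with different contours
                bg_rng.integers(-grid.perturbation_max, grid.perturbation_max + 1, 2)
                bg_rng.uniform(-90.0, 90.0)
                if is_target:
                    ori = _wrap_orientation(
                        contour_cells[(row, col)]
                        + jitter_draw(jitter.jitter_max, contour_rng)
                    )
                else:
                    ori = contour_rng.uniform(-90.0, 90.0)
                dx_px = dy_px = 0.0
            else:
                dx_px, dy_px = bg_rng.integers(
                    -grid.perturbation_max, grid.perturbation_max + 1, 2
                )
                ori = bg_rng.uniform(-90.0, 90.0)
            elements.append(
                GaborSpec(
                    center_x=(x_px + dx_px - cx_px) / ppd,
                    center_y=(y_px + dy_px - cy_px) / ppd,
                    orientation=float(ori),
                    spatial_frequency=CI_GABOR.spatial_frequency,
                    sigma=CI_GABOR.sigma,
                    phase=CI_GABOR.phase,
                    contrast=CI_GABOR.contrast,
                )
            )
            membership.append(on_contour)

    label = (
        f"ci-{shape}-j{jitter.jitter_max}-"
        f"{'target' if is_target else 'comparison'}"
    )
    if render:
        frame = compose_frame(elements, geometry, label=label)
    else:
        frame = StimulusFrame(
            image=np.full((1, 1), geometry.mean_luminance),
            elements=elements,
            geometry=geometry,
            label=label,
        )
    frame.metadata.update(
        {
            "shape": shape,
            "jitter_max": jitter.jitter_max,
            "is_target": is_target,
            "contour_mask": membership,
        }
    )
    return frame
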