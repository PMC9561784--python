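"""Variable-spacing grid design and difficulty-weighted printability scoring.

The print-quality benchmark is a two-layer rectangular mesh whose fiber
spacing increases block by block in integer increments of the nozzle inner
diameter ``Di``.  A printed sample is summarized by a binary mask (ink =
True); each designed mesh window is scored by the fraction of its expected
open area that remained resolved, and the per-cell fractions are combined
into a single printability index using difficulty weights that penalize the
easy-to-resolve (large) windows.  An index above 0.33 counts as printable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PRINTABLE_CUTOFF = 0.33


@dataclass(frozen=True)
class GridCell:
    """One mesh window: the region between four filament centerlines."""

    multiplier: int
    x0: float  # µm, left centerline
    y0: float
    x1: float
    y1: float

    @property
    def spacing(self) -> float:
        return self.x1 - self.x0


@dataclass
class GridDesign:
    """Layout of the printability test grid in physical (µm) coordinates.

    Each spacing multiplier ``m`` contributes one block of
    ``cells_per_side x cells_per_side`` square windows with centerline pitch
    ``m * di_um``.  ``layer_height_um`` is metadata (2/3 of the nozzle
    diameter); the mask itself is a 2-D projection.
    """

    di_um: float
    multipliers: tuple[int, ...]
    pixel_size_um: float
    cells: list[GridCell]
    canvas_um: tuple[float, float]  # (width, height)
    layer_height_um: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.layer_height_um:
            self.layer_height_um = 2.0 / 3.0 * self.di_um

    @property
    def shape_px(self) -> tuple[int, int]:
        w, h = self.canvas_um
        return (int(round(h / self.pixel_size_um)), int(round(w / self.pixel_size_um)))

    def included_cells(self) -> list[GridCell]:
        """Cells with a nonzero expected open window (multiplier > 1)."""
        return [c for c in self.cells if c.multiplier > 1]


@dataclass
class PrintabilityResult:
    """Per-cell resolved fractions and the difficulty-weighted index."""

    resolved: np.ndarray  # r_c in [0,1], one per included cell
    weights: np.ndarray  # normalized difficulty weights, sum 1
    multipliers: np.ndarray  # spacing multiplier per included cell
    score: float
    printable: bool


def build_grid_design(
    di_um: float = 410.0,
    multipliers: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    pixel_size_um: float = 10.0,
    cells_per_side: int = 2,
    margin_um: float | None = None,
) -> GridDesign:
    """Lay out one block per spacing multiplier, left to right.

    Raises ``ValueError`` if the multipliers are not strictly increasing
    positive integers or the pixel size is too coarse to resolve the nozzle
    diameter.
    """
    mult = tuple(int(m) for m in multipliers)
    if len(mult) == 0 or any(m <= 0 for m in mult):
        raise ValueError("multipliers must be positive integers")
    if any(b <= a for a, b in zip(mult, mult[1:])):
        raise ValueError("multipliers must be strictly increasing")
    if pixel_size_um <= 0 or pixel_size_um > di_um / 4.0:
        raise ValueError(
            f"pixel_size_um={pixel_size_um} too coarse to resolve Di={di_um} µm"
        )
    if margin_um is None:
        margin_um = di_um
    cells: list[GridCell] = []
    x = margin_um
    y0 = margin_um
    max_h = cells_per_side * max(mult) * di_um
    for m in mult:
        pitch = m * di_um
        for i in range(cells_per_side):
            for j in range(cells_per_side):
                cells.append(
                    GridCell(
                        multiplier=m,
                        x0=x + i * pitch,
                        y0=y0 + j * pitch,
                        x1=x + (i + 1) * pitch,
                        y1=y0 + (j + 1) * pitch,
                    )
                )
        x += cells_per_side * pitch + margin_um
    canvas = (x, 2 * margin_um + max_h)
    return GridDesign(
        di_um=di_um,
        multipliers=mult,
        pixel_size_um=pixel_size_um,
        cells=cells,
        canvas_um=canvas,
    )


def difficulty_weights(design: GridDesign) -> np.ndarray:
    """Difficulty weight per included cell: 1/multiplier, normalized to sum 1.

    Larger windows are easier to resolve and are penalized by a lower
    weight; zero-window cells (multiplier 1) are excluded altogether.
    """
    mults = np.array([c.multiplier for c in design.included_cells()], dtype=float)
    w = 1.0 / mults
    return w / w.sum()


def _block_lines(design: GridDesign) -> list[tuple[float, float, np.ndarray, np.ndarray]]:
    """Per block: (x-range, y-range, vertical line xs, horizontal line ys)."""
    blocks: dict[int, list[GridCell]] = {}
    for c in design.cells:
        blocks.setdefault(c.multiplier, []).append(c)
    out = []
    for m, cells in blocks.items():
        xs = sorted({c.x0 for c in cells} | {c.x1 for c in cells})
        ys = sorted({c.y0 for c in cells} | {c.y1 for c in cells})
        out.append(
            (
                (xs[0], xs[-1]),
                (ys[0], ys[-1]),
                np.asarray(xs, dtype=float),
                np.asarray(ys, dtype=float),
            )
        )
    return out


def rasterize_print(design: GridDesign, width_um: float) -> np.ndarray:
    """Draw the design's filaments at the given width; ink = True.

    A pixel is inked when its center lies within ``width_um / 2`` of a
    filament centerline (within the block's extent).  At
    ``width_um == di_um`` this is the nominal print the expected open areas
    are measured against.
    """
    h, w = design.shape_px
    ps = design.pixel_size_um
    xc = (np.arange(w) + 0.5) * ps
    yc = (np.arange(h) + 0.5) * ps
    mask = np.zeros((h, w), dtype=bool)
    half = width_um / 2.0
    for (bx0, bx1), (by0, by1), vxs, hys in _block_lines(design):
        in_x = (xc >= bx0 - half) & (xc <= bx1 + half)
        in_y = (yc >= by0 - half) & (yc <= by1 + half)
        near_v = np.zeros(w, dtype=bool)
        for x in vxs:
            near_v |= np.abs(xc - x) <= half
        near_h = np.zeros(h, dtype=bool)
        for y in hys:
            near_h |= np.abs(yc - y) <= half
        mask |= np.outer(in_y, near_v & in_x)
        mask |= np.outer(near_h & in_y, in_x)
    return mask


def _cell_pixel_sets(design: GridDesign, cell: GridCell) -> tuple[np.ndarray, np.ndarray]:
    """(row slice mask, col slice mask) of pixel centers inside the cell."""
    h, w = design.shape_px
    ps = design.pixel_size_um
    xc = (np.arange(w) + 0.5) * ps
    yc = (np.arange(h) + 0.5) * ps
    cols = (xc > cell.x0) & (xc < cell.x1)
    rows = (yc > cell.y0) & (yc < cell.y1)
    return rows, cols


def expected_open_pixels(design: GridDesign, cell: GridCell) -> int:
    """Pixels of the cell farther than di/2 from every filament centerline.

    This is exactly the open window of the nominal-width rasterization, so a
    perfect print scores 1.0 with no quantization bias.
    """
    ps = design.pixel_size_um
    half = design.di_um / 2.0
    xc = (np.arange(int(round(design.canvas_um[0] / ps))) + 0.5) * ps
    yc = (np.arange(int(round(design.canvas_um[1] / ps))) + 0.5) * ps
    cols = (xc > cell.x0 + half) & (xc < cell.x1 - half)
    rows = (yc > cell.y0 + half) & (yc < cell.y1 - half)
    return int(cols.sum()) * int(rows.sum())


def score_print(
    mask: np.ndarray,
    design: GridDesign,
    weights: np.ndarray | None = None,
) -> PrintabilityResult:
    """Difficulty-weighted printability index of a printed binary mask.

    ``r_c`` is the open-pixel count inside cell c divided by the expected
    open pixels of the nominal print, clipped to [0, 1]; the index is the
    weight-normalized sum and a sample is printable iff it exceeds 0.33
    (strictly).
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask != 0
    if mask.shape != design.shape_px:
        raise ValueError(
            f"mask shape {mask.shape} does not match design canvas {design.shape_px}"
        )
    cells = design.included_cells()
    if weights is None:
        weights = difficulty_weights(design)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(cells),):
        raise ValueError("one weight per included cell required")
    r = np.empty(len(cells))
    for i, cell in enumerate(cells):
        rows, cols = _cell_pixel_sets(design, cell)
        open_px = int((~mask[np.ix_(rows, cols)]).sum())
        exp_px = expected_open_pixels(design, cell)
        r[i] = min(1.0, open_px / exp_px) if exp_px > 0 else 0.0
    wsum = weights.sum()
    score = float(np.dot(weights, r) / wsum)
    return PrintabilityResult(
        resolved=r,
        weights=weights / wsum,
        multipliers=np.array([c.multiplier for c in cells]),
        score=score,
        printable=bool(score > PRINTABLE_CUTOFF),
    )
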