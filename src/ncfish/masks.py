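"""Soma/neurite mask construction, neurite straightening, and
arc-length compartment partitioning.

Conventions: 0-based pixel indices in (row, col) order, pixel centers at
integer coordinates; physical lengths are pixel lengths times
``pixel_size_um``. A neurite is a user-traced centerline polyline expanded
into a corridor of ``width_px`` pixels; the soma is a user-drawn polygon.
Compartments along a neurite are proximal (first 20 um from the soma),
middle, and distal (last 20 um).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString, Polygon
from skimage.draw import polygon2mask

from .prep import PrepParams, threshold

log = logging.getLogger(__name__)

__all__ = [
    "NeuritePath",
    "CellMask",
    "CompartmentPartition",
    "build_cell_mask",
    "straighten",
    "partition_neurite",
    "region_area",
]

COMPARTMENTS = ("proximal", "middle", "distal")


@dataclass
class NeuritePath:
    """A traced neurite centerline.

    ``vertices`` are subpixel (row, col) points ordered from the soma
    outward; ``width_px`` is the corridor expansion (published range
    50-100 px, default the midpoint 75).
    """

    vertices: np.ndarray
    width_px: int = 75
    pixel_size_um: float = 0.05
    name: str = "neurite"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("vertices must be an (n>=2, 2) array of (row, col)")
        steps = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive vertices must be distinct")
        if self.width_px < 1:
            raise ValueError("width_px must be a positive integer")
        self.vertices = v
        self._steps = steps

    @property
    def arc_length_px(self) -> float:
        return float(self._steps.sum())

    @property
    def arc_length_um(self) -> float:
        return self.arc_length_px * self.pixel_size_um

    def resample(self, step_px: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
        """Points and unit tangents at equal arc-length steps.

        Returns ``(points, tangents)`` with points[j] at arc length
        ``j * step_px`` (the endpoint is always included).
        """
        v = self.vertices
        cum = np.concatenate([[0.0], np.cumsum(self._steps)])
        total = cum[-1]
        n = int(np.floor(total / step_px)) + 1
        s = np.arange(n) * step_px
        if total - s[-1] > 1e-9:
            s = np.append(s, total)
        rows = np.interp(s, cum, v[:, 0])
        cols = np.interp(s, cum, v[:, 1])
        pts = np.column_stack([rows, cols])
        tang = np.gradient(pts, s, axis=0) if len(s) > 1 else np.array([[1.0, 0.0]])
        norms = np.linalg.norm(tang, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return pts, tang / norms

    def arc_of_point(self, point: Sequence[float]) -> float:
        """Arc length (um) of the centerline point nearest to ``point``."""
        pts, _ = self.resample(1.0)
        d = np.linalg.norm(pts - np.asarray(point, dtype=float), axis=1)
        j = int(np.argmin(d))
        return min(float(j), self.arc_length_px) * self.pixel_size_um


@dataclass
class CellMask:
    """Binary soma and neurite masks for one cell.

    ``neurites`` pairs each traced path with its corridor mask. Pixels at
    the soma-neurite junction are assigned to the neurite (distal analysis
    is the focus), so soma and neurite masks are disjoint by construction.
    """

    soma: np.ndarray
    neurites: List[Tuple[NeuritePath, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        self.soma = np.asarray(self.soma, dtype=bool)
        self.neurites = [(p, np.asarray(m, dtype=bool)) for p, m in self.neurites]

    @property
    def whole_cell(self) -> np.ndarray:
        out = self.soma.copy()
        for _, m in self.neurites:
            out |= m
        return out


@dataclass
class CompartmentPartition:
    """Proximal / middle / distal arc-length intervals of one neurite."""

    total_um: float
    boundaries_um: Tuple[float, float]

    @property
    def segment_lengths_um(self) -> Tuple[float, float, float]:
        b1, b2 = self.boundaries_um
        return (b1, b2 - b1, self.total_um - b2)

    def label(self, arc_um: float) -> str:
        """Compartment containing the given arc position (um from soma)."""
        b1, b2 = self.boundaries_um
        if arc_um < b1:
            return "proximal"
        if arc_um < b2:
            return "middle"
        return "distal"


def partition_neurite(path: "NeuritePath | float", proximal_um: float = 20.0,
                      distal_um: float = 20.0) -> CompartmentPartition:
    """Split a neurite into proximal / middle / distal compartments.

    Accepts a :class:`NeuritePath` or a plain total arc length in um.
    The neurite must be at least ``proximal_um + distal_um`` long; shorter
    paths raise rather than silently collapsing to fewer compartments, so
    the caller decides how to handle stubby neurites.
    """
    total = path.arc_length_um if isinstance(path, NeuritePath) else float(path)
    if proximal_um < 0 or distal_um < 0:
        raise ValueError("compartment lengths must be nonnegative")
    if total < proximal_um + distal_um - 1e-9:
        raise ValueError(
            f"neurite of {total:.3g} um is shorter than proximal+distal "
            f"({proximal_um:g}+{distal_um:g} um); no silent fallback"
        )
    return CompartmentPartition(total_um=total,
                                boundaries_um=(proximal_um, total - distal_um))


def _rasterize_polygon(shape, vertices) -> np.ndarray:
    return polygon2mask(shape, np.asarray(vertices, dtype=float))


def _corridor_mask(shape, path: NeuritePath) -> np.ndarray:
    """Rasterize the centerline dilated to width_px (round caps)."""
    line = LineString(path.vertices)  # (row, col) treated as planar (x, y)
    poly = line.buffer(path.width_px / 2.0)
    if poly.is_empty:
        return np.zeros(shape, dtype=bool)
    geoms = poly.geoms if hasattr(poly, "geoms") else [poly]
    out = np.zeros(shape, dtype=bool)
    for g in geoms:
        out |= _rasterize_polygon(shape, np.asarray(g.exterior.coords))
    return out


def build_cell_mask(marker: np.ndarray, nucleus: Optional[np.ndarray],
                    soma_polygon: Sequence[Sequence[float]],
                    neurite_polylines: Sequence[NeuritePath],
                    params: Optional[PrepParams] = None,
                    corridor_only: bool = False) -> CellMask:
    """Build soma and neurite masks from the marker (IF) channel.

    The marker channel is thresholded to binary; the soma mask is the
    thresholded marker restricted to the user-drawn soma polygon (with the
    thresholded nucleus channel, if given, unioned into the soma support,
    since the nuclear stain sits inside the soma); each neurite mask is the
    thresholded marker restricted to the polyline corridor. With
    ``corridor_only=True`` the corridor itself is the mask, without the
    marker intersection.
    """
    marker = np.asarray(marker, dtype=float)
    shape = marker.shape
    fg = threshold(marker, params)
    if not fg.any():
        raise ValueError("marker channel is empty after thresholding")
    if nucleus is not None:
        nuc = np.asarray(nucleus, dtype=float)
        if nuc.max() > nuc.min():
            fg = fg | threshold(nuc, params)

    soma_poly = np.asarray(soma_polygon, dtype=float)
    if soma_poly.min() < -0.5 or (soma_poly.max(axis=0) > np.array(shape) - 0.5).any():
        raise ValueError("soma polygon exceeds image bounds")
    soma = _rasterize_polygon(shape, soma_poly)
    soma &= fg

    neurites = []
    neurite_union = np.zeros(shape, dtype=bool)
    for path in neurite_polylines:
        corridor = _corridor_mask(shape, path)
        m = corridor if corridor_only else (corridor & fg)
        if not m.any():
            log.warning("neurite %r lies outside the marker support", path.name)
            raise ValueError(
                f"neurite {path.name!r}: corridor does not intersect the "
                "thresholded marker (empty mask)"
            )
        neurites.append((path, m))
        neurite_union |= m
    # junction pixels go to the neurite
    soma &= ~neurite_union
    if not soma.any() and soma_poly.size:
        raise ValueError("soma mask is empty after thresholding")
    return CellMask(soma=soma, neurites=neurites)


def straighten(img: np.ndarray, path: NeuritePath) -> np.ndarray:
    """Resample the image along a neurite into a straight rectangle.

    Output has ``path.width_px`` rows (spanning the corridor normal,
    centered on the centerline) and ``round(arc length in px) + 1``
    columns; column ``j`` samples the image at arc length ``j`` along the
    path by bilinear interpolation. Samples falling outside the image are
    zero-filled with a logged warning. An axis-aligned straight path with
    odd width therefore reproduces the corresponding crop exactly.
    """
    img = np.asarray(img, dtype=float)
    pts, tang = path.resample(1.0)
    n_cols = int(round(path.arc_length_px)) + 1
    s = np.linspace(0.0, path.arc_length_px, n_cols)
    cum = np.arange(len(pts), dtype=float)
    cum[-1] = path.arc_length_px
    rows_c = np.interp(s, cum, pts[:, 0])
    cols_c = np.interp(s, cum, pts[:, 1])
    t_r = np.interp(s, cum, tang[:, 0])
    t_c = np.interp(s, cum, tang[:, 1])
    nrm = np.hypot(t_r, t_c)
    nrm[nrm == 0] = 1.0
    # normal = tangent rotated 90 degrees; the sign keeps a left-to-right
    # horizontal path mapping onto the crop in natural row order
    n_r, n_c = t_c / nrm, -t_r / nrm
    w = path.width_px
    offsets = np.arange(w, dtype=float) - (w - 1) / 2.0
    rr = rows_c[None, :] + offsets[:, None] * n_r[None, :]
    cc = cols_c[None, :] + offsets[:, None] * n_c[None, :]
    outside = ((rr < 0) | (rr > img.shape[0] - 1) | (cc < 0) | (cc > img.shape[1] - 1))
    if outside.any():
        log.warning("straighten: %d samples fall outside the image; zero-filled",
                    int(outside.sum()))
    return map_coordinates(img, [rr, cc], order=1, mode="constant", cval=0.0)


def region_area(mask: np.ndarray, pixel_size_um: float) -> float:
    """Area of a binary region in um^2 (pixel count times pixel area)."""
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(np.unique(mask), [0, 1]).all():
        raise ValueError("mask must be binary")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return float(np.count_nonzero(mask)) * pixel_size_um ** 2
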