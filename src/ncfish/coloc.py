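"""Object-based colocalization scoring.

A reference object (an mRNA spot or punctum) counts as colocalized with a
target channel when the fraction of its pixel support covered by some
target object reaches a threshold — the published criterion is >= 50%
spatial overlap. Point detections are rasterized to disks of radius
``ceil(2 * sigma_dog)`` pixels before overlap is computed, since a point
has no footprint of its own. Mander's coefficients and corridor line
scans complete the colocalization readouts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree
from skimage.draw import disk

from .masks import NeuritePath
from .spots import Punctum, PunctumSet, Spot, SpotSet

log = logging.getLogger(__name__)

__all__ = [
    "ColocReport",
    "rasterize_spots",
    "overlap_fraction",
    "pairwise_coloc",
    "triple_coloc",
    "manders",
    "line_scan",
]


@dataclass
class ColocReport:
    """Per-object and aggregate colocalization result.

    ``fraction`` is colocalized reference objects over all reference
    objects considered; ``per_object`` holds each reference object's best
    overlap fraction (max over target objects). Per-compartment counts are
    filled when reference objects carry compartment labels.
    """

    reference_channel: str
    target_channels: List[str]
    threshold: float
    n_reference: int
    n_target: Dict[str, int]
    colocalized: int
    fraction: float
    per_object: np.ndarray
    per_compartment: Dict[str, Dict[str, int]] = field(default_factory=dict)
    warning: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-reference-object table."""
        return pd.DataFrame({
            "reference_channel": self.reference_channel,
            "object": np.arange(self.n_reference),
            "best_overlap": self.per_object,
            "colocalized": self.per_object >= self.threshold,
        })


def rasterize_spots(spotset: SpotSet, shape, sigma_dog: float = 1.4975) -> PunctumSet:
    """Give point detections a pixel footprint: a disk of radius
    ``ceil(2 * sigma_dog)`` centered on each subpixel position."""
    radius = math.ceil(2.0 * sigma_dog)
    puncta = []
    for s in spotset.spots:
        rr, cc = disk(s.position, radius + 0.5, shape=shape)
        p = Punctum(support=np.column_stack([rr, cc]), centroid=s.position,
                    mean_intensity=s.intensity, compartment=s.compartment,
                    neurite=s.neurite, arc_um=s.arc_um)
        puncta.append(p)
    return PunctumSet(puncta=puncta, channel=spotset.channel)


def _support_set(obj) -> set:
    if isinstance(obj, Punctum):
        return set(map(tuple, np.asarray(obj.support, dtype=int)))
    if isinstance(obj, np.ndarray) and obj.dtype == bool:
        return set(map(tuple, np.argwhere(obj)))
    raise TypeError(f"cannot rasterize object of type {type(obj).__name__}; "
                    "rasterize spots to disks first")


def overlap_fraction(obj_a, obj_b) -> float:
    """Fraction of A's pixel support covered by B, in [0, 1].

    The denominator is the reference object A; the measure is therefore
    asymmetric. Both objects must be rasterized on the same grid.
    """
    a = _support_set(obj_a)
    if not a:
        raise ValueError("reference object has empty support")
    b = _support_set(obj_b)
    return len(a & b) / len(a)


def _restrict(puncta: List[Punctum], mask: Optional[np.ndarray]) -> List[Punctum]:
    if mask is None:
        return list(puncta)
    out = []
    for p in puncta:
        r, c = int(round(p.centroid[0])), int(round(p.centroid[1]))
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
            out.append(p)
    return out


def _best_overlaps(ref: List[Punctum], target: List[Punctum]) -> np.ndarray:
    """Max overlap fraction per reference object, pruned by centroid distance."""
    best = np.zeros(len(ref))
    if not ref or not target:
        return best
    t_pos = np.array([p.centroid for p in target])
    t_rad = np.array([np.linalg.norm(np.asarray(p.support, float) - p.centroid, axis=1).max(initial=0.0)
                      for p in target])
    tree = cKDTree(t_pos)
    max_t_rad = float(t_rad.max(initial=0.0))
    for i, a in enumerate(ref):
        a_rad = float(np.linalg.norm(np.asarray(a.support, float) - a.centroid, axis=1).max(initial=0.0))
        cand = tree.query_ball_point(a.centroid, r=a_rad + max_t_rad + 1.5)
        if not cand:
            continue
        a_set = _support_set(a)
        best[i] = max((len(a_set & _support_set(target[j])) / len(a_set)
                       for j in cand), default=0.0)
    return best


def _as_puncta(objset: Union[SpotSet, PunctumSet], shape,
               sigma_dog: float) -> PunctumSet:
    if isinstance(objset, SpotSet):
        return rasterize_spots(objset, shape, sigma_dog)
    return objset


def _compartment_table(ref: List[Punctum], coloc: np.ndarray) -> Dict[str, Dict[str, int]]:
    out: Dict[str, Dict[str, int]] = {}
    for p, hit in zip(ref, coloc):
        comp = p.compartment or "all"
        d = out.setdefault(comp, {"n": 0, "colocalized": 0})
        d["n"] += 1
        d["colocalized"] += int(hit)
    return out


def pairwise_coloc(ref: Union[SpotSet, PunctumSet], target: Union[SpotSet, PunctumSet],
                   threshold: float = 0.5, mask: Optional[np.ndarray] = None,
                   shape=None, sigma_dog: float = 1.4975) -> ColocReport:
    """Score reference-channel objects against one target channel.

    A reference object is colocalized iff its best overlap fraction over
    all target objects reaches ``threshold``. Objects whose centroid falls
    outside ``mask`` (if given) are excluded. Zero reference objects in
    the mask is not an error; the report carries a warning flag instead.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if shape is None:
        shape = mask.shape if mask is not None else None
    if shape is None:
        raise ValueError("provide mask or shape to rasterize objects on")
    ref_p = _restrict(_as_puncta(ref, shape, sigma_dog).puncta, mask)
    tgt_p = _restrict(_as_puncta(target, shape, sigma_dog).puncta, mask)
    best = _best_overlaps(ref_p, tgt_p)
    hits = best >= threshold
    warning = None
    if len(ref_p) == 0:
        warning = "no reference objects inside the analysis mask"
        log.warning(warning)
    frac = float(hits.mean()) if len(ref_p) else 0.0
    return ColocReport(
        reference_channel=ref.channel, target_channels=[target.channel],
        threshold=threshold, n_reference=len(ref_p),
        n_target={target.channel: len(tgt_p)},
        colocalized=int(hits.sum()), fraction=frac, per_object=best,
        per_compartment=_compartment_table(ref_p, hits), warning=warning,
    )


def triple_coloc(a: Union[SpotSet, PunctumSet], b: Union[SpotSet, PunctumSet],
                 c: Union[SpotSet, PunctumSet], threshold: float = 0.5,
                 mask: Optional[np.ndarray] = None, shape=None,
                 sigma_dog: float = 1.4975) -> ColocReport:
    """Reference objects overlapping BOTH other channels independently.

    Each reference object must reach ``threshold`` against channel b and,
    separately, against channel c (e.g. an mRNA simultaneously on a
    mitochondrion and on a ribosomal cluster). The triple count can never
    exceed either pairwise count.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if shape is None:
        shape = mask.shape if mask is not None else None
    if shape is None:
        raise ValueError("provide mask or shape to rasterize objects on")
    ref_p = _restrict(_as_puncta(a, shape, sigma_dog).puncta, mask)
    b_p = _restrict(_as_puncta(b, shape, sigma_dog).puncta, mask)
    c_p = _restrict(_as_puncta(c, shape, sigma_dog).puncta, mask)
    best_b = _best_overlaps(ref_p, b_p)
    best_c = _best_overlaps(ref_p, c_p)
    hits = (best_b >= threshold) & (best_c >= threshold)
    warning = None
    if len(ref_p) == 0:
        warning = "no reference objects inside the analysis mask"
        log.warning(warning)
    return ColocReport(
        reference_channel=a.channel, target_channels=[b.channel, c.channel],
        threshold=threshold, n_reference=len(ref_p),
        n_target={b.channel: len(b_p), c.channel: len(c_p)},
        colocalized=int(hits.sum()),
        fraction=float(hits.mean()) if len(ref_p) else 0.0,
        per_object=np.minimum(best_b, best_c),
        per_compartment=_compartment_table(ref_p, hits), warning=warning,
    )


def manders(img_a: np.ndarray, img_b: np.ndarray, thr_a: float, thr_b: float,
            mask: Optional[np.ndarray] = None):
    """Mander's colocalization coefficients (M1, M2).

    M1 is the fraction of channel-a intensity residing in pixels where
    channel b exceeds its threshold; M2 is the symmetric quantity. Both
    live in [0, 1]. Thresholds should come from the preprocessing stage
    and are the caller's responsibility to log.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    sel = np.ones(a.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    a_tot = a[sel].sum()
    b_tot = b[sel].sum()
    if a_tot <= 0 or b_tot <= 0:
        raise ValueError("zero total intensity in a channel within the mask")
    m1 = a[sel & (b > thr_b)].sum() / a_tot
    m2 = b[sel & (a > thr_a)].sum() / b_tot
    return float(m1), float(m2)


def line_scan(images: Dict[str, np.ndarray], path: NeuritePath,
              step_px: float = 1.0) -> pd.DataFrame:
    """Per-channel intensity profile along a neurite.

    At each arc step the intensity is the mean across the corridor normal
    (``path.width_px`` bilinear samples). Returns a tidy frame with
    columns ``arc_um``, ``channel``, ``intensity``; all channels share the
    same arc grid.
    """
    pts, tang = path.resample(step_px)
    n_r, n_c = tang[:, 1], -tang[:, 0]
    w = path.width_px
    offsets = np.arange(w, dtype=float) - (w - 1) / 2.0
    rr = pts[:, 0][None, :] + offsets[:, None] * n_r[None, :]
    cc = pts[:, 1][None, :] + offsets[:, None] * n_c[None, :]
    arc_um = np.arange(len(pts)) * step_px * path.pixel_size_um
    arc_um[-1] = path.arc_length_um
    frames = []
    for name, img in images.items():
        samples = map_coordinates(np.asarray(img, dtype=float), [rr, cc],
                                  order=1, mode="constant", cval=0.0)
        frames.append(pd.DataFrame({
            "arc_um": arc_um, "channel": name, "intensity": samples.mean(axis=0),
        }))
    return pd.concat(frames, ignore_index=True)
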