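"""Compartment-normalized readouts.

These are the quantities the imaging figures plot: corrected total cell
fluorescence (CTCF), per-um^2 intensity ratios, per-compartment spot
densities and the neurite-to-soma density ratio, regional (proximal /
middle / distal) distribution fractions, and transfection efficiency.
The same density code path serves smFISH spot counts and Puro-PLA puncta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .masks import COMPARTMENTS, CellMask, CompartmentPartition, region_area
from .spots import PunctumSet, SpotSet

log = logging.getLogger(__name__)

__all__ = [
    "CompartmentStats",
    "ctcf",
    "intensity_ratio",
    "density_stats",
    "regional_distribution",
    "transfection_efficiency",
]


@dataclass
class CompartmentStats:
    """Per-compartment counts, areas and densities for one cell.

    ``table`` has one row per (neurite, compartment) plus one soma row:
    columns ``neurite, compartment, count, area_um2, density``.
    ``neurite_soma_ratio`` maps each neurite name to its whole-neurite
    density divided by the soma density (NaN, with a flag, when the soma
    density is zero). ``per_neurite_fractions`` are proximal/middle/distal
    fractions of that neurite's in-neurite objects.
    """

    table: pd.DataFrame
    soma_density: float
    neurite_soma_ratio: Dict[str, float]
    per_neurite_fractions: Dict[str, Dict[str, float]]
    n_outside: int
    ratio_defined: bool = True


def ctcf(img: np.ndarray, region: np.ndarray, background: np.ndarray) -> float:
    """Corrected total cell fluorescence.

    Integrated intensity over the region minus region area times the mean
    background intensity. Adding a constant to the whole image leaves the
    result unchanged, which is the point of the correction.
    """
    img = np.asarray(img, dtype=float)
    region = np.asarray(region, dtype=bool)
    background = np.asarray(background, dtype=bool)
    if not region.any():
        raise ValueError("CTCF region is empty")
    if not background.any():
        raise ValueError("CTCF background region is empty")
    if (region & background).any():
        raise ValueError("region and background must be disjoint")
    integrated = img[region].sum()
    return float(integrated - region.sum() * img[background].mean())


def intensity_ratio(img: np.ndarray, soma_mask: np.ndarray,
                    neurite_mask: np.ndarray, pixel_size_um: float) -> float:
    """Neurite intensity per um^2 divided by soma intensity per um^2.

    Per-area intensity is total intensity over mask area; since both
    numerator and denominator carry the same pixel-area factor the result
    equals the ratio of mean pixel intensities. Returns NaN (with a
    logged flag) when the soma carries no signal.
    """
    img = np.asarray(img, dtype=float)
    soma_mask = np.asarray(soma_mask, dtype=bool)
    neurite_mask = np.asarray(neurite_mask, dtype=bool)
    if not soma_mask.any() or not neurite_mask.any():
        raise ValueError("both masks must be non-empty")
    soma_density = img[soma_mask].sum() / region_area(soma_mask, pixel_size_um)
    neur_density = img[neurite_mask].sum() / region_area(neurite_mask, pixel_size_um)
    if soma_density == 0:
        log.warning("intensity_ratio undefined: zero soma signal")
        return float("nan")
    return float(neur_density / soma_density)


def _neurite_compartment_areas(cellmask: CellMask,
                               partitions: Sequence[Optional[CompartmentPartition]],
                               pixel_size_um: float) -> Dict[str, Dict[str, float]]:
    """Split each neurite mask's area by arc-length compartment.

    Every mask pixel is assigned to the compartment of its nearest
    centerline point.
    """
    areas: Dict[str, Dict[str, float]] = {}
    px_area = pixel_size_um ** 2
    for (path, m), part in zip(cellmask.neurites, partitions):
        pix = np.argwhere(m)
        if part is None:
            areas[path.name] = {"neurite": len(pix) * px_area}
            continue
        pts, _ = path.resample(1.0)
        tree = cKDTree(pts)
        _, idx = tree.query(pix.astype(float))
        arc_um = np.minimum(idx, path.arc_length_px) * pixel_size_um
        d: Dict[str, float] = {c: 0.0 for c in COMPARTMENTS}
        for a in arc_um:
            d[part.label(float(a))] += px_area
        areas[path.name] = d
    return areas


def density_stats(objects: Union[SpotSet, PunctumSet], cellmask: CellMask,
                  partitions: Optional[Sequence[Optional[CompartmentPartition]]],
                  pixel_size_um: float) -> CompartmentStats:
    """Per-compartment object counts, areas, densities, and ratios.

    ``objects`` must already carry compartment labels (see
    :func:`ncfish.spots.assign_to_compartments`). Objects labeled
    ``"outside"`` are kept out of every density. Compartment areas are
    derived from the masks themselves, so densities are count / area with
    consistent geometry, and compartment counts always sum to the in-mask
    total.
    """
    items = objects.spots if isinstance(objects, SpotSet) else objects.puncta
    if partitions is None:
        partitions = [None] * len(cellmask.neurites)
    if any(i.compartment is None for i in items):
        raise ValueError("objects are unlabeled; run assign_to_compartments first")

    soma_area = region_area(cellmask.soma, pixel_size_um)
    if soma_area == 0:
        raise ValueError("soma compartment has zero area")
    n_soma = sum(1 for i in items if i.compartment == "soma")
    n_outside = sum(1 for i in items if i.compartment == "outside")
    soma_density = n_soma / soma_area

    comp_areas = _neurite_compartment_areas(cellmask, partitions, pixel_size_um)
    rows = [{"neurite": "soma", "compartment": "soma", "count": n_soma,
             "area_um2": soma_area, "density": soma_density}]
    ratios: Dict[str, float] = {}
    fractions: Dict[str, Dict[str, float]] = {}
    ratio_defined = soma_density > 0
    for (path, m), part in zip(cellmask.neurites, partitions):
        name = path.name
        comps = list(comp_areas[name].keys())
        counts = {c: 0 for c in comps}
        for i in items:
            if i.neurite == name and i.compartment in counts:
                counts[i.compartment] += 1
        total_count = sum(counts.values())
        total_area = sum(comp_areas[name].values())
        if total_area == 0:
            raise ValueError(f"neurite {name!r} has zero mask area")
        for c in comps:
            area = comp_areas[name][c]
            rows.append({"neurite": name, "compartment": c, "count": counts[c],
                         "area_um2": area,
                         "density": counts[c] / area if area > 0 else 0.0})
        density = total_count / total_area
        if soma_density > 0:
            ratios[name] = density / soma_density
        else:
            ratios[name] = 0.0 if total_count == 0 else float("nan")
            if total_count:
                log.warning("neurite/soma ratio undefined for %r: soma density 0", name)
        fractions[name] = ({c: counts[c] / total_count for c in comps}
                           if total_count > 0 else {c: float("nan") for c in comps})
    return CompartmentStats(table=pd.DataFrame(rows), soma_density=soma_density,
                            neurite_soma_ratio=ratios,
                            per_neurite_fractions=fractions,
                            n_outside=n_outside, ratio_defined=ratio_defined)


def regional_distribution(arc_positions_um: Sequence[float],
                          partition: CompartmentPartition) -> Dict[str, float]:
    """Proximal/middle/distal fractions of colocalized objects.

    ``arc_positions_um`` are the arc positions of the colocalized puncta
    along one neurite; each regional count is expressed as a fraction of
    the total, so the three fractions sum to 1. Zero objects is flagged
    undefined (NaN fractions) rather than silently zero.
    """
    arcs = np.asarray(list(arc_positions_um), dtype=float)
    if arcs.size == 0:
        log.warning("regional_distribution undefined: zero colocalized objects")
        return {c: float("nan") for c in COMPARTMENTS}
    counts = {c: 0 for c in COMPARTMENTS}
    for a in arcs:
        counts[partition.label(float(a))] += 1
    n = arcs.size
    return {c: counts[c] / n for c in COMPARTMENTS}


def transfection_efficiency(cells: Sequence[Tuple[object, bool]]) -> float:
    """Marker-positive cells over all cells, in [0, 1]."""
    cells = list(cells)
    if not cells:
        raise ValueError("no cells recorded")
    positive = sum(1 for _, flag in cells if flag)
    return positive / len(cells)
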