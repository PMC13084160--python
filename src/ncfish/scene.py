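"""Ground-truthed synthetic neuron scenes and assay tables.

The generator emulates the statistical structure of compartment-resolved
smFISH experiments in cultured neurons: a round soma with a nuclear
stain, a few traced neurites, diffraction-limited mRNA spots rendered as
analytic 2D Gaussians (no point-mask convolution, so the truth
coordinates are unambiguous), clustered ribosomal puncta, elongated
mitochondrial blobs, a planted colocalization fraction, constant
background with additive Gaussian noise (Poisson optionally), plus
synthetic qPCR Ct tables and RNA-seq count tables with planted
enrichments. Every scene carries a complete truth record so pipeline
estimates can be scored against exact planted values.

Colocalization planting: for each target channel (ribosome,
mitochondria), ``round(coloc_fraction * n_target)`` target objects are
centered within 1 px of distinct mRNA spots; the remaining target objects
are kept at least ``clear_margin_px`` away from every mRNA spot so the
planted fraction is the only source of overlap. When the target channel
has as many objects as the mRNA channel (the default), the planted
fraction is therefore also the fraction of mRNA spots with a partner —
the quantity an mRNA-referenced overlap analysis estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.draw import polygon2mask

from .masks import NeuritePath, _corridor_mask
from .prep import ImageScene

__all__ = [
    "ScenarioParams",
    "SceneTruth",
    "SyntheticScene",
    "generate_scene",
    "generate_ct_table",
    "generate_count_table",
]

EDGE_MARGIN_PX = 10  # geometry must keep this far from the border


@dataclass
class ScenarioParams:
    """Study conditions for one synthetic scene.

    Defaults emulate a differentiated neuronal cell imaged at
    0.05 um/px: a 5-um-radius soma, three neurites 15-18 um long,
    100 mRNA spots with a 1.5-px Gaussian PSF at 10x the noise SD,
    and a planted colocalization fraction of 0.6 for both the ribosome
    and the mitochondria channels.
    """

    image_shape: Tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.05
    soma_radius_um: float = 5.0
    neurite_specs: Sequence[Tuple[float, float, float]] = (
        (18.0, 1.6, 15.0), (15.0, 1.4, 135.0), (16.0, 1.2, 255.0),
    )  # (length_um, width_um, start_angle_deg)
    n_spots_per_channel: Dict[str, int] = field(
        default_factory=lambda: {"rna": 100, "ribosome": 100})
    psf_sigma_px: float = 1.5
    spot_amplitude: float = 0.5
    coloc_fraction: Union[float, Dict[str, float]] = 0.6
    mito_specs: Tuple[int, float, float] = (30, 2.0, 0.5)  # count, length, width um
    background_level: float = 0.1
    noise_sd: float = 0.05
    poisson_noise: bool = False
    neurite_density_weight: float = 1.0
    ribosome_sigma_px: float = 2.5
    ribosome_amplitude: float = 0.8
    mito_amplitude: float = 0.7
    clear_margin_px: float = 12.0
    min_spot_separation_px: float = 6.0

    def __post_init__(self):
        if not (0 <= self._coloc_min() and self._coloc_max() <= 1):
            raise ValueError("coloc_fraction must lie in [0, 1]")
        for name, val in (("pixel_size_um", self.pixel_size_um),
                          ("soma_radius_um", self.soma_radius_um),
                          ("psf_sigma_px", self.psf_sigma_px)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be nonnegative")
        if any(n < 0 for n in self.n_spots_per_channel.values()):
            raise ValueError("spot counts must be nonnegative")
        for i, (length, width, _) in enumerate(self.neurite_specs):
            if length <= 0 or width <= 0:
                raise ValueError(f"neurite {i}: length and width must be positive")

    def _coloc_values(self):
        if isinstance(self.coloc_fraction, dict):
            return list(self.coloc_fraction.values()) or [0.0]
        return [self.coloc_fraction]

    def _coloc_min(self):
        return min(self._coloc_values())

    def _coloc_max(self):
        return max(self._coloc_values())

    def coloc_for(self, channel: str) -> float:
        if isinstance(self.coloc_fraction, dict):
            return float(self.coloc_fraction.get(channel, 0.0))
        return float(self.coloc_fraction)


@dataclass
class SceneTruth:
    """Exact planted record for one scene."""

    spots: Dict[str, np.ndarray]            # channel -> (n, 2) subpixel (row, col)
    coloc_labels: Dict[str, np.ndarray]     # target channel -> bool per object
    coloc_partner: Dict[str, np.ndarray]    # target channel -> rna index or -1
    rna_has_partner: Dict[str, np.ndarray]  # target channel -> bool per rna spot
    soma_polygon: np.ndarray
    nucleus_polygon: np.ndarray
    neurite_paths: List[NeuritePath]
    cell_region: np.ndarray                 # boolean soma+neurite support
    soma_region: np.ndarray
    neurite_regions: List[np.ndarray]


@dataclass
class SyntheticScene:
    images: ImageScene
    truth: SceneTruth
    params: ScenarioParams
    seed: int


def _circle_polygon(center, radius_px, n=72) -> np.ndarray:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius_px * np.sin(t),
                            center[1] + radius_px * np.cos(t)])


def _add_gaussian(img: np.ndarray, r: float, c: float, amp: float,
                  sig_r: float, sig_c: float, theta: float = 0.0):
    """Add one analytic (possibly rotated, anisotropic) Gaussian in place."""
    ext = int(math.ceil(4.0 * max(sig_r, sig_c))) + 1
    r0, r1 = max(int(r) - ext, 0), min(int(r) + ext + 1, img.shape[0])
    c0, c1 = max(int(c) - ext, 0), min(int(c) + ext + 1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - r, cc - c
    if theta != 0.0:
        ct, st = math.cos(theta), math.sin(theta)
        dr, dc = ct * dr + st * dc, -st * dr + ct * dc
    img[r0:r1, c0:c1] += amp * np.exp(-0.5 * ((dr / sig_r) ** 2 + (dc / sig_c) ** 2))


def _sample_positions(rng, n, soma_pixels, neurite_pixels, weight, margin, shape,
                      min_dist: float = 0.0):
    """Uniform subpixel positions over the cell, soma vs neurite weighted.

    ``min_dist`` enforces a minimum pairwise separation (rejection
    sampling) so rendered spots stay resolvable.
    """
    pools = []
    weights = []
    if len(soma_pixels):
        pools.append(soma_pixels)
        weights.append(1.0 * len(soma_pixels))
    if len(neurite_pixels):
        pools.append(neurite_pixels)
        weights.append(weight * len(neurite_pixels))
    if not pools:
        raise ValueError("cell region is empty; cannot place spots")
    weights = np.asarray(weights) / np.sum(weights)
    out = np.empty((n, 2))
    k = 0
    attempts = 0
    while k < n:
        pool = pools[rng.choice(len(pools), p=weights)]
        r, c = pool[rng.integers(len(pool))]
        pos = np.array([r, c], dtype=float) + rng.uniform(-0.5, 0.5, 2)
        pos = np.clip(pos, margin, np.array(shape, dtype=float) - 1 - margin)
        if min_dist > 0 and k and np.linalg.norm(out[:k] - pos, axis=1).min() < min_dist:
            attempts += 1
            if attempts > 200 * n + 1000:
                raise RuntimeError("could not satisfy spot separation; too crowded")
            continue
        out[k] = pos
        k += 1
    return out


def generate_scene(params: Optional[ScenarioParams] = None, seed: int = 0) -> SyntheticScene:
    """Render one ground-truthed multi-channel scene.

    Deterministic for fixed ``(params, seed)``. Raises if a neurite does
    not fit inside the image (naming the offending neurite).
    """
    params = params or ScenarioParams()
    rng = np.random.default_rng(seed)
    shape = tuple(params.image_shape)
    px = params.pixel_size_um
    center = np.array([shape[0] / 2.0, shape[1] / 2.0])
    soma_r_px = params.soma_radius_um / px

    # --- geometry ---------------------------------------------------------
    soma_poly = _circle_polygon(center, soma_r_px)
    nucleus_poly = _circle_polygon(center, 0.55 * soma_r_px, n=48)
    paths: List[NeuritePath] = []
    for i, (length_um, width_um, angle_deg) in enumerate(params.neurite_specs):
        ang = math.radians(angle_deg)
        direction = np.array([math.sin(ang), math.cos(ang)])
        start = center + soma_r_px * 0.98 * direction
        length_px = length_um / px
        n_seg = max(int(length_px // 25), 1)
        ts = np.linspace(0.0, 1.0, n_seg + 1)
        lateral = np.array([direction[1], -direction[0]])
        wiggle = rng.uniform(-3.0, 3.0, n_seg + 1)
        wiggle[0] = 0.0
        verts = (start[None, :] + ts[:, None] * length_px * direction[None, :]
                 + wiggle[:, None] * lateral[None, :])
        if (verts.min() < EDGE_MARGIN_PX
                or (verts > np.array(shape) - 1 - EDGE_MARGIN_PX).any()):
            raise ValueError(
                f"neurite {i} (length {length_um} um at {angle_deg} deg) does "
                f"not fit inside image {shape} at {px} um/px"
            )
        width_px = max(int(round(width_um / px)), 3)
        paths.append(NeuritePath(vertices=verts, width_px=width_px,
                                 pixel_size_um=px, name=f"neurite_{i}"))

    soma_region = polygon2mask(shape, soma_poly)
    neurite_regions = [_corridor_mask(shape, p) & ~soma_region for p in paths]
    cell_region = soma_region.copy()
    for m in neurite_regions:
        cell_region |= m

    soma_pixels = np.argwhere(soma_region)
    neur_pixels = (np.concatenate([np.argwhere(m) for m in neurite_regions])
                   if neurite_regions else np.empty((0, 2), dtype=int))
    margin = 5.0 * params.psf_sigma_px

    # --- mRNA spots -------------------------------------------------------
    n_rna = int(params.n_spots_per_channel.get("rna", 0))
    rna_pos = (_sample_positions(rng, n_rna, soma_pixels, neur_pixels,
                                 params.neurite_density_weight, margin, shape,
                                 min_dist=params.min_spot_separation_px)
               if n_rna else np.empty((0, 2)))

    spots: Dict[str, np.ndarray] = {"rna": rna_pos}
    coloc_labels: Dict[str, np.ndarray] = {}
    coloc_partner: Dict[str, np.ndarray] = {}
    rna_has_partner: Dict[str, np.ndarray] = {}

    def plant_targets(channel: str, n_obj: int) -> np.ndarray:
        """Positions for a target channel with the planted coloc fraction."""
        frac = params.coloc_for(channel)
        n_coloc = int(round(frac * n_obj))
        if n_coloc > n_rna:
            raise ValueError(
                f"cannot plant {n_coloc} colocalized {channel} objects with "
                f"only {n_rna} rna spots"
            )
        labels = np.zeros(n_obj, dtype=bool)
        partner = np.full(n_obj, -1, dtype=int)
        pos = np.empty((n_obj, 2))
        chosen = (rng.choice(n_rna, size=n_coloc, replace=False)
                  if n_coloc else np.empty(0, dtype=int))
        for k, idx in enumerate(chosen):
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 0.9)
            pos[k] = rna_pos[idx] + rad * np.array([math.sin(ang), math.cos(ang)])
            labels[k] = True
            partner[k] = idx
        # the rest go anywhere in the cell but clear of every rna spot
        k = n_coloc
        attempts = 0
        while k < n_obj:
            cand = _sample_positions(rng, 1, soma_pixels, neur_pixels,
                                     params.neurite_density_weight, margin, shape)[0]
            if (n_rna == 0 or
                    np.linalg.norm(rna_pos - cand, axis=1).min() >= params.clear_margin_px):
                pos[k] = cand
                k += 1
            attempts += 1
            if attempts > 200 * n_obj + 1000:
                raise RuntimeError(
                    f"could not place clear {channel} objects; scene too crowded"
                )
        mask_rna = np.zeros(n_rna, dtype=bool)
        mask_rna[chosen] = True
        coloc_labels[channel] = labels
        coloc_partner[channel] = partner
        rna_has_partner[channel] = mask_rna
        return pos

    n_ribo = int(params.n_spots_per_channel.get("ribosome", 0))
    ribo_pos = plant_targets("ribosome", n_ribo) if n_ribo else np.empty((0, 2))
    spots["ribosome"] = ribo_pos

    n_mito = int(params.mito_specs[0])
    mito_pos = plant_targets("mito", n_mito) if n_mito else np.empty((0, 2))
    mito_theta = rng.uniform(0, math.pi, n_mito)
    spots["mito"] = mito_pos

    # --- render channels --------------------------------------------------
    bg = params.background_level
    marker = np.full(shape, 0.05)
    marker[cell_region] = 0.9
    nucleus_img = np.full(shape, 0.05)
    nucleus_img[polygon2mask(shape, nucleus_poly)] = 0.9

    rna_img = np.full(shape, bg)
    for r, c in rna_pos:
        _add_gaussian(rna_img, r, c, params.spot_amplitude,
                      params.psf_sigma_px, params.psf_sigma_px)

    ribo_img = np.full(shape, bg)
    for r, c in ribo_pos:
        _add_gaussian(ribo_img, r, c, params.ribosome_amplitude,
                      params.ribosome_sigma_px, params.ribosome_sigma_px)

    mito_img = np.full(shape, bg)
    sig_l = params.mito_specs[1] / px / 4.0
    sig_w = params.mito_specs[2] / px / 2.0
    for (r, c), th in zip(mito_pos, mito_theta):
        _add_gaussian(mito_img, r, c, params.mito_amplitude, sig_l, sig_w, th)

    channels = {"marker": marker, "nucleus": nucleus_img, "rna": rna_img,
                "ribosome": ribo_img, "mito": mito_img}
    for name, img in channels.items():
        if params.poisson_noise:
            scale = 1000.0
            img = rng.poisson(np.clip(img, 0, None) * scale) / scale
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, shape)
        channels[name] = np.clip(img, 0.0, None)

    truth = SceneTruth(spots=spots, coloc_labels=coloc_labels,
                       coloc_partner=coloc_partner,
                       rna_has_partner=rna_has_partner,
                       soma_polygon=soma_poly, nucleus_polygon=nucleus_poly,
                       neurite_paths=paths, cell_region=cell_region,
                       soma_region=soma_region, neurite_regions=neurite_regions)
    _check_truth(truth, params, shape)
    return SyntheticScene(images=ImageScene(channels=channels, pixel_size_um=px),
                          truth=truth, params=params, seed=seed)


def _check_truth(truth: SceneTruth, params: ScenarioParams, shape):
    for channel, pos in truth.spots.items():
        if pos.size and (pos.min() < 0 or (pos > np.array(shape) - 1).any()):
            raise AssertionError(f"truth spots of {channel!r} leave the image")
    n_rna = int(params.n_spots_per_channel.get("rna", 0))
    if len(truth.spots["rna"]) != n_rna:
        raise AssertionError("rna truth count mismatch")
    for channel, labels in truth.coloc_labels.items():
        want = round(params.coloc_for(channel) * len(labels))
        if int(labels.sum()) != want:
            raise AssertionError(f"planted coloc count mismatch for {channel!r}")


def generate_ct_table(genes: Sequence[str], fractions: Sequence[str],
                      planted_log2_enrichment: Dict[str, Union[float, Dict[str, float]]],
                      n_reps: int = 3, noise_sd: float = 0.0, seed: int = 0,
                      baseline_ct: float = 22.0):
    """Synthetic qPCR Ct table with planted fraction enrichments.

    ``Ct(gene, fraction) = baseline - shift + N(0, noise_sd)``, one row per
    replicate. A scalar planted value is shorthand for a shift applied to
    the first listed fraction (i.e. a log2 enrichment of ``fractions[0]``
    relative to the rest); a dict gives per-fraction shifts. Gene
    baselines are staggered by 1.5 cycles for realism. Deterministic per
    seed.
    """
    import pandas as pd

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    unknown = set(planted_log2_enrichment) - set(genes)
    if unknown:
        raise ValueError(f"planted enrichment for unknown genes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for gi, gene in enumerate(genes):
        base = baseline_ct + 1.5 * gi
        planted = planted_log2_enrichment.get(gene, 0.0)
        for fraction in fractions:
            if isinstance(planted, dict):
                shift = float(planted.get(fraction, 0.0))
            else:
                shift = float(planted) if fraction == fractions[0] else 0.0
            for rep in range(1, n_reps + 1):
                ct = base - shift + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                rows.append({"gene": gene, "fraction": fraction,
                             "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)


def generate_count_table(genes: Sequence[str],
                         planted_neurite_soma_ratio: Dict[str, float],
                         depth: int = 100_000, n_reps: int = 3, seed: int = 0,
                         n_background_genes: int = 50):
    """Synthetic normalized-count table with planted neurite/soma ratios.

    Per replicate and compartment, ``depth`` reads are distributed
    multinomially over the target genes plus ``n_background_genes``
    unit-ratio background genes; neurite sampling weights are the soma
    weights scaled by each gene's planted ratio. Counts are reported as
    counts per million, so with the background dominating the library the
    expected neurite/soma ratio of a target gene equals its planted ratio
    up to a small (<~2%) compositional bias. Deterministic per seed.
    """
    import pandas as pd

    if depth <= 0:
        raise ValueError("depth must be positive")
    if any(r <= 0 for r in planted_neurite_soma_ratio.values()):
        raise ValueError("planted ratios must be positive")
    unknown = set(planted_neurite_soma_ratio) - set(genes)
    if unknown:
        raise ValueError(f"planted ratio for unknown genes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    all_genes = list(genes) + [f"bg_{i}" for i in range(n_background_genes)]
    base = np.ones(len(all_genes)) / len(all_genes)
    ratios = np.array([planted_neurite_soma_ratio.get(g, 1.0) for g in all_genes])
    rows = []
    for rep in range(1, n_reps + 1):
        soma = rng.multinomial(depth, base)
        w = base * ratios
        neurite = rng.multinomial(depth, w / w.sum())
        for g, s_count, n_count in zip(all_genes, soma, neurite):
            for comp, count in (("soma", s_count), ("neurite", n_count)):
                rows.append({"gene": g, "compartment": comp, "replicate": rep,
                             "count": count / depth * 1e6,
                             "normalization": "CPM"})
    return pd.DataFrame(rows)
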