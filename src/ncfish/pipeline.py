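"""End-to-end scenario pipelines: prep -> masks -> detect -> colocalize ->
quantify -> stats, with every intermediate written and a manifest recording
parameters, seeds and input hashes.

Scenarios mirror the study's figure designs:

- ``density``       per-neurite spot densities and neurite/soma ratios
- ``coloc-ribosome`` mRNA vs ribosomal puncta overlap (>=50%)
- ``coloc-mito``     mRNA vs mitochondria overlap plus Mander's coefficients
- ``triple``         mRNA simultaneously on mitochondria and ribosomes
- ``trna-coloc``     same overlap machinery, tRNA/synthetase naming
- ``puro-pla``       thresholded puncta densities (nascent-protein spots)
- ``aso``            three conditions (untreated / scramble-like / ASO-like)
  compared with the Kruskal-Wallis + post hoc battery

Each scenario runs on synthetic scenes (no raw-image download needed) or,
for single-cell scenarios, on a TIFF + ROI pair supplied in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as ncio
from .coloc import manders, pairwise_coloc, triple_coloc
from .masks import CellMask, build_cell_mask, partition_neurite
from .prep import ImageScene, PrepParams, gaussian_blur, clahe, threshold, max_project
from .quantify import density_stats
from .scene import ScenarioParams, SyntheticScene, generate_scene
from .spots import DetectionParams, assign_to_compartments, detect_spots_dog, find_puncta
from .stats import compare_groups

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline",
           "detect_in_scene", "target_puncta", "scene_coloc_fraction"]

SCENARIOS = ("density", "coloc-ribosome", "coloc-mito", "triple",
             "trna-coloc", "puro-pla", "aso")

_TARGET_CHANNEL = {"coloc-ribosome": "ribosome", "coloc-mito": "mito",
                   "trna-coloc": "ribosome"}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run.

    Round-trips losslessly through JSON. Image/ROI inputs are optional;
    without them the synthetic generator supplies the scenes.
    """

    scenario: str = "coloc-ribosome"
    seed: int = 0
    n_cells: int = 10
    coloc_threshold: float = 0.5
    # CLAHE before thresholding suits the original interactive (manual
    # threshold) chain; Otsu needs the unequalized histogram, so the
    # reproducible default thresholds the blurred image directly.
    use_clahe: bool = False
    min_area_px: int = 4
    scene: dict = field(default_factory=dict)      # ScenarioParams overrides
    prep: dict = field(default_factory=dict)       # PrepParams overrides
    detect: dict = field(default_factory=dict)     # DetectionParams overrides
    condition_coloc: Dict[str, float] = field(
        default_factory=lambda: {"untreated": 0.6, "scramble": 0.5, "aso": 0.2})
    image_path: Optional[str] = None
    roi_path: Optional[str] = None
    channel_order: Optional[List[str]] = None
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")

    def scene_params(self, **extra) -> ScenarioParams:
        kw = dict(self.scene)
        kw.update(extra)
        return ScenarioParams(**kw)

    def prep_params(self) -> PrepParams:
        return PrepParams(**self.prep)

    def detect_params(self) -> DetectionParams:
        kw = {"threshold_mode": "auto"}
        kw.update(self.detect)
        return DetectionParams(**kw)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _prep_channel(img: np.ndarray, prep: PrepParams, use_clahe: bool) -> np.ndarray:
    """The published coloc preprocessing chain: blur then CLAHE."""
    if img.ndim == 3:
        img = max_project(img)
    out = gaussian_blur(img, prep.blur_sigma_px)
    if use_clahe:
        block = min(prep.clahe_block_px, (min(out.shape) // 2) * 2 - 1)
        out = clahe(out, block, prep.clahe_max_slope)
    return out


def detect_in_scene(images: ImageScene, channel: str,
                    detect: DetectionParams):
    img = images.channels[channel]
    if img.ndim == 3:
        img = max_project(img)
    return detect_spots_dog(img, detect, channel=channel)


def target_puncta(images: ImageScene, channel: str, prep: PrepParams,
                  use_clahe: bool, min_area_px: int):
    """Blur -> CLAHE -> threshold -> particle analysis for a target channel."""
    raw = images.channels[channel]
    if raw.ndim == 3:
        raw = max_project(raw)
    pre = _prep_channel(raw, prep, use_clahe)
    binary = threshold(pre, prep)
    return find_puncta(binary, raw, min_area_px=min_area_px, channel=channel)


def scene_coloc_fraction(scene: SyntheticScene, target_channel: str,
                         config: PipelineConfig, mask: Optional[np.ndarray] = None):
    """Detect mRNA spots, extract target puncta, score >=threshold overlap."""
    spots = detect_in_scene(scene.images, "rna", config.detect_params())
    puncta = target_puncta(scene.images, target_channel, config.prep_params(),
                           config.use_clahe, config.min_area_px)
    report = pairwise_coloc(spots, puncta, threshold=config.coloc_threshold,
                            mask=mask, shape=scene.images.shape,
                            sigma_dog=config.detect_params().sigma_dog)
    return report, spots, puncta


def _build_mask_from_truth(scene: SyntheticScene,
                           config: PipelineConfig) -> CellMask:
    return build_cell_mask(
        scene.images.channels["marker"], scene.images.channels["nucleus"],
        scene.truth.soma_polygon, scene.truth.neurite_paths,
        config.prep_params(),
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run one scenario end to end; returns (and optionally writes) the
    result bundle.

    The bundle always contains a ``manifest`` (config, seeds, versions,
    input hashes) and per-scenario tables. With ``config.out_dir`` set,
    every table is written as CSV and the manifest as JSON; outputs are
    byte-stable for a fixed config.
    """
    from . import __version__

    bundle: dict = {}
    try:
        if config.scenario == "density":
            bundle = _run_density(config)
        elif config.scenario in _TARGET_CHANNEL or config.scenario == "triple":
            bundle = _run_coloc(config)
        elif config.scenario == "puro-pla":
            bundle = _run_puro_pla(config)
        elif config.scenario == "aso":
            bundle = _run_aso(config)
    except Exception as exc:
        raise RuntimeError(f"stage failure in scenario {config.scenario!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "scenario": config.scenario,
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "inputs": {},
    }
    for key in ("image_path", "roi_path"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": p, "sha256": _sha256(p)}
    bundle["manifest"] = manifest

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                ncio.write_table(out / f"{name}.csv", obj)
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True,
                                                      indent=1))
        (out / "summary.json").write_text(json.dumps(
            {k: v for k, v in bundle.items()
             if not isinstance(v, pd.DataFrame) and k != "manifest"},
            sort_keys=True, indent=1, default=str))
    return bundle


def _scenes(config: PipelineConfig, **param_overrides):
    """Synthetic scenes for multi-cell scenarios, seeds derived from config."""
    for i in range(config.n_cells):
        params = config.scene_params(**param_overrides)
        yield generate_scene(params, seed=config.seed * 10_000 + i)


def _load_or_generate_single(config: PipelineConfig):
    if config.image_path:
        if not config.channel_order:
            raise ValueError("channel_order is required with image_path")
        images = ncio.read_image(config.image_path, config.channel_order,
                                 config.scene_params().pixel_size_um)
        if not config.roi_path:
            raise ValueError("roi_path is required with image_path")
        soma, neurites = ncio.read_roi(config.roi_path, images.pixel_size_um)
        mask = build_cell_mask(images.channels["marker"],
                               images.channels.get("nucleus"),
                               soma, neurites, config.prep_params())
        return images, mask, None
    scene = generate_scene(config.scene_params(), seed=config.seed)
    return scene.images, _build_mask_from_truth(scene, config), scene


def _run_density(config: PipelineConfig) -> dict:
    images, cellmask, scene = _load_or_generate_single(config)
    spots = detect_in_scene(images, "rna", config.detect_params())
    partitions = []
    for path, _ in cellmask.neurites:
        try:
            partitions.append(partition_neurite(path))
        except ValueError:
            partitions.append(None)  # neurite too short for a 3-way split
    labeled = assign_to_compartments(spots, cellmask, partitions)
    stats = density_stats(labeled, cellmask, partitions, images.pixel_size_um)
    ratios = pd.DataFrame(
        [{"neurite": k, "neurite_soma_ratio": v}
         for k, v in stats.neurite_soma_ratio.items()])
    fractions = pd.DataFrame(
        [{"neurite": k, **v} for k, v in stats.per_neurite_fractions.items()])
    out = {
        "compartments": stats.table,
        "ratios": ratios,
        "regional_fractions": fractions,
        "spots": ncio.spots_to_frame(labeled),
        "n_spots": len(labeled),
        "soma_density": stats.soma_density,
    }
    if scene is not None:
        out["truth_n_rna"] = int(len(scene.truth.spots["rna"]))
    return out


def _run_coloc(config: PipelineConfig) -> dict:
    rows = []
    per_cell = []
    for scene in _scenes(config):
        mask = scene.truth.cell_region
        if config.scenario == "triple":
            spots = detect_in_scene(scene.images, "rna", config.detect_params())
            prep = config.prep_params()
            ribo = target_puncta(scene.images, "ribosome", prep,
                                 config.use_clahe, config.min_area_px)
            mito = target_puncta(scene.images, "mito", prep,
                                 config.use_clahe, config.min_area_px)
            report = triple_coloc(spots, mito, ribo,
                                  threshold=config.coloc_threshold, mask=mask,
                                  sigma_dog=config.detect_params().sigma_dog)
        else:
            target = _TARGET_CHANNEL[config.scenario]
            report, spots, _ = scene_coloc_fraction(scene, target, config, mask)
        row = {"cell": scene.seed, "n_reference": report.n_reference,
               "colocalized": report.colocalized, "fraction": report.fraction,
               "planted": scene.params.coloc_for(
                   _TARGET_CHANNEL.get(config.scenario, "mito"))}
        if config.scenario == "coloc-mito":
            pre_a = _prep_channel(scene.images.channels["rna"],
                                  config.prep_params(), config.use_clahe)
            pre_b = _prep_channel(scene.images.channels["mito"],
                                  config.prep_params(), config.use_clahe)
            from skimage.filters import threshold_otsu
            m1, m2 = manders(pre_a, pre_b, threshold_otsu(pre_a),
                             threshold_otsu(pre_b), mask)
            row.update({"manders_m1": m1, "manders_m2": m2})
        rows.append(row)
        per_cell.append(report)
    table = pd.DataFrame(rows)
    return {"per_cell": table,
            "mean_fraction": float(table["fraction"].mean()),
            "n_cells": len(table)}


def _run_puro_pla(config: PipelineConfig) -> dict:
    images, cellmask, scene = _load_or_generate_single(config)
    prep = config.prep_params()
    raw = images.channels.get("pla", images.channels["rna"])
    binary = threshold(gaussian_blur(raw, prep.blur_sigma_px), prep)
    puncta = find_puncta(binary, raw, min_area_px=config.min_area_px,
                         channel="pla")
    labeled = assign_to_compartments(puncta, cellmask,
                                     [None] * len(cellmask.neurites))
    stats = density_stats(labeled, cellmask, None, images.pixel_size_um)
    return {
        "compartments": stats.table,
        "ratios": pd.DataFrame([{"neurite": k, "neurite_soma_ratio": v}
                                for k, v in stats.neurite_soma_ratio.items()]),
        "n_puncta": len(labeled),
    }


def _run_aso(config: PipelineConfig) -> dict:
    """Three-condition colocalization comparison with the stats battery."""
    values, groups = [], []
    rows = []
    offset = 0
    for cond, frac in config.condition_coloc.items():
        for i in range(config.n_cells):
            params = config.scene_params(coloc_fraction=frac)
            scene = generate_scene(params,
                                   seed=config.seed * 100_000 + offset + i)
            report, _, _ = scene_coloc_fraction(
                scene, "ribosome", config, scene.truth.cell_region)
            values.append(report.fraction)
            groups.append(cond)
            rows.append({"condition": cond, "cell": scene.seed,
                         "fraction": report.fraction, "planted": frac})
        offset += 1000
    comparison = compare_groups(values, groups, posthoc="dunn",
                                correction="bonferroni")
    return {"per_cell": pd.DataFrame(rows),
            "kruskal_H": comparison.statistic,
            "kruskal_p": comparison.p_value,
            "posthoc": comparison.posthoc,
            "stats": comparison.to_dict()}
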