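"""Readers and writers for images, ROIs, object tables and scenes.

Formats: multi-page TIFF (one page per channel, channel order supplied by
the caller/config — never inferred from intensity), a small JSON ROI
dialect (named soma polygon plus neurite polylines with subpixel (row,
col) vertices), and CSV tables with fixed schemas. Writers are byte-stable
for fixed inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .masks import NeuritePath
from .prep import ImageScene
from .spots import Punctum, PunctumSet, Spot, SpotSet

__all__ = [
    "read_image",
    "write_image",
    "read_roi",
    "write_roi",
    "read_table",
    "write_table",
    "spots_to_frame",
    "frame_to_spots",
    "write_scene",
    "read_scene",
]

SPOT_COLUMNS = ["channel", "row", "col", "response", "intensity",
                "compartment", "neurite", "arc_um"]


def read_image(path, channel_names: Sequence[str], pixel_size_um: float,
               normalize: bool = False) -> ImageScene:
    """Load a multi-page TIFF into an :class:`ImageScene`.

    ``channel_names[i]`` names page i. With ``normalize=True`` each channel
    is min-max scaled to [0, 1], so 8-bit and 16-bit encodings of the same
    data load identically.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"{path}: {arr.shape[0]} pages but {len(channel_names)} channel names"
        )
    channels = {}
    for name, page in zip(channel_names, arr):
        page = page.astype(float)
        if normalize:
            lo, hi = page.min(), page.max()
            page = (page - lo) / (hi - lo) if hi > lo else np.zeros_like(page)
        channels[name] = page
    return ImageScene(channels=channels, pixel_size_um=pixel_size_um)


def write_image(path, scene: ImageScene, dtype=np.float32) -> List[str]:
    """Write an ImageScene as a multi-page TIFF; returns the page order."""
    names = sorted(scene.channels)
    stack = np.stack([scene.channels[n].astype(dtype) for n in names])
    tifffile.imwrite(str(path), stack)
    return names


def read_roi(path, pixel_size_um: float = 0.05) -> Tuple[np.ndarray, List[NeuritePath]]:
    """Read the ROI JSON dialect.

    Schema: ``{"soma": [[r, c], ...], "neurites": [{"name": ..,
    "vertices": [[r, c], ...], "width_px": 75}, ...]}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    data = json.loads(path.read_text())
    if "soma" not in data:
        raise ValueError(f"{path}: ROI file lacks a 'soma' polygon")
    soma = np.asarray(data["soma"], dtype=float)
    neurites = [
        NeuritePath(vertices=np.asarray(n["vertices"], dtype=float),
                    width_px=int(n.get("width_px", 75)),
                    pixel_size_um=pixel_size_um,
                    name=n.get("name", f"neurite_{i}"))
        for i, n in enumerate(data.get("neurites", []))
    ]
    return soma, neurites


def write_roi(path, soma_polygon, neurite_paths: Sequence[NeuritePath]):
    data = {
        "soma": np.asarray(soma_polygon, dtype=float).tolist(),
        "neurites": [
            {"name": p.name, "vertices": p.vertices.tolist(), "width_px": p.width_px}
            for p in neurite_paths
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def read_table(path, required: Sequence[str]) -> pd.DataFrame:
    """Read a CSV table, erroring with the missing column's name."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(path, df: pd.DataFrame):
    df.to_csv(path, index=False, float_format="%.10g")


def spots_to_frame(objects) -> pd.DataFrame:
    """Serialize a SpotSet or PunctumSet to a tidy frame (lossless for
    spots; puncta lose their pixel supports but keep area)."""
    rows = []
    if isinstance(objects, SpotSet):
        for s in objects.spots:
            rows.append({"channel": objects.channel, "row": s.position[0],
                         "col": s.position[1], "response": s.response,
                         "intensity": s.intensity, "compartment": s.compartment,
                         "neurite": s.neurite, "arc_um": s.arc_um})
        return pd.DataFrame(rows, columns=SPOT_COLUMNS)
    for p in objects.puncta:
        rows.append({"channel": objects.channel, "row": p.centroid[0],
                     "col": p.centroid[1], "area_px": p.area_px,
                     "intensity": p.mean_intensity, "compartment": p.compartment,
                     "neurite": p.neurite, "arc_um": p.arc_um})
    return pd.DataFrame(rows, columns=["channel", "row", "col", "area_px",
                                       "intensity", "compartment", "neurite",
                                       "arc_um"])


def frame_to_spots(df: pd.DataFrame) -> SpotSet:
    """Inverse of :func:`spots_to_frame` for spot tables."""
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing column(s) {missing}")
    def _opt(v):
        return None if pd.isna(v) else v
    spots = [Spot(position=(row.row, row.col), response=row.response,
                  intensity=row.intensity, compartment=_opt(row.compartment),
                  neurite=_opt(row.neurite),
                  arc_um=_opt(row.arc_um))
             for row in df.itertuples()]
    channel = df["channel"].iloc[0] if len(df) else "rna"
    return SpotSet(spots=spots, channel=channel)


def write_scene(outdir, scene) -> Dict[str, str]:
    """Write a synthetic scene: channels as multi-page TIFF, truth + ROIs
    as JSON. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tiff = outdir / "scene.tif"
    order = write_image(tiff, scene.images)
    truth = scene.truth
    truth_json = {
        "seed": scene.seed,
        "pixel_size_um": scene.images.pixel_size_um,
        "channel_order": order,
        "spots": {k: v.tolist() for k, v in truth.spots.items()},
        "coloc_labels": {k: v.astype(int).tolist() for k, v in truth.coloc_labels.items()},
        "rna_has_partner": {k: v.astype(int).tolist()
                            for k, v in truth.rna_has_partner.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, sort_keys=True))
    write_roi(outdir / "roi.json", truth.soma_polygon, truth.neurite_paths)
    return {"tiff": str(tiff), "truth": str(outdir / "truth.json"),
            "roi": str(outdir / "roi.json")}


def read_scene(outdir) -> Tuple[ImageScene, dict, Tuple[np.ndarray, List[NeuritePath]]]:
    """Load a written scene back: (images, truth dict, (soma, neurites))."""
    outdir = Path(outdir)
    truth = json.loads((outdir / "truth.json").read_text())
    images = read_image(outdir / "scene.tif", truth["channel_order"],
                        truth["pixel_size_um"])
    roi = read_roi(outdir / "roi.json", truth["pixel_size_um"])
    return images, truth, roi
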