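"""File formats, run configuration and the end-to-end pipeline.

Image sets are stored as one 16-bit TIFF per channel plus a JSON sidecar
recording channel order and pixel size; tables are CSV with one header
row; thresholds and configuration are JSON.  ``run_pipeline`` ties the
stages together in analysis order: quantify every field of view, build a
dose-response curve per descriptor, locate variance-ratio thresholds,
pool them into global thresholds and sort cells into regimes.
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
import tifffile

from . import __version__
from .morphometrics import CellImageSet, FibreParams, quantify_cell
from .regimes import (assign_regimes, build_drc, detect_thresholds,
                      global_thresholds, rov_series)
from .synthetic import (NoiseConfig, PopulationConfig, TransferFunction,
                        generate_population)

logger = logging.getLogger("cytodose")

CHANNELS = ("gfp", "stain", "dapi")

# Pooled statistic per descriptor, mirroring how each quantity is usually
# reported: multiplicative quantities geometrically, bounded or symmetric
# ones by mean or median.
DEFAULT_POOLING: Dict[str, str] = {
    "area": "gmean",
    "fibre_amount": "gmean",
    "fibre_thickness": "mean",
    "fibre_length": "gmean",
    "stellate_factor": "mean",
    "aspect_ratio": "median",
    "orientation_coherence": "mean",
    "radiality": "median",
}


# ---------------------------------------------------------------------------
# Image-set I/O
# ---------------------------------------------------------------------------


def write_image_set(images: CellImageSet, out_dir: Path) -> Path:
    """Write one image set as per-channel uint16 TIFFs + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = images.identifier or "cell"
    paths = {}
    for ch in CHANNELS:
        arr = np.asarray(getattr(images, ch))
        data = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
        p = out_dir / f"{stem}_{ch}.tif"
        tifffile.imwrite(p, data)
        paths[ch] = p.name
    sidecar = {
        "identifier": stem,
        "channels": paths,
        "channel_order": list(CHANNELS),
        "pixel_size_um": images.pixel_size,
    }
    sidecar_path = out_dir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def read_image_set(sidecar_path: Path,
                   channel_map: Optional[Dict[str, str]] = None
                   ) -> CellImageSet:
    """Load an image set from its JSON sidecar.

    ``channel_map`` optionally remaps logical channel names (gfp, stain,
    dapi) to the names used in the sidecar.
    """
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    channel_map = channel_map or {}
    arrays = {}
    for ch in CHANNELS:
        key = channel_map.get(ch, ch)
        if key not in meta["channels"]:
            raise ValueError(f"sidecar {sidecar_path} lacks channel '{key}'")
        p = sidecar_path.parent / meta["channels"][key]
        if not p.exists():
            raise FileNotFoundError(f"missing channel file: {p}")
        arrays[ch] = tifffile.imread(p).astype(float)
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ: {sorted(shapes)}")
    return CellImageSet(pixel_size=float(meta["pixel_size_um"]),
                        identifier=meta.get("identifier", sidecar_path.stem),
                        **arrays)


def read_image_dir(in_dir: Path,
                   channel_map: Optional[Dict[str, str]] = None
                   ) -> List[CellImageSet]:
    """Load every sidecar-described image set in a directory."""
    in_dir = Path(in_dir)
    sidecars = sorted(in_dir.glob("*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no image-set sidecars (*.json) in {in_dir}")
    return [read_image_set(p, channel_map) for p in sidecars]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one end-to-end analysis run needs.

    Exactly one of ``input_dir`` (pre-existing image sets) or ``simulate``
    (a synthetic population to generate on the fly) must be set.
    """

    out_dir: Path
    input_dir: Optional[Path] = None
    simulate: Optional[PopulationConfig] = None
    channel_map: Dict[str, str] = field(default_factory=dict)
    descriptors: Sequence[str] = ("area", "fibre_amount", "fibre_thickness",
                                  "stellate_factor", "aspect_ratio",
                                  "orientation_coherence")
    pooling: Dict[str, str] = field(default_factory=dict)
    n_min: int = 100
    rov_window: int = 3
    min_log_ratio: float = float(np.log(4.0))
    fibre_params: FibreParams = field(default_factory=FibreParams)
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of input_dir or simulate must be provided")
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if self.rov_window < 2:
            raise ValueError("rov_window must be >= 2")
        if self.min_log_ratio <= 0:
            raise ValueError("min_log_ratio must be positive")
        for d in self.pooling.values():
            if d not in ("gmean", "mean", "median"):
                raise ValueError(f"unknown pooling '{d}'")

    def pooling_for(self, descriptor: str) -> str:
        return self.pooling.get(
            descriptor, DEFAULT_POOLING.get(descriptor, "gmean"))

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        d = dataclasses.asdict(self)
        return json.dumps(d, default=enc, sort_keys=True, indent=2)


def load_run_config(path: Path) -> RunConfig:
    """Read a RunConfig from JSON (paths relative to the file's folder)."""
    path = Path(path)
    raw = json.loads(path.read_text())
    sim = raw.pop("simulate", None)
    if sim is not None:
        noise = NoiseConfig(**sim.pop("noise", {}))
        transfer = sim.pop("transfer", None)
        if transfer is not None:
            transfer = {k: TransferFunction(**v) for k, v in transfer.items()}
        sim = PopulationConfig(noise=noise, transfer=transfer, **sim)
    fibre = FibreParams(**raw.pop("fibre_params", {}))
    for key in ("out_dir", "input_dir"):
        if raw.get(key) is not None:
            raw[key] = (path.parent / raw[key]).resolve()
    cfg = RunConfig(simulate=sim, fibre_params=fibre, **raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def quantify_image_sets(image_sets: Sequence[CellImageSet],
                        fibre_params: Optional[FibreParams] = None
                        ) -> pd.DataFrame:
    """Quantify a batch of fields of view into a per-cell table."""
    rows = []
    for images in image_sets:
        try:
            rows.append(quantify_cell(images, params=fibre_params).to_dict())
        except ValueError as exc:
            logger.warning("skipping %s: %s", images.identifier, exc)
    if not rows:
        raise ValueError("no cell could be quantified")
    return pd.DataFrame(rows)


def analyse_cells(cells: pd.DataFrame, config: RunConfig) -> dict:
    """DRCs, RoV thresholds, global thresholds and regime labels."""
    curves, rovs, candidates = {}, {}, {}
    for desc in config.descriptors:
        curve = build_drc(cells, desc, n_min=config.n_min,
                          pooling=config.pooling_for(desc))
        log_scale = bool(np.all(curve.stat > 0))
        rov = rov_series(curve.stat, N=config.rov_window, log=log_scale)
        cand = detect_thresholds(rov, curve,
                                 min_log_ratio=config.min_log_ratio)
        curves[desc] = curve
        rovs[desc] = rov
        candidates[desc] = cand
    g1, g2 = global_thresholds(candidates.values())
    seg = assign_regimes(cells, g1, g2)
    return {"curves": curves, "rov": rovs, "candidates": candidates,
            "g1": g1, "g2": g2, "segmentation": seg}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write its outputs.

    Writes ``cells.csv`` (per-cell descriptors), ``drc/<descriptor>.csv``
    (binned curves with RoV), ``thresholds.json`` (per-curve candidates
    and global thresholds) and ``regimes.csv`` (per-cell labels), plus a
    ``run_log.json`` recording version, seed and config hash.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        image_sets, _ = generate_population(sim)
    else:
        image_sets = read_image_dir(config.input_dir, config.channel_map)

    cells = quantify_image_sets(image_sets, config.fibre_params)
    cells.to_csv(out / "cells.csv", index=False)

    results = analyse_cells(cells, config)

    drc_dir = out / "drc"
    drc_dir.mkdir(exist_ok=True)
    for desc, curve in results["curves"].items():
        frame = curve.to_frame()
        frame["rov"] = results["rov"][desc].values
        frame.to_csv(drc_dir / f"{desc}.csv", index=False)

    thresholds = {
        "global": {"g1": results["g1"], "g2": results["g2"]},
        "per_descriptor": {
            desc: [{"expression": c.expression, "index": c.index,
                    "direction": c.direction, "magnitude": c.magnitude}
                   for c in cands]
            for desc, cands in results["candidates"].items()},
    }
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2))

    seg = results["segmentation"]
    regimes_df = pd.DataFrame({
        "identifier": cells["identifier"],
        "total_gfp": cells["total_gfp"],
        "regime": seg.labels,
    })
    regimes_df.to_csv(out / "regimes.csv", index=False)

    cfg_json = config.to_json()
    log = {
        "version": __version__,
        "seed": config.seed,
        "n_cells": int(len(cells)),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "regime_counts": seg.counts,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    results["cells"] = cells
    return results
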