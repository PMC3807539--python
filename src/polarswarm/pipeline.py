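"""End-to-end pipeline: align training shapes, segment, evaluate.

Driven by a YAML config with a small versioned schema; every run writes a
manifest recording the config, input hashes, seed, per-stage timings and
output paths, so a run can be reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from pathlib import Path

import numpy as np

from . import __version__
from .alignment import align_shapes, build_template
from .imaging import load_image, load_mask, save_mask
from .metrics import evaluate
from .multiswarm import CT_PRESET, MR_PRESET, PsoConfig, run_segmentation

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: config keys the schema accepts (beyond the pso block)
_KNOWN_KEYS = {
    "schema_version", "image", "shapes_dir", "ground_truth", "out_dir",
    "seed", "preset", "pso",
}


class ConfigError(ValueError):
    """Invalid pipeline config; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


def pso_config_from(config: dict, seed: int | None = None) -> PsoConfig:
    """Build a PsoConfig from a preset name plus per-field overrides."""
    preset = config.get("preset", "ct")
    if preset not in ("ct", "mr"):
        raise ConfigError("preset", "must be 'ct' or 'mr'")
    base = CT_PRESET if preset == "ct" else MR_PRESET
    overrides = dict(config.get("pso") or {})
    if "scale_range" in overrides:
        overrides["scale_range"] = tuple(overrides["scale_range"])
    if seed is not None:
        overrides["seed"] = seed
    valid = {f.name for f in dataclasses.fields(PsoConfig)}
    for key in overrides:
        if key not in valid:
            raise ConfigError(f"pso.{key}", "unknown PSO setting")
    return dataclasses.replace(base, **overrides)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_atomic(path: Path, payload: dict) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=2, sort_keys=True))
    os.replace(tmp, path)


def validate_config(config: dict) -> None:
    for key in config:
        if key not in _KNOWN_KEYS:
            raise ConfigError(key, "unknown key")
    if int(config.get("schema_version", SCHEMA_VERSION)) != SCHEMA_VERSION:
        raise ConfigError("schema_version", f"expected {SCHEMA_VERSION}")
    for field in ("image", "shapes_dir", "out_dir"):
        if field not in config:
            raise ConfigError(field, "missing required field")
        if field != "out_dir" and not Path(config[field]).exists():
            raise ConfigError(field, f"path does not exist: {config[field]}")


def run_pipeline(config: dict) -> dict:
    """Execute align -> segment -> evaluate; return the manifest dict.

    Inputs are never mutated; all outputs are new files under ``out_dir``.
    A stage failure leaves partial outputs plus a FAILED marker file.
    """
    validate_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    pso = pso_config_from(config, seed=seed)
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": config,
        "seed": seed,
        "inputs": {},
        "outputs": {},
        "timings_s": {},
    }
    try:
        image_path = Path(config["image"])
        manifest["inputs"][str(image_path)] = _sha256(image_path)
        shape_paths = sorted(Path(config["shapes_dir"]).glob("*.png")) + sorted(
            Path(config["shapes_dir"]).glob("*.pgm")
        )
        if not shape_paths:
            raise ConfigError("shapes_dir", "contains no PNG/PGM shapes")
        for p in shape_paths:
            manifest["inputs"][str(p)] = _sha256(p)

        t0 = time.perf_counter()
        shapes = [load_mask(p) for p in shape_paths]
        result = align_shapes(shapes)
        template = build_template(result.aligned)
        manifest["timings_s"]["align"] = time.perf_counter() - t0
        template_path = out_dir / "template.png"
        save_mask(template.union, template_path)
        manifest["outputs"]["template"] = str(template_path)
        log.info("align: energy %.4g -> %.4g over %d iterations [seed %d]",
                 result.energy_trace[0], result.energy_trace[-1],
                 len(result.energy_trace) - 1, seed)

        t0 = time.perf_counter()
        image = load_image(image_path)
        seg = run_segmentation(image, template, pso)
        manifest["timings_s"]["segment"] = time.perf_counter() - t0
        mask_path = out_dir / "mask.png"
        save_mask(seg.mask, mask_path)
        manifest["outputs"]["mask"] = str(mask_path)
        np.savetxt(out_dir / "contour.csv", seg.contour, delimiter=",",
                   header="angle_rad,radius_px", comments="")
        manifest["outputs"]["contour"] = str(out_dir / "contour.csv")
        log.info("segment: origin (%.1f, %.1f) [seed %d]",
                 seg.origin[0], seg.origin[1], seed)

        if config.get("ground_truth"):
            truth_path = Path(config["ground_truth"])
            manifest["inputs"][str(truth_path)] = _sha256(truth_path)
            t0 = time.perf_counter()
            report = evaluate(load_mask(truth_path), seg.mask)
            manifest["timings_s"]["evaluate"] = time.perf_counter() - t0
            report_path = out_dir / "report.json"
            _write_atomic(report_path, report.as_dict())
            manifest["outputs"]["report"] = str(report_path)
            log.info("evaluate: dice %.4f jaccard %.4f [seed %d]",
                     report.dice, report.jaccard, seed)
    except Exception:
        (out_dir / "FAILED").write_text("pipeline stage failed\n")
        raise
    _write_atomic(out_dir / "manifest.json", manifest)
    return manifest
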