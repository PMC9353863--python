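"""Shared I/O, configuration and pipeline orchestration.

Images travel as 8-bit PNG/TIFF via imageio; tables as CSV with
unit-bearing headers via pandas.  ``run_pipeline`` executes the stages in
method order (simulate → denoise → edges → fit → curvature), logs each
stage's parameters, and writes a manifest listing every artifact with its
SHA-256 checksum so a fixed config + seed is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import boundary as bnd
from . import denoising as dn
from . import edges as ed
from . import synthetic as syn

__all__ = [
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("clawmech")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as 8-bit grayscale (BT.601 luma for colour)."""
    path = Path(path)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValueError(f"unsupported image format: {path.suffix}")
    try:
        img = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"malformed image file {path}: {exc}") from exc
    return dn.to_grayscale(img)


def write_image(path, image: np.ndarray) -> Path:
    """Write an 8-bit image losslessly (PNG or TIFF)."""
    path = Path(path)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValueError(f"unsupported image format: {path.suffix}")
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(float)), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)
    return path


def read_table(path, required=None) -> pd.DataFrame:
    """Read a CSV table with a header row; validates required columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing} "
                             f"(found {list(df.columns)})")
    return df


def write_table(path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_KNOWN_BLOCKS = {"simulate", "denoise", "edges", "fit", "adhesion", "indent"}
_KNOWN_GLOBALS = {"seed", "pixel_size_um", "output_dir", "stages"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``stages`` lists the stages to run, in order, from
    simulate/denoise/edges/fit; per-stage parameter blocks live in
    ``params``.  Unknown keys are rejected before anything runs.
    """

    seed: int = 0
    pixel_size_um: float = 1.0
    output_dir: str = "clawmech_out"
    stages: tuple = ("simulate", "denoise", "edges", "fit")
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - _KNOWN_BLOCKS
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        bad = [s for s in self.stages if s not in _KNOWN_BLOCKS]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        # surface module precondition violations before any stage runs
        dn.NlmParams(**self.params.get("denoise", {}))
        e = self.params.get("edges", {})
        if e.get("lam", 0) is not None and e.get("lam", 0) < 0:
            raise ValueError("edges.lam must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_GLOBALS - _KNOWN_BLOCKS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params = {k: raw.pop(k) for k in list(raw) if k in _KNOWN_BLOCKS}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(params=params, **raw)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order and return the run manifest.

    Each stage record lists its parameters and artifact paths; artifacts
    carry SHA-256 checksums.  A stage failure raises ``RuntimeError``
    naming the stage; artifacts from completed stages remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": []}
    state: dict = {}

    for stage in config.stages:
        params = dict(config.params.get(stage, {}))
        log.info("stage %s: params=%s", stage, params)
        record = {"stage": stage, "params": params, "artifacts": {}}
        try:
            if stage == "simulate":
                size = int(params.pop("size", 256))
                noise = syn.NoiseSpec(
                    gaussian_sd=params.pop("gaussian_sd", 10.0),
                    impulse_fraction=params.pop("impulse_fraction", 0.02),
                    seed=config.seed)
                spec = syn.default_phantom_spec(size, size, **params)
                phantom = syn.generate_claw_phantom(spec)
                state["clean"] = phantom.image
                state["image"] = syn.add_noise(phantom.image, noise)
                record["artifacts"]["clean"] = str(
                    write_image(out / "phantom_clean.png", state["clean"]))
                record["artifacts"]["noisy"] = str(
                    write_image(out / "phantom_noisy.png", state["image"]))
                truth = {"outer": phantom.outer_curve.coefficients(),
                         "inner": phantom.inner_curve.coefficients()}
                p = out / "phantom_truth.json"
                p.write_text(json.dumps(truth, indent=2))
                record["artifacts"]["truth"] = str(p)
            elif stage == "denoise":
                scheme = params.pop("scheme", "improved")
                nlm = dn.NlmParams(**params)
                state["image"] = dn.nlm_denoise(state["image"], nlm, scheme)
                record["artifacts"]["denoised"] = str(
                    write_image(out / "denoised.png", state["image"]))
                if "clean" in state:
                    m = dn.mse(state["clean"], state["image"])
                    rep = {"mse": m, "psnr_db": dn.psnr(m)}
                    p = out / "denoise_metrics.json"
                    p.write_text(json.dumps(rep, indent=2))
                    record["artifacts"]["metrics"] = str(p)
            elif stage == "edges":
                scales = tuple(params.pop("scales", (1,)))
                maps = ed.multiscale_edge_detect(state["image"], scales,
                                                 **params)
                state["edges"] = maps[scales[0]]
                for j, em in maps.items():
                    p = write_image(out / f"edges_j{j}.png",
                                    em.binary.astype(np.uint8) * 255)
                    record["artifacts"][f"edges_j{j}"] = str(p)
            elif stage == "fit":
                families = params.pop("families",
                                      ("fourier2", "poly2", "poly3"))
                chains = bnd.extract_boundary(state["edges"],
                                              config.pixel_size_um,
                                              **params)
                longest = max(chains, key=len)
                segs = bnd.split_x_monotone(longest, min_length=10)
                results = []
                for seg in segs:
                    fits = [bnd.fit_curve(seg, fam) for fam in families]
                    best = bnd.select_model(fits)
                    prof = bnd.curvature_profile(best.model, best.x_range)
                    results.append({
                        "segment": seg.label, "n_points": len(seg),
                        "family": best.family, "r_squared": best.r_squared,
                        "sse": best.sse,
                        "coefficients": best.coefficients(),
                        "max_K_per_um": prof.max_K,
                        "classification": prof.classification})
                p = out / "fits.json"
                p.write_text(json.dumps(results, indent=2))
                record["artifacts"]["fits"] = str(p)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

        for name, path in record["artifacts"].items():
            record["artifacts"][name] = {"path": path,
                                         "sha256": _sha256(Path(path))}
        manifest["stages"].append(record)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest
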