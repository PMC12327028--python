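"""End-to-end orchestration over one or more timepoints.

Stage order per timepoint: segment the structural volume (predict
labels, boundaries, thickness) -> denoise the angiographic volume in
the curvelet domain -> oriented-flux enhancement -> smooth / binarize /
component-filter / skeletonize -> 3D and en-face (2D) vessel metrics
restricted to the dermis mask.  The full angiographic volume is
denoised; masks are applied only at metrics time.

All intermediates are persisted under the output directory; every
output carries the configuration hash, and two runs with identical
config + seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curvelet, metrics as vmetrics, vesselize
from .io import read_volume, write_volume
from .oof import OOFParams, oof_response
from .segmentation import SegModel, extract_boundaries, predict_labels, thickness_stats
from .volume import Volume3D

__all__ = ["RunConfig", "RunRecord", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Run manifest plus per-stage parameter blocks.

    ``inputs`` is a list of dicts with keys day, structural, angiographic
    (paths).  Per-timepoint overrides for any stage block can be given
    under ``overrides[day]``.
    """

    inputs: list
    output_dir: str
    model_checkpoint: str | None = None
    seed: int = 0
    segmentation: dict = field(default_factory=dict)
    curvelet: dict = field(default_factory=dict)
    oof: dict = field(default_factory=dict)
    vesselize: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def __post_init__(self):
        if not self.inputs:
            raise ConfigError("config needs at least one input timepoint")
        for item in self.inputs:
            missing = {"day", "structural", "angiographic"} - set(item)
            if missing:
                raise ConfigError(f"input entry missing keys: {sorted(missing)}")
        known_v = {"smooth_size", "smooth_sigma", "threshold_method",
                   "threshold_value", "min_volume", "source"}
        unknown = set(self.vesselize) - known_v
        if unknown:
            raise ConfigError(f"unknown vesselize options: {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in
             ("inputs", "model_checkpoint", "seed", "segmentation",
              "curvelet", "oof", "vesselize", "metrics", "overrides")},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_params(self, stage: str, day) -> dict:
        base = dict(getattr(self, stage))
        base.update(self.overrides.get(day, {}).get(stage, {}))
        return base


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    config_hash: str
    timings: dict = field(default_factory=dict)
    qc_flags: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage, day, exc):
        super().__init__(f"stage {stage!r} failed at day {day!r}: {exc}")
        self.stage, self.day = stage, day


def _vesselize_stage(resp, params):
    smooth = vesselize.gaussian_smooth(
        resp, size=int(params.get("smooth_size", 5)),
        sigma=float(params.get("smooth_sigma", 1.0)))
    binary = vesselize.binarize(smooth,
                                method=params.get("threshold_method", "otsu"),
                                value=params.get("threshold_value"))
    filtered = vesselize.filter_components(
        binary, min_volume=int(params.get("min_volume", 27)))
    skeleton = vesselize.skeletonize3d(filtered)
    return binary, filtered, skeleton


def run_pipeline(config: RunConfig, model: SegModel | None = None) -> RunRecord:
    """Execute the full workflow; returns the run record.

    A trained segmentation model is taken from ``model`` or loaded from
    ``config.model_checkpoint``.  Outputs per day land under
    ``<output_dir>/day<label>/``; a tidy metrics table (day, parameter,
    dims, value) is written to ``<output_dir>/metrics.csv``.
    """
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    record = RunRecord(config_hash=chash)

    if model is None:
        if config.model_checkpoint is None:
            raise ConfigError("no segmentation model: set model_checkpoint "
                              "or pass a model")
        model = SegModel.load(config.model_checkpoint)

    rows = []
    for item in config.inputs:
        day = item["day"]
        day_dir = out_root / f"day{day}"
        day_dir.mkdir(exist_ok=True)
        meta = {"config_hash": chash, "day": day}

        def timed(stage, fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                record.save(out_root / "run_record.json")
                raise StageError(stage, day, exc) from exc
            record.timings[f"day{day}/{stage}"] = round(
                time.perf_counter() - t0, 4)
            return result

        struct = timed("read", lambda: read_volume(item["structural"]))
        angio = read_volume(item["angiographic"])
        if struct.shape != angio.shape:
            raise StageError("read", day, ValueError(
                f"structural {struct.shape} vs angiographic {angio.shape}"))

        labels = timed("segment", lambda: predict_labels(model, struct))
        write_volume(labels.astype(np.float32), day_dir / "labels.tif",
                     voxel_size_um=struct.voxel_size_um, meta=meta)
        bounds = timed("boundaries", lambda: extract_boundaries(labels))
        record.qc_flags[f"day{day}"] = bounds.qc_flags
        thick = timed("thickness", lambda: thickness_stats(
            labels, voxel_size_um=struct.voxel_size_um[0], boundaries=bounds))
        for layer, tm in thick.items():
            rows.append({"day": day, "parameter": f"{layer}_thickness_um",
                         "dims": "3D", "value": tm.mean})
        dermis = labels == 2

        cpar = config.stage_params("curvelet", day)
        def _denoise():
            system = curvelet.CurveletSystem(angio.shape)
            thr = curvelet.ThresholdParams(
                c_default=float(cpar.get("c_default", 3.0)),
                c_finest=float(cpar.get("c_finest", 4.0)),
                sigma=cpar.get("sigma"))
            stripes = curvelet.select_stripe_bands(
                system, stripe_axis=int(cpar.get("stripe_axis", 1)),
                tol_deg=float(cpar.get("stripe_tol_deg", 15.0)))
            return curvelet.denoise(angio, thr, stripes, system)
        den = timed("denoise", _denoise)
        write_volume(den, day_dir / "denoised.tif",
                     voxel_size_um=angio.voxel_size_um, meta=meta)

        opar = config.stage_params("oof", day)
        oof_params = OOFParams(
            radii=tuple(opar.get("radii", (2, 3, 4, 5, 6))),
            eig_rule=opar.get("eig_rule", "mean12"),
            smooth_sigma=float(opar.get("smooth_sigma", 1.0)))
        resp = timed("enhance", lambda: oof_response(den, oof_params))
        write_volume(resp, day_dir / "response.tif",
                     voxel_size_um=angio.voxel_size_um, meta=meta)

        vpar = config.stage_params("vesselize", day)
        source = {"response": resp, "denoised": den}[
            vpar.get("source", "response")]
        binary, filtered, skeleton = timed(
            "vesselize", lambda: _vesselize_stage(source, vpar))
        write_volume(filtered.astype(np.float32), day_dir / "binary.tif",
                     voxel_size_um=angio.voxel_size_um, meta=meta)
        write_volume(skeleton.astype(np.float32), day_dir / "skeleton.tif",
                     voxel_size_um=angio.voxel_size_um, meta=meta)
        record.parameters[f"day{day}"] = {
            "threshold": binary.threshold, "curvelet": cpar,
            "oof": opar, "vesselize": vpar}

        def _metrics():
            m3 = vmetrics.metrics3d(filtered, skeleton, dermis, day=day)
            m2 = vmetrics.mip_metrics(filtered, skeleton, dermis, day=day)
            return m3, m2
        m3, m2 = timed("metrics", _metrics)
        for m in (m3, m2):
            for name, value in m.as_dict().items():
                rows.append({"day": day, "parameter": name, "dims": m.dims,
                             "value": value})
        record.outputs[f"day{day}"] = str(day_dir)

    table = pd.DataFrame(rows, columns=["day", "parameter", "dims", "value"])
    table.to_csv(out_root / "metrics.csv", index=False)
    record.outputs["metrics"] = str(out_root / "metrics.csv")
    record.save(out_root / "run_record.json")
    return record
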