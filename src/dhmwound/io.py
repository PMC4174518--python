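"""File formats, run configuration and the end-to-end pipeline driver.

Phase maps travel as 32-bit float TIFF in radians (lossless for the
quantities downstream); holograms as 16-bit integer TIFF (camera
realism).  Tabular outputs are tidy CSVs whose column names carry units.
A full run is a pure function of the YAML config plus the seed: rerunning
writes byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import StageError, ValidationError
from .holography import Hologram, background_correct, reconstruct_phase, unwrap_phase
from .metrics import compute_frame_metrics, estimate_rates, frames_to_table, relative_series
from .optics import OpticalConfig, PhaseImage, RegionMask
from .segmentation import WoundGeometry, segment_cells

__all__ = [
    "RunConfig",
    "ConditionSpec",
    "read_phase_stack",
    "write_phase_stack",
    "read_hologram_stack",
    "write_hologram_stack",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- formats

def write_phase_stack(path: str | Path, frames: list[PhaseImage]) -> None:
    """Write frames as a multi-page float32 TIFF (radians)."""
    data = np.stack([f.values for f in frames]).astype(np.float32)
    tifffile.imwrite(str(path), data)


def read_phase_stack(
    path: str | Path,
    pixel_pitch_um: float,
    interval_min: float | None = None,
    times_min: list[float] | None = None,
) -> list[PhaseImage]:
    """Read a single- or multi-page float TIFF of phase maps, radians.

    Timestamps come from ``times_min`` (one per page) or a uniform
    ``interval_min``; a single page defaults to t = 0.
    """
    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValidationError(f"expected a 2-D or 3-D TIFF, got shape {data.shape}")
    n = data.shape[0]
    if times_min is not None:
        if len(times_min) != n:
            raise ValidationError(f"{len(times_min)} timestamps for {n} pages")
        times = [float(t) for t in times_min]
    elif interval_min is not None:
        times = [i * float(interval_min) for i in range(n)]
    elif n == 1:
        times = [0.0]
    else:
        raise ValidationError("multi-page stack needs timestamps or a frame interval")
    return [
        PhaseImage(values=data[i], pixel_pitch_um=pixel_pitch_um, time_min=times[i])
        for i in range(n)
    ]


def write_hologram_stack(path: str | Path, holos: list[Hologram]) -> None:
    """Write holograms as 16-bit TIFF, scaled to the global intensity maximum."""
    data = np.stack([h.intensity for h in holos])
    top = data.max()
    scaled = (data / top * 65535).round().astype(np.uint16) if top > 0 else data.astype(np.uint16)
    tifffile.imwrite(str(path), scaled)


def read_hologram_stack(
    path: str | Path, carrier: tuple[float, float], pixel_pitch_um: float
) -> list[Hologram]:
    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    if data.ndim == 2:
        data = data[None]
    return [
        Hologram(intensity=page, carrier=tuple(carrier), pixel_pitch_um=pixel_pitch_um)
        for page in data
    ]


# ------------------------------------------------------------- run config

_SEGMENTATION_KEYS = {
    "threshold", "smooth_sigma", "closing_radius_px", "min_object_um2", "min_hole_um2",
}
_GEOMETRY_KEYS = {"axis", "gap_start_um", "gap_end_um"}
_CONDITION_KEYS = {"n_cell", "dm_single_pg", "x_min_um", "x_max_um"}
_HOLOGRAPHY_KEYS = {"carrier", "window_radius", "background_poly_order"}
_INPUT_KEYS = {"path", "kind", "frame_interval_min"}
_TOP_KEYS = {
    "optics", "segmentation", "geometry", "conditions", "holography",
    "input", "output_dir", "seed",
}


def _check_keys(block: dict, allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValidationError(f"unknown key(s) in {name} block: {sorted(unknown)}")


@dataclass(frozen=True)
class ConditionSpec:
    """One assay side/condition: its refractive index, the mean single-cell
    dry mass used for cell counting, and an optional x-range restriction."""

    n_cell: float
    dm_single_pg: float | None = None
    x_min_um: float | None = None
    x_max_um: float | None = None


@dataclass(frozen=True)
class RunConfig:
    optics: OpticalConfig
    geometry: WoundGeometry
    conditions: dict[str, ConditionSpec]
    input_path: str
    input_kind: str  # "phase" | "holograms"
    frame_interval_min: float
    output_dir: str
    segmentation: dict = field(default_factory=dict)
    holography: dict = field(default_factory=dict)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "top-level")
    for required in ("optics", "geometry", "conditions", "input", "output_dir"):
        if required not in raw:
            raise ValidationError(f"config missing required block {required!r}")
    optics = OpticalConfig.from_dict(raw["optics"])
    geom_raw = dict(raw["geometry"])
    _check_keys(geom_raw, _GEOMETRY_KEYS, "geometry")
    geometry = WoundGeometry(**geom_raw)
    conditions = {}
    for name, block in raw["conditions"].items():
        block = dict(block)
        _check_keys(block, _CONDITION_KEYS, f"conditions.{name}")
        if "n_cell" not in block:
            raise ValidationError(f"conditions.{name} missing n_cell")
        conditions[name] = ConditionSpec(**block)
    seg = dict(raw.get("segmentation", {}))
    _check_keys(seg, _SEGMENTATION_KEYS, "segmentation")
    holo = dict(raw.get("holography", {}))
    _check_keys(holo, _HOLOGRAPHY_KEYS, "holography")
    inp = dict(raw["input"])
    _check_keys(inp, _INPUT_KEYS, "input")
    if "path" not in inp:
        raise ValidationError("input block missing 'path'")
    kind = inp.get("kind", "phase")
    if kind not in ("phase", "holograms"):
        raise ValidationError(f"input.kind must be 'phase' or 'holograms', got {kind!r}")
    if kind == "holograms" and "carrier" not in holo:
        raise ValidationError("holographic input needs holography.carrier in the config")
    return RunConfig(
        optics=optics,
        geometry=geometry,
        conditions=conditions,
        input_path=str(inp["path"]),
        input_kind=kind,
        frame_interval_min=float(inp.get("frame_interval_min", 30.0)),
        output_dir=str(raw["output_dir"]),
        segmentation=seg,
        holography=holo,
        seed=int(raw.get("seed", 0)),
    )


# --------------------------------------------------------------- pipeline

def _reconstruct_stack(config: RunConfig) -> list[PhaseImage]:
    carrier = tuple(config.holography["carrier"])
    holos = read_hologram_stack(config.input_path, carrier, config.optics.pixel_pitch_um)
    order = int(config.holography.get("background_poly_order", 1))
    radius = config.holography.get("window_radius")
    frames = []
    for i, h in enumerate(holos):
        try:
            wrapped = reconstruct_phase(h, carrier_hint=carrier, window_radius=radius)
            phase = unwrap_phase(wrapped)
            # cell-free estimate for the background fit: everything a coarse
            # segmentation leaves uncovered
            coarse = segment_cells(phase, threshold="auto")
            cellfree = ~coarse.values
            if cellfree.sum() >= (order + 1) * (order + 2) // 2:
                phase = background_correct(phase, cellfree, poly_order=order)
        except (ValidationError, StageError) as exc:
            raise StageError("reconstruct", str(exc), frame=i) from exc
        frames.append(
            PhaseImage(
                values=np.clip(phase.values, None, None),
                pixel_pitch_um=config.optics.pixel_pitch_um,
                time_min=i * config.frame_interval_min,
            )
        )
    return frames


def _condition_region(
    cond: ConditionSpec, geometry: WoundGeometry, shape: tuple[int, int], pitch: float
) -> np.ndarray:
    """Gap-band mask restricted to the condition's x-range, if any."""
    region = geometry.mask(shape, pitch).values.copy()
    if cond.x_min_um is not None or cond.x_max_um is not None:
        x = (np.arange(shape[1]) + 0.5) * pitch
        keep = np.ones_like(x, dtype=bool)
        if cond.x_min_um is not None:
            keep &= x >= cond.x_min_um
        if cond.x_max_um is not None:
            keep &= x < cond.x_max_um
        region &= keep[None, :]
    return region


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run reconstruction (if needed), segmentation, metrics and rates.

    Writes ``metrics.csv`` (one row per frame per condition) and
    ``rates.csv`` (one row per metric per condition) under
    ``config.output_dir`` and returns their paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("optics config: %s", config.optics.to_dict())
    logger.info("segmentation params: %s", config.segmentation or "defaults")
    if config.input_kind == "holograms":
        frames = _reconstruct_stack(config)
    else:
        frames = read_phase_stack(
            config.input_path,
            config.optics.pixel_pitch_um,
            interval_min=config.frame_interval_min,
        )
    if len(frames) < 2:
        raise ValidationError("pipeline needs at least 2 frames for a time series")
    shape = frames[0].shape
    metric_tables = []
    rate_tables = []
    for name, cond in config.conditions.items():
        region = _condition_region(cond, config.geometry, shape, config.optics.pixel_pitch_um)
        per_frame = []
        for i, img in enumerate(frames):
            try:
                cell_mask = segment_cells(img, **config.segmentation)
                covered = RegionMask(
                    values=cell_mask.values & region,
                    pixel_pitch_um=img.pixel_pitch_um,
                )
                per_frame.append(
                    compute_frame_metrics(
                        img, covered, cond.n_cell, config.optics,
                        dm_single_pg=cond.dm_single_pg,
                    )
                )
            except (ValidationError, StageError) as exc:
                raise StageError("metrics", str(exc), frame=i) from exc
        series = relative_series(per_frame)
        if cond.dm_single_pg is not None:
            series["n_cells_est"] = series["dDM_pg"] / cond.dm_single_pg
        series.insert(0, "condition", name)
        metric_tables.append(series)
        rates = estimate_rates(frames_to_table(per_frame)).table
        rates.insert(0, "condition", name)
        rate_tables.append(rates)
        logger.info("condition %s: n_cell=%s frames=%d", name, cond.n_cell, len(per_frame))
    metrics_path = out / "metrics.csv"
    rates_path = out / "rates.csv"
    pd.concat(metric_tables, ignore_index=True).to_csv(metrics_path, index=False)
    pd.concat(rate_tables, ignore_index=True).to_csv(rates_path, index=False)
    summary = {
        "n_frames": len(frames),
        "conditions": list(config.conditions),
        "seed": config.seed,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {"metrics": metrics_path, "rates": rates_path}
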