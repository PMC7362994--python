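"""Readers, writers and run configuration.

Tidy long-format CSV carries traces (cell_id, prep_id, condition, dose_um,
time_s, signal, signal_kind); per-cell parameter tables and statistical
reports are CSV/JSON; images are TIFF/PNG with a JSON calibration sidecar.
Numeric round-trips are lossless (values written with full precision).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import FieldImage
from .transients import SIGNAL_KINDS, Transient

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["cell_id", "prep_id", "condition", "dose_um", "time_s", "signal", "signal_kind"]


class SchemaError(ValueError):
    """Input file violates the expected schema."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int
    species: str = "rat"
    out_dir: str = "."
    alpha: float = 0.05
    estimator: str = "reml"
    suitability_rule: bool = True
    equation_form: str = "full_inhibition"
    finder_overrides: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "seed" not in raw:
            raise SchemaError("config must specify a seed")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def log(self) -> None:
        logger.info("run config (sha %s): %s", self.digest(), self.__dict__)


def read_traces(path: str | Path, pacing_hz: float | None = None):
    """Read a tidy trace CSV into (metadata, Transient) pairs.

    Header-driven, so column order is free. Raises :class:`SchemaError` for
    missing columns, unknown signal kinds or non-monotone time, reporting the
    offending cell.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trace file {path}: missing columns {missing}")
    if len(frame) == 0:
        raise SchemaError(f"trace file {path}: no rows")
    bad_kinds = set(frame["signal_kind"].unique()) - set(SIGNAL_KINDS)
    if bad_kinds:
        raise SchemaError(f"trace file {path}: unknown signal_kind {sorted(bad_kinds)}")
    records = []
    for (cell, prep, cond, dose, kind), group in frame.groupby(
        ["cell_id", "prep_id", "condition", "dose_um", "signal_kind"], sort=False
    ):
        t = group["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            first_bad = int(np.nonzero(np.diff(t) <= 0)[0][0])
            raise SchemaError(
                f"trace file {path}: non-monotone time for cell {cell!r} "
                f"near row {group.index[first_bad]}"
            )
        meta = {"cell_id": cell, "prep_id": prep, "condition": cond, "dose_um": dose}
        records.append((meta, Transient(
            time_s=t, signal=group["signal"].to_numpy(dtype=float),
            signal_kind=kind, pacing_hz=pacing_hz,
        )))
    return records


def write_traces(records, path: str | Path) -> None:
    from .synthetic import transients_to_frame

    transients_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def write_params(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-cell parameter table as CSV (full float precision)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_params(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"cell_id", "prep_id", "pct_shortening", "contractile"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"parameter file {path}: missing columns {sorted(missing)}")
    return frame


def read_image(path: str | Path, sidecar: str | Path | None = None) -> FieldImage:
    """Read a TIFF/PNG field image with its JSON calibration sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    pixels = np.asarray(iio.imread(path), dtype=float)
    if pixels.ndim == 3:
        pixels = pixels.mean(axis=2)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise SchemaError(f"calibration sidecar not found: {sidecar}")
    meta = json.loads(Path(sidecar).read_text())
    if "calibration_um_per_px" not in meta:
        raise SchemaError(f"sidecar {sidecar}: missing calibration_um_per_px")
    return FieldImage(pixels=pixels, calibration_um_per_px=float(meta["calibration_um_per_px"]))


def report_block(fit, parameter: str) -> dict:
    """One parameter's simple + hierarchical report block."""
    return {
        "parameter": parameter,
        "simple": {"mean": fit.simple_mean, "se": fit.simple_se, "n": fit.n_total},
        "hierarchical": {
            "mean": fit.grand_mean, "se": fit.se,
            "icc": fit.icc, "eff_df": fit.eff_df,
            "n_preps": fit.n_clusters,
            "suitable": bool(fit.p_cluster < 0.05),
        },
    }


def write_report(blocks: list[dict], path: str | Path, comparisons: list[dict] | None = None) -> None:
    """Write a statistics report (simple + hierarchical blocks) as JSON."""
    payload = {"blocks": blocks}
    if comparisons:
        payload["comparisons"] = comparisons
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
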