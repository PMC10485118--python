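"""File formats, configuration, and run provenance.

Frames, plot tables, observations and results travel as CSV; polygon
layers (agricultural masks, subsidized-area polygons) as GeoJSON in planar
metric coordinates; configuration as YAML (JSON accepted); provenance as
JSON.  Floats are written with 10 significant digits so that re-runs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FRAME_COLUMNS",
    "RunProvenance",
    "read_square_frame",
    "write_square_frame",
    "read_polygons",
    "read_config",
    "write_csv",
    "file_digest",
]

logger = logging.getLogger(__name__)

#: required columns of a square-frame CSV, with their units
FRAME_COLUMNS = {
    "square_id": "unique identifier",
    "x": "square centre easting (m, planar)",
    "y": "square centre northing (m, planar)",
    "density_class": "'dense' (1 per 48 km²) or 'regular' (1 per 96 km²)",
    "A_i": "accessible agricultural area (km²)",
    "n_i": "habitat plot centres on accessible land (count, 0..361)",
    "elev": "mean elevation of accessible land (m a.s.l.)",
    "U": "stratum label, first stratification (production zones)",
    "V": "stratum label, second stratification (biogeographic regions)",
    "R": "rotation group (panel year)",
}

_FLOAT_FORMAT = "%.10g"


def read_square_frame(path) -> pd.DataFrame:
    """Read and validate a square-frame CSV.

    Checks for the required columns, finite numeric values, ``n_i`` within
    0..361 and non-negative areas; raises a descriptive error naming the
    file and the offending column.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ValueError(f"cannot read square frame from {path}: {exc}") from exc
    missing = [c for c in FRAME_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("x", "y", "A_i", "n_i", "elev"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"{path}: non-numeric values in column '{col}'")
        frame[col] = vals
    if (frame["A_i"] < 0).any():
        raise ValueError(f"{path}: negative accessible area A_i")
    if ((frame["n_i"] < 0) | (frame["n_i"] > 361)).any():
        raise ValueError(f"{path}: n_i outside the valid range 0..361")
    if frame["square_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate square ids")
    return frame


def write_square_frame(frame: pd.DataFrame, path) -> None:
    write_csv(frame, path)


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a CSV with the documented 10-significant-digit float format."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_polygons(path) -> dict:
    """Read a GeoJSON file into shapely geometries indexed by feature id.

    Coordinates are taken as planar metric; areas are therefore directly
    in m².  Invalid geometries raise an error naming the feature.
    """
    from shapely.geometry import shape

    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    if not features:
        logger.warning("%s: empty polygon collection", path)
        return {}
    out = {}
    for k, feat in enumerate(features):
        fid = feat.get("id", feat.get("properties", {}).get("id", k))
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise ValueError(f"{path}: invalid geometry for feature "
                             f"{fid!r}: {exc}") from exc
        if not geom.is_valid:
            raise ValueError(f"{path}: invalid geometry for feature {fid!r}")
        out[fid] = geom
    return out


def read_config(path) -> dict:
    """Read a YAML (or JSON) configuration file into a dict."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunProvenance:
    """Everything needed to re-run a stage bit-identically."""

    stage: str
    seed: int | None
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    algorithm_versions: dict = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.algorithm_versions:
            from . import __version__
            self.algorithm_versions = {
                "allema": __version__,
                "numpy": np.__version__,
            }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        record = asdict(self)
        record["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2, default=str)
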