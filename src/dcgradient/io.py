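"""Plain-text I/O: delimited signal matrices, tables, configs, manifests.

All artifacts are diffable text: signals as TSV matrices (rows =
samples, columns = channels, header row of channel ids) with a JSON
metadata sidecar, tables as TSV with stable column order, configuration
as YAML, manifests as JSON with SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, DataError
from .grid import ChannelGrid, build_channel_grid
from .signals import HemoglobinTimeSeries, OpticalTimeSeries


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_timeseries(ts, path) -> Path:
    """Write a hemoglobin or optical time series as TSV + metadata sidecar.

    Hemoglobin columns are ``<channel>.HbO`` / ``<channel>.HbR``;
    optical columns are ``<channel>.w<wavelength>``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(ts, HemoglobinTimeSeries):
        cols = {}
        for i, c in enumerate(ts.channel_ids):
            cols[f"{c}.HbO"] = ts.hbo[i]
        for i, c in enumerate(ts.channel_ids):
            cols[f"{c}.HbR"] = ts.hbr[i]
        meta = {
            "kind": "hemoglobin",
            "sampling_rate": ts.sampling_rate,
            "channel_ids": list(ts.channel_ids),
        }
    elif isinstance(ts, OpticalTimeSeries):
        cols = {}
        for w, wl in enumerate(ts.wavelengths_nm):
            for i, c in enumerate(ts.channel_ids):
                cols[f"{c}.w{wl:g}"] = ts.intensities[w, i]
        meta = {
            "kind": "optical",
            "sampling_rate": ts.sampling_rate,
            "channel_ids": list(ts.channel_ids),
            "wavelengths_nm": list(ts.wavelengths_nm),
        }
    else:
        raise DataError(f"cannot serialize object of type {type(ts).__name__}")
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")
    _meta_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_timeseries(path):
    """Read a time series written by :func:`write_timeseries`.

    Validates against the metadata sidecar; ragged or non-numeric rows
    surface as a :class:`DataError` naming the offending line.
    """
    path = Path(path)
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise DataError(f"metadata sidecar missing: {meta_file}")
    meta = json.loads(meta_file.read_text())
    try:
        frame = pd.read_csv(path, sep="\t", dtype=float, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    ids = meta["channel_ids"]
    fs = float(meta["sampling_rate"])
    if meta["kind"] == "hemoglobin":
        expected = [f"{c}.HbO" for c in ids] + [f"{c}.HbR" for c in ids]
        missing = [c for c in expected if c not in frame.columns]
        if missing:
            raise DataError(f"{path}: columns do not match sidecar: missing {missing}")
        hbo = frame[[f"{c}.HbO" for c in ids]].to_numpy().T
        hbr = frame[[f"{c}.HbR" for c in ids]].to_numpy().T
        return HemoglobinTimeSeries(hbo=hbo, hbr=hbr, channel_ids=ids, sampling_rate=fs)
    if meta["kind"] == "optical":
        wls = meta["wavelengths_nm"]
        arrs = []
        for wl in wls:
            cols = [f"{c}.w{wl:g}" for c in ids]
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise DataError(f"{path}: missing columns {missing}")
            arrs.append(frame[cols].to_numpy().T)
        return OpticalTimeSeries(
            intensities=np.stack(arrs),
            channel_ids=ids,
            sampling_rate=fs,
            wavelengths_nm=tuple(wls),
        )
    raise DataError(f"unknown time-series kind {meta['kind']!r}")


def validate_against_grid(ts, grid: ChannelGrid) -> None:
    """Ensure the time-series channels are consistent with the grid layout."""
    unknown = sorted(set(ts.channel_ids) - set(grid.channel_ids))
    if unknown:
        raise DataError(f"time-series channels not in grid layout: {unknown}")
    missing = sorted(set(grid.analyzed["id"]) - set(ts.channel_ids))
    if missing:
        raise DataError(f"time series lacks grid channels: {missing}")


def write_grid(grid: ChannelGrid, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(grid.to_config(), sort_keys=False))
    return path


def read_grid(path) -> ChannelGrid:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"grid layout file not found: {path}")
    return build_channel_grid(yaml.safe_load(path.read_text()))


def write_table(frame: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format="%.17g")
    return path


def write_dc_matrix(dc, path) -> Path:
    """Square matrix file (sink rows x source columns) with channel-id labels."""
    frame = pd.DataFrame(dc.dc, index=dc.channel_ids, columns=dc.channel_ids)
    frame.index.name = "sink"
    return write_table(frame, path, index=True)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path
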