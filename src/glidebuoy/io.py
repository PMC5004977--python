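"""Reading and writing the package's interchange formats.

Tag records travel as CSV (columns time_s, depth_m, ax, ay, az and
optionally prop_rps) or NetCDF with equivalently named variables; glide
segment tables as CSV with the exact GlideSegment field names; model
specs and priors as YAML.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .bayes import ModelSpec, Priors
from .simulate import DivePlan, GlideTableDesign, TruthConfig
from .tagdata import SEGMENT_COLUMNS, TagRecord

__all__ = [
    "read_tag_record_csv",
    "write_tag_record_csv",
    "read_tag_record_netcdf",
    "write_tag_record_netcdf",
    "read_segments_csv",
    "write_segments_csv",
    "load_model_spec",
    "load_priors",
    "load_sim_config",
]

_RECORD_COLUMNS = ["time_s", "depth_m", "ax", "ay", "az"]


def read_tag_record_csv(path, individual_id: Optional[str] = None) -> TagRecord:
    table = pd.read_csv(path)
    missing = set(_RECORD_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"tag record CSV missing columns: {sorted(missing)}")
    time = table["time_s"].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(time)))
    prop = (
        table["prop_rps"].to_numpy(dtype=float) if "prop_rps" in table.columns else None
    )
    return TagRecord(
        individual_id=individual_id or str(path),
        sample_rate=fs,
        time=time,
        depth=table["depth_m"].to_numpy(dtype=float),
        accel=table[["ax", "ay", "az"]].to_numpy(dtype=float),
        propeller_rate=prop,
    )


def write_tag_record_csv(record: TagRecord, path) -> None:
    data = {
        "time_s": record.time,
        "depth_m": record.depth,
        "ax": record.accel[:, 0],
        "ay": record.accel[:, 1],
        "az": record.accel[:, 2],
    }
    if record.propeller_rate is not None:
        data["prop_rps"] = record.propeller_rate
    pd.DataFrame(data).to_csv(path, index=False)


def write_tag_record_netcdf(record: TagRecord, path) -> None:
    import xarray as xr

    ds = xr.Dataset(
        {
            "depth_m": ("time", record.depth),
            "ax": ("time", record.accel[:, 0]),
            "ay": ("time", record.accel[:, 1]),
            "az": ("time", record.accel[:, 2]),
        },
        coords={"time": record.time},
        attrs={
            "individual_id": record.individual_id,
            "sample_rate": record.sample_rate,
            "location_tag": record.location_tag,
        },
    )
    if record.propeller_rate is not None:
        ds["prop_rps"] = ("time", record.propeller_rate)
    ds.to_netcdf(path, engine="scipy")


def read_tag_record_netcdf(path) -> TagRecord:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        time = ds["time"].values.astype(float)
        fs = float(ds.attrs.get("sample_rate", 1.0 / np.median(np.diff(time))))
        prop = ds["prop_rps"].values if "prop_rps" in ds else None
        return TagRecord(
            individual_id=str(ds.attrs.get("individual_id", path)),
            sample_rate=fs,
            time=time,
            depth=ds["depth_m"].values.astype(float),
            accel=np.column_stack(
                [ds["ax"].values, ds["ay"].values, ds["az"].values]
            ).astype(float),
            propeller_rate=prop,
            location_tag=str(ds.attrs.get("location_tag", "")),
        )


def read_segments_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(SEGMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"segment CSV missing columns: {sorted(missing)}")
    return table[SEGMENT_COLUMNS]


def write_segments_csv(segments: pd.DataFrame, path) -> None:
    segments[SEGMENT_COLUMNS].to_csv(path, index=False)


def load_model_spec(path) -> ModelSpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return ModelSpec(**cfg)


def load_priors(path) -> Priors:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for key in ("r_bounds", "density_bounds", "gas_global_bounds", "gas_value_bounds",
                "drag_bounds", "error_scale_bounds"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return Priors(**cfg)


def load_sim_config(path):
    """Parse a simulation YAML with optional truth/design/plan sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    truth = TruthConfig(**cfg.get("truth", {}))
    design = GlideTableDesign(**cfg.get("design", {}))
    plan = DivePlan(**cfg.get("plan", {}))
    return truth, design, plan
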