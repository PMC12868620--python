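"""CSV/YAML/JSON readers and writers and the run configuration.

Trace tables are long-format CSV with one row per (trace, timepoint):

    trace_id, kind, cell_line, ca_mM, field_level, replicate_id,
    exposure_time_s, time_s, value

Morphometry and force-curve dialects are documented in their modules.
Every report run writes a manifest JSON recording the tool version, the
configuration and its hash, so outputs are reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .traces import ExponentialUptakeFit, FluorescenceTrace

__all__ = [
    "RunConfig",
    "load_traces",
    "save_traces",
    "traces_to_frame",
    "save_fits",
    "write_manifest",
]

TRACE_COLUMNS = [
    "trace_id",
    "kind",
    "cell_line",
    "ca_mM",
    "field_level",
    "replicate_id",
    "exposure_time_s",
    "time_s",
    "value",
]

_META_KEYS = ("kind", "cell_line", "ca_mM", "field_level", "replicate_id")


@dataclasses.dataclass
class RunConfig:
    """Run configuration, serializable to/from a YAML file.

    Unknown keys in the file are rejected so typos fail loudly.
    """

    output_dir: str = "electroperm_out"
    traces_csv: str | None = None
    seed: int = 0
    sampling_interval_s: float = 3.0
    t_eval_s: float = 180.0
    n_per_group: int = 20
    stages: tuple[str, ...] = ("simulate", "fit", "stats", "threshold")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def traces_to_frame(traces: list[FluorescenceTrace]) -> pd.DataFrame:
    """Flatten traces into the long CSV dialect."""
    frames = []
    for tr in traces:
        df = pd.DataFrame({"time_s": tr.times, "value": tr.values})
        df["trace_id"] = tr.meta.get("trace_id", "")
        for k in _META_KEYS:
            df[k] = tr.meta.get(k, "")
        df["exposure_time_s"] = tr.exposure_time
        frames.append(df[TRACE_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def save_traces(traces: list[FluorescenceTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def load_traces(path: str | Path) -> list[FluorescenceTrace]:
    """Read a long-format trace CSV into validated traces.

    Rows within a trace are sorted by time; missing columns, duplicate
    (trace_id, time_s) rows and non-finite values raise descriptive errors
    naming the offending column or rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("trace_id", "time_s", "value", "exposure_time_s") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    dup = df.duplicated(subset=["trace_id", "time_s"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate (trace_id, time_s) at file row(s) {rows}")
    bad = ~np.isfinite(df["value"].to_numpy(dtype=float))
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]
        raise ValueError(f"{path}: non-finite value at file row(s) {rows}")
    traces = []
    for trace_id, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("time_s")
        t0 = grp["exposure_time_s"].iloc[0]
        if grp["exposure_time_s"].nunique() != 1:
            raise ValueError(f"{path}: trace '{trace_id}' has conflicting exposure_time_s")
        meta = {"trace_id": trace_id}
        for k in _META_KEYS:
            if k in grp.columns:
                meta[k] = grp[k].iloc[0]
        traces.append(
            FluorescenceTrace(
                times=grp["time_s"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
                exposure_time=float(t0),
                meta=meta,
            )
        )
    return traces


def save_fits(fits: dict[str, ExponentialUptakeFit], path: str | Path) -> None:
    """Write per-trace exponential fits (trace_id, amplitude, tau_s, r2, converged)."""
    pd.DataFrame(
        [
            {
                "trace_id": tid,
                "amplitude": f.amplitude,
                "tau_s": f.tau_reseal,
                "r2": f.r_squared,
                "converged": f.converged,
            }
            for tid, f in fits.items()
        ]
    ).to_csv(path, index=False)


def write_manifest(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Record tool version, config and config hash next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "tool": "electroperm",
        "version": __version__,
        "config": {**dataclasses.asdict(config), "stages": list(config.stages)},
        "config_hash": config.digest(),
    }
    if extra:
        payload.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
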