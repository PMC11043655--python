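"""File formats and pipeline configuration.

Time series travel as two-column delimited text (``time_s,value``) with a
JSON sidecar carrying sampling rate and labels — inspectable and
language-neutral, since source-space regional series have no single
standard container.  Values are written with ``repr`` so a write/read
round-trip is bit-exact.  Grids are long-format CSV tables (one row per
cell); reports are JSON.

The pipeline configuration is one YAML document with four sections
(``cohort``, ``grid``, ``stats``, ``output``); unknown keys are rejected so
typos fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .comodulogram import GridSpec, PacGrid, frame_to_grids, grids_to_frame
from .pac import PacParameterError, RegionalTimeSeries
from .synthdata import CouplingSpec, SyntheticCohortSpec

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_cohort",
    "read_cohort",
    "write_grids",
    "read_grids",
    "PipelineConfig",
    "load_config",
    "config_to_dict",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_timeseries(ts: RegionalTimeSeries, path: str | Path, sidecar: bool = True) -> Path:
    """Write ``time_s,value`` text plus (by default) a JSON sidecar with fs and labels."""
    path = Path(path)
    t = np.arange(ts.n_samples) / ts.fs
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for ti, vi in zip(t.tolist(), ts.samples.tolist()):
            # Python float repr round-trips exactly, so read-back is bit-identical
            fh.write(f"{ti!r},{vi!r}\n")
    if sidecar:
        meta = {
            "subject_id": ts.subject_id,
            "group": ts.group,
            "region": ts.region,
            "fs_hz": ts.fs,
            "n_samples": ts.n_samples,
            "duration_s": ts.duration,
        }
        with open(_sidecar_path(path), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return path


def read_timeseries(
    path: str | Path,
    sidecar: str | Path | dict | None = None,
    fs: float | None = None,
    subject_id: str | None = None,
    group: str | None = None,
    region: str | None = None,
) -> RegionalTimeSeries:
    """Read a one- or two-column delimited text time series.

    Sampling rate must come from the sidecar (a path, a dict, or the
    default ``<stem>.json`` beside the file) or the ``fs`` argument.
    Non-numeric or non-finite rows are rejected with their row number.
    """
    path = Path(path)
    meta: dict = {}
    if isinstance(sidecar, dict):
        meta = dict(sidecar)
    else:
        sc = Path(sidecar) if sidecar is not None else _sidecar_path(path)
        if sc.exists():
            with open(sc) as fh:
                meta = json.load(fh)
    fs = fs if fs is not None else meta.get("fs_hz")
    if fs is None:
        raise PacParameterError(
            f"no sampling rate for {path}: provide fs or a sidecar with 'fs_hz'"
        )
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    col = "value" if "value" in frame.columns else frame.columns[-1]
    values = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=np.float64)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.nonzero(bad)[0][0]) + 2  # 1-based, counting the header line
        raise PacParameterError(
            f"{path}: non-numeric or non-finite value at line {row}"
        )
    return RegionalTimeSeries(
        samples=values,
        fs=float(fs),
        subject_id=subject_id if subject_id is not None else str(meta.get("subject_id", "")),
        group=group if group is not None else str(meta.get("group", "")),
        region=region if region is not None else str(meta.get("region", "")),
    )


def write_cohort(cohort: list[RegionalTimeSeries], out_dir: str | Path) -> Path:
    """One ``<subject>__<region>.csv`` (+ sidecar) per series, plus a cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for ts in cohort:
        name = f"{ts.subject_id}__{ts.region}.csv"
        write_timeseries(ts, out_dir / name)
        files.append(name)
    manifest = out_dir / "cohort.json"
    with open(manifest, "w") as fh:
        json.dump({"files": sorted(files)}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def read_cohort(in_dir: str | Path) -> list[RegionalTimeSeries]:
    """Read every time series listed by the cohort manifest (or all ``*.csv``)."""
    in_dir = Path(in_dir)
    manifest = in_dir / "cohort.json"
    if manifest.exists():
        with open(manifest) as fh:
            names = json.load(fh)["files"]
        paths = [in_dir / n for n in names]
    else:
        paths = sorted(p for p in in_dir.glob("*.csv"))
    if not paths:
        raise PacParameterError(f"no time-series files found in {in_dir}")
    return [read_timeseries(p) for p in paths]


def write_grids(grids: list[PacGrid], path: str | Path) -> Path:
    path = Path(path)
    grids_to_frame(grids).to_csv(path, index=False)
    return path


def read_grids(path: str | Path, spec: GridSpec | None = None) -> list[PacGrid]:
    return frame_to_grids(pd.read_csv(Path(path)), spec=spec)


# --------------------------------------------------------------------------
# Pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs: cohort source, grid spec, statistics."""

    grid: GridSpec
    cohort: SyntheticCohortSpec | None = None
    input_dir: str | None = None
    group_a: str = "A"
    group_b: str = "B"
    regions: tuple[str, ...] | None = None
    n_perm: int = 1024
    cluster_alpha: float = 0.05
    stats_seed: int = 0
    out_dir: str = "pacgrid_out"
    write_signals: bool = False

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise PacParameterError(
                "config needs exactly one of a synthetic cohort spec or an input directory"
            )
        if self.n_perm < 10:
            raise PacParameterError(f"n_perm={self.n_perm} is below the minimum of 10")


def _require_keys(section: str, data: dict, allowed: set[str], required: set[str] = frozenset()):
    unknown = set(data) - allowed
    if unknown:
        raise PacParameterError(f"unknown key(s) in {section}: {sorted(unknown)}")
    missing = required - set(data)
    if missing:
        raise PacParameterError(f"missing key(s) in {section}: {sorted(missing)}")


_COUPLING_KEYS = {
    "f_phase",
    "f_amp",
    "kappa",
    "preferred_phase_deg",
    "lf_amplitude",
    "hf_amplitude",
    "noise_sd",
    "noise_exponent",
    "phase_jitter",
}


def _coupling_from_dict(section: str, data: dict) -> CouplingSpec:
    _require_keys(section, data, _COUPLING_KEYS)
    kwargs = dict(data)
    if "preferred_phase_deg" in kwargs:
        kwargs["preferred_phase"] = math.radians(kwargs.pop("preferred_phase_deg"))
    return CouplingSpec(**kwargs)


def _cohort_from_dict(data: dict) -> SyntheticCohortSpec:
    allowed = {
        "n_group_a",
        "n_group_b",
        "label_a",
        "label_b",
        "fs",
        "duration",
        "seed",
        "regions",
    }
    _require_keys("cohort", data, allowed, {"n_group_a", "n_group_b", "regions"})
    label_a = data.get("label_a", "A")
    label_b = data.get("label_b", "B")
    coupling: dict[str, dict[str, CouplingSpec]] = {}
    for region, by_group in data["regions"].items():
        _require_keys(f"cohort.regions.{region}", by_group, {label_a, label_b})
        coupling[region] = {
            label: _coupling_from_dict(f"cohort.regions.{region}.{label}", cdict)
            for label, cdict in by_group.items()
        }
    return SyntheticCohortSpec(
        n_group_a=int(data["n_group_a"]),
        n_group_b=int(data["n_group_b"]),
        coupling=coupling,
        label_a=label_a,
        label_b=label_b,
        fs=float(data.get("fs", 600.0)),
        duration=float(data.get("duration", 60.0)),
        seed=int(data.get("seed", 0)),
    )


def _grid_from_dict(data: dict) -> GridSpec:
    allowed = {
        "phase_edges",
        "amp_edges",
        "n_surrogates",
        "min_lag",
        "trim",
        "amp_filter",
        "amp_band_expand",
        "seed",
    }
    _require_keys("grid", data, allowed)
    kwargs = dict(data)
    for key in ("phase_edges", "amp_edges"):
        if key in kwargs:
            kwargs[key] = tuple(float(v) for v in kwargs[key])
    return GridSpec(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration; unknown keys are errors."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise PacParameterError(f"{path} is not a mapping")
    _require_keys("config", doc, {"cohort", "input_dir", "grid", "stats", "output"})
    stats = doc.get("stats", {})
    _require_keys("stats", stats, {"n_perm", "cluster_alpha", "seed", "group_a", "group_b", "regions"})
    output = doc.get("output", {})
    _require_keys("output", output, {"dir", "write_signals"})
    cohort = _cohort_from_dict(doc["cohort"]) if "cohort" in doc else None
    group_a = stats.get("group_a", cohort.label_a if cohort else "A")
    group_b = stats.get("group_b", cohort.label_b if cohort else "B")
    regions = stats.get("regions")
    return PipelineConfig(
        grid=_grid_from_dict(doc.get("grid", {})),
        cohort=cohort,
        input_dir=doc.get("input_dir"),
        group_a=group_a,
        group_b=group_b,
        regions=tuple(regions) if regions else None,
        n_perm=int(stats.get("n_perm", 1024)),
        cluster_alpha=float(stats.get("cluster_alpha", 0.05)),
        stats_seed=int(stats.get("seed", 0)),
        out_dir=str(output.get("dir", "pacgrid_out")),
        write_signals=bool(output.get("write_signals", False)),
    )


def config_to_dict(config: PipelineConfig) -> dict:
    """JSON-serializable echo of the effective configuration (for run manifests)."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(config)
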