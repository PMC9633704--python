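"""Delimited-text formats, configuration, and sidecars.

All tables are TSV; timeseries are written regions-as-rows with a header
row of timepoint indices; square matrices (connectomes, meta-matrices)
are plain TSV grids. Every matrix write can carry a JSON sidecar with
the resolved parameters, seed, config hash and package version so runs
are reproducible from their outputs alone.
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
from .synth import CohortSpec, SimulationConfig, StructuralConnectome
from .windows import RegionTimeSeries

__all__ = [
    "PipelineConfig",
    "read_timeseries",
    "write_timeseries",
    "read_connectome",
    "write_connectome",
    "write_matrix",
    "read_manifest",
    "write_manifest",
    "write_sidecar",
    "read_simulation_spec",
    "write_simulation_spec",
]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """End-to-end analysis settings (validated on construction)."""

    window_length: int = 24
    step: int = 1
    taper_sigma: float | None = None  # None -> window_length / 6
    mm_metrics: tuple[str, ...] = ("pearson",)
    tdsm_kinds: tuple[str, ...] = ("linear", "exp_slow", "exp_fast")
    proximal_lags: tuple[int, ...] = (1,)
    distal_k: tuple[int, ...] = (13,)
    distal_mode: str = "per_column"
    sampen_m: int = 1
    sampen_r: float = 0.2
    bins: int = 10
    sf_metric: str = "pearson"
    sf_rank: str = "signed"
    condition_order: tuple[str, ...] = ("UWS", "MCS", "SED", "CON")
    region_subsets: dict | None = None  # name -> list of region ids
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 2 or self.step < 1:
            raise ValueError("window_length >= 2 and step >= 1 required")
        if self.taper_sigma is not None and self.taper_sigma <= 0:
            raise ValueError("taper_sigma must be positive")
        for m in self.mm_metrics:
            if m not in ("pearson", "manhattan", "cosine"):
                raise ValueError(f"unknown MM metric: {m}")
        for k in self.tdsm_kinds:
            if k not in ("linear", "exp_slow", "exp_fast"):
                raise ValueError(f"unknown TDSM kind: {k}")
        if any(l < 1 for l in self.proximal_lags):
            raise ValueError("proximal lags must be >= 1")
        if any(k < 1 for k in self.distal_k):
            raise ValueError("distal k must be >= 1")
        if self.distal_mode not in ("per_column", "vectorized"):
            raise ValueError("distal_mode must be per_column or vectorized")
        if len(self.condition_order) < 2:
            raise ValueError("need >= 2 conditions")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("mm_metrics", "tdsm_kinds", "proximal_lags", "distal_k",
                    "condition_order"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def write_simulation_spec(path, spec: SimulationConfig | CohortSpec) -> None:
    """Serialise a single-subject config or a cohort spec to YAML."""
    if isinstance(spec, SimulationConfig):
        doc = {"kind": "simulation", "config": dataclasses.asdict(spec)}
    elif isinstance(spec, CohortSpec):
        doc = {"kind": "cohort",
               "conditions": list(spec.conditions),
               "n_subjects_per_condition": list(spec.n_subjects_per_condition),
               "base_config": dataclasses.asdict(spec.base_config),
               "overrides": spec.overrides,
               "sc_density": spec.sc_density,
               "base_seed": spec.base_seed}
    else:
        raise TypeError("expected SimulationConfig or CohortSpec")
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_simulation_spec(path) -> SimulationConfig | CohortSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kind = doc.get("kind")
    if kind == "simulation":
        return SimulationConfig(**doc["config"])
    if kind == "cohort":
        return CohortSpec(
            conditions=tuple(doc["conditions"]),
            n_subjects_per_condition=tuple(doc["n_subjects_per_condition"]),
            base_config=SimulationConfig(**doc.get("base_config", {})),
            overrides=doc.get("overrides"),
            sc_density=doc.get("sc_density", 0.3),
            base_seed=doc.get("base_seed", 0))
    raise ValueError(f"unknown spec kind: {kind!r}")


def write_timeseries(path, ts: RegionTimeSeries) -> None:
    """Regions as rows, header row of timepoint indices, region ids in the
    first column."""
    df = pd.DataFrame(ts.values.T, index=list(ts.region_ids),
                      columns=[str(t) for t in range(ts.n_timepoints)])
    df.to_csv(path, sep="\t", index_label="region")
    write_sidecar(path, {"tr_seconds": ts.tr_seconds,
                         "orientation": "regions_by_time"})


def read_timeseries(path, orientation: str = "regions_by_time",
                    tr_seconds: float | None = None) -> RegionTimeSeries:
    """Read a delimited timeseries table.

    ``orientation`` says whether rows are regions (default, the package's
    own format) or timepoints. TR is taken from the JSON sidecar when not
    given explicitly.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "regions_by_time":
        values = mat.T
        region_ids = [str(r) for r in df.index]
    elif orientation == "time_by_regions":
        values = mat
        region_ids = [str(c) for c in df.columns]
    else:
        raise ValueError("orientation must be regions_by_time or time_by_regions")
    if len(set(region_ids)) != len(region_ids):
        raise ValueError("duplicate region ids")
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        coords = [(int(t), region_ids[r]) for t, r in bad[:5]]
        raise ValueError(f"missing/non-finite values at (timepoint, region): "
                         f"{coords}")
    if tr_seconds is None:
        side = _sidecar_path(path)
        if side.exists():
            tr_seconds = json.loads(side.read_text()).get("tr_seconds")
    if tr_seconds is None:
        raise ValueError("tr_seconds not given and no sidecar found")
    return RegionTimeSeries(values=values, tr_seconds=float(tr_seconds),
                            region_ids=tuple(region_ids))


def write_connectome(path, sc: StructuralConnectome) -> None:
    np.savetxt(path, sc.weights, delimiter="\t")


def read_connectome(path) -> StructuralConnectome:
    return StructuralConnectome(weights=np.loadtxt(path, delimiter="\t"))


def write_matrix(path, values: np.ndarray, meta: dict | None = None) -> None:
    """Square matrix as TSV with an optional JSON sidecar of metadata."""
    np.savetxt(path, values, delimiter="\t")
    if meta is not None:
        write_sidecar(path, meta)


def _sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_sidecar(path, meta: dict) -> None:
    meta = dict(meta)
    meta.setdefault("fcdyn_version", __version__)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def write_manifest(path, rows: list[dict]) -> None:
    """Cohort manifest: subject_id, condition, timeseries_path,
    connectome_path."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "condition", "timeseries_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in manifest")
    return df
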