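"""Dataset and configuration I/O.

The dataset format is a single self-describing JSON document (versioned,
MRDviz-style) with top-level keys, in fixed order: ``metadata``,
``subjects``, ``observations``, ``covariates``, ``endpoints`` and
``ground_truth`` (the last omitted when exporting blinded datasets).
Numbers round-trip at full precision; ``+inf`` relapse times ("never
relapses") are serialized as JSON ``null``.  A descriptive schema
document ships at ``docs/schema.json``.

CSV exports are tidy RFC-4180 tables: one subjects table, one long-format
observations table, one ground-truth parameter table.

Simulation configs are YAML or JSON; validation is aggregated (all
problems reported at once) and the fully-resolved config — defaults
included — is echoed into dataset metadata so a dataset can be
regenerated byte-for-byte from its own metadata and stored seed.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from .cohort import (
    ConfigError,
    Dataset,
    Observation,
    SimulationConfig,
    Subject,
    _covariate_from_dict,
    _covariate_to_dict,
    _hazard_from_dict,
    _hazard_to_dict,
    _subgroup_from_dict,
    _subgroup_to_dict,
    config_from_dict,
    config_to_dict,
)
from .trajectory import TrajectoryParams

__all__ = ["write_json", "read_json", "export_csv", "load_config"]

SCHEMA_VERSION = "1.0"


def _repr_float(x) -> str:
    """Shortest round-trip decimal representation for CSV floats."""
    return repr(float(x))
_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


class DatasetValidationError(ValueError):
    """Dataset violates a structural invariant."""


class ReferentialIntegrityError(DatasetValidationError):
    """An observation or endpoint references an unknown subject."""


class MalformedJSONError(ValueError):
    """The file is not parseable JSON."""


def _validate_dataset(dataset: Dataset) -> None:
    problems = []
    ids = {s.id for s in dataset.subjects}
    if len(ids) != len(dataset.subjects):
        problems.append("subjects: duplicate ids")
    dangling = sorted(
        {o.subject_id for o in dataset.observations} - ids
    )
    if dangling:
        raise ReferentialIntegrityError(
            f"observations reference unknown subjects: {dangling}"
        )
    for name, records in dataset.endpoints.items():
        rec_ids = {r["subject_id"] for r in records}
        missing_refs = sorted(rec_ids - ids)
        if missing_refs:
            raise ReferentialIntegrityError(
                f"endpoint {name!r} references unknown subjects: {missing_refs}"
            )
        if ids - rec_ids:
            problems.append(
                f"endpoint {name!r}: subjects missing records: "
                f"{sorted(ids - rec_ids)}"
            )
    for cov, colors in dataset.metadata.get("colormaps", {}).items():
        entries = colors.values() if isinstance(colors, dict) else colors
        bad = [c for c in entries if not _HEX_RE.match(str(c))]
        if bad:
            problems.append(f"colormap {cov!r}: invalid hex codes {bad}")
    if problems:
        raise DatasetValidationError("; ".join(problems))


def _traj_to_dict(p: TrajectoryParams) -> dict:
    return {
        "beta0": p.beta0,
        "beta1": p.beta1,
        "beta2": p.beta2,
        "te": p.te,
        "tr": None if math.isinf(p.tr) else p.tr,
        "sigma": p.sigma,
    }


def _traj_from_dict(d: dict) -> TrajectoryParams:
    return TrajectoryParams(
        beta0=float(d["beta0"]),
        beta1=float(d["beta1"]),
        beta2=float(d["beta2"]),
        te=float(d["te"]),
        tr=math.inf if d.get("tr") is None else float(d["tr"]),
        sigma=float(d["sigma"]),
    )


def _dataset_to_obj(dataset: Dataset, blinded: bool = False) -> dict:
    obj: dict[str, Any] = {
        "metadata": dataset.metadata,
        "subjects": [
            {
                "id": s.id,
                "subgroup": s.subgroup,
                "covariates": s.covariates,
                "time_variant_covariates": {
                    name: [{"start": t, "value": v} for t, v in track]
                    for name, track in s.tv_tracks.items()
                },
                "event_time": s.event_time,
                "status": s.status,
                "censor_reason": s.censor_reason,
            }
            for s in dataset.subjects
        ],
        "observations": [
            {
                "subject_id": o.subject_id,
                "time": o.time,
                "value": o.value,
                "raw_value": o.raw_value,
                "below_lod": o.below_lod,
                "missing": o.missing,
            }
            for o in dataset.observations
        ],
        "covariates": [_covariate_to_dict(c) for c in dataset.covariate_specs],
        "endpoints": dataset.endpoints,
    }
    if not blinded and dataset.ground_truth is not None:
        gt = dataset.ground_truth
        obj["ground_truth"] = {
            "trajectories": {
                sid: _traj_to_dict(p) for sid, p in gt["trajectories"].items()
            },
            "hazard": _hazard_to_dict(gt["hazard"]),
            "subgroups": [_subgroup_to_dict(s) for s in gt["subgroups"]],
        }
    return obj


def write_json(dataset: Dataset, path: str | Path, blinded: bool = False) -> Path:
    """Write the dataset as one UTF-8 JSON document.

    ``blinded`` drops the ``ground_truth`` key (for method-benchmarking
    exercises where the answer sheet stays private).
    """
    _validate_dataset(dataset)
    path = Path(path)
    obj = _dataset_to_obj(dataset, blinded=blinded)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, allow_nan=False)
        fh.write("\n")
    return path


def read_json(path: str | Path) -> Dataset:
    """Read and validate an MRDviz-style JSON dataset.

    Unknown keys warn rather than fail (forward compatibility); a
    schema-version mismatch warns and parsing proceeds best-effort.
    """
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as e:
        raise MalformedJSONError(f"{path}: {e}") from e
    known = {
        "metadata", "subjects", "observations", "covariates", "endpoints",
        "ground_truth",
    }
    unknown = set(obj) - known
    if unknown:
        warnings.warn(f"{path}: ignoring unknown top-level keys {sorted(unknown)}")
    missing_keys = {"metadata", "subjects", "observations"} - set(obj)
    if missing_keys:
        raise DatasetValidationError(
            f"{path}: missing required top-level keys {sorted(missing_keys)}"
        )
    version = obj["metadata"].get("schema_version")
    if version != SCHEMA_VERSION:
        warnings.warn(
            f"{path}: schema version {version!r} != {SCHEMA_VERSION!r}; "
            "attempting best-effort parse"
        )
    subjects = [
        Subject(
            id=s["id"],
            subgroup=s.get("subgroup", ""),
            covariates=dict(s.get("covariates", {})),
            tv_tracks={
                name: [(seg["start"], seg["value"]) for seg in track]
                for name, track in s.get("time_variant_covariates", {}).items()
            },
            truth=None,  # filled from ground_truth below when present
            event_time=float(s["event_time"]),
            status=int(s["status"]),
            censor_reason=s.get("censor_reason", "none"),
        )
        for s in obj["subjects"]
    ]
    observations = [
        Observation(
            subject_id=o["subject_id"],
            time=float(o["time"]),
            value=None if o.get("value") is None else float(o["value"]),
            raw_value=None if o.get("raw_value") is None else float(o["raw_value"]),
            below_lod=bool(o.get("below_lod", False)),
            missing=bool(o.get("missing", False)),
        )
        for o in obj["observations"]
    ]
    covariate_specs = [_covariate_from_dict(c) for c in obj.get("covariates", [])]
    ground_truth = None
    if "ground_truth" in obj:
        gt = obj["ground_truth"]
        trajectories = {
            sid: _traj_from_dict(d) for sid, d in gt.get("trajectories", {}).items()
        }
        ground_truth = {
            "trajectories": trajectories,
            "hazard": _hazard_from_dict(gt.get("hazard", {})),
            "subgroups": [_subgroup_from_dict(s) for s in gt.get("subgroups", [])],
        }
        for s in subjects:
            s.truth = trajectories.get(s.id)
    dataset = Dataset(
        metadata=obj["metadata"],
        subjects=subjects,
        observations=observations,
        covariate_specs=covariate_specs,
        endpoints=obj.get("endpoints", {}),
        ground_truth=ground_truth,
    )
    _validate_dataset(dataset)
    return dataset


def export_csv(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write subjects.csv, observations.csv and ground_truth.csv.

    ``tr = +inf`` (no relapse) serializes as an empty cell.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subj_rows = []
    for s in dataset.subjects:
        row = {"id": s.id, "subgroup": s.subgroup}
        row.update(s.covariates)
        row["event_time"] = s.event_time
        row["status"] = s.status
        row["censor_reason"] = s.censor_reason
        subj_rows.append(row)
    paths = {}
    paths["subjects"] = out_dir / "subjects.csv"
    pd.DataFrame(subj_rows).to_csv(paths["subjects"], index=False, float_format=_repr_float)
    obs = pd.DataFrame(
        [
            {
                "subject_id": o.subject_id,
                "time": o.time,
                "value": o.value,
                "raw_value": o.raw_value,
                "below_lod": o.below_lod,
                "missing": o.missing,
            }
            for o in dataset.observations
        ]
    )
    paths["observations"] = out_dir / "observations.csv"
    obs.to_csv(paths["observations"], index=False, float_format=_repr_float)
    if dataset.ground_truth is not None:
        gt_rows = []
        for sid, p in dataset.ground_truth["trajectories"].items():
            gt_rows.append(
                {
                    "subject_id": sid,
                    "beta0": p.beta0,
                    "beta1": p.beta1,
                    "beta2": p.beta2,
                    "te": p.te,
                    "tr": "" if math.isinf(p.tr) else p.tr,
                    "sigma": p.sigma,
                }
            )
        paths["ground_truth"] = out_dir / "ground_truth.csv"
        pd.DataFrame(gt_rows).to_csv(paths["ground_truth"], index=False, float_format=_repr_float)
    return paths


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a simulation config from YAML or JSON.

    All validation problems are aggregated into one ConfigError; unknown
    top-level keys warn and are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as e:
            raise MalformedJSONError(f"{path}: {e}") from e
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(raw)}")
    return config_from_dict(raw)


def replay_dataset(dataset_or_path: Dataset | str | Path) -> Dataset:
    """Re-run the simulation recorded in a dataset's metadata echo."""
    from .cohort import build_cohort

    ds = (
        dataset_or_path
        if isinstance(dataset_or_path, Dataset)
        else read_json(dataset_or_path)
    )
    cfg = config_from_dict(ds.metadata["config"])
    return build_cohort(cfg, ds.metadata["seed"])
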