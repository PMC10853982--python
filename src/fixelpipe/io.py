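"""Pipeline file formats, configuration hashing and run manifests.

Everything is plain text: tab-separated tables with '.' decimals for
subject records, fixel metrics and results; JSON-lines for streamlines; a
JSON manifest per pipeline stage recording config hash, seed and file
digests so deterministic stages reproduce byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .simulate import GROUPS, SimulationConfig
from .template import TRACT_NAMES, FixelTemplate

_FLOAT_FMT = "%.10g"

COHORT_REQUIRED = ("subject_id", "timepoint", "group", "age", "sex",
                   "education_high", "head_scale")
VOLUME_COLUMNS = ("NBV", "NWMV", "NCGMV", "NDGMV")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def config_hash(config) -> str:
    """Stable digest of a configuration (dataclass or mapping)."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def load_config(path) -> SimulationConfig:
    """Read a YAML/JSON key-value file of SimulationConfig overrides.

    Only top-level scalar fields and per-group scalar overrides
    (``groups: {RRMS: {size: 10, ...}}``) are accepted; unknown keys raise
    :class:`ValidationError` naming the key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must be a mapping")
    config = SimulationConfig()
    scalar_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key, value in raw.items():
        if key == "groups":
            for g, overrides in value.items():
                if g not in config.groups:
                    raise ValidationError(f"unknown group {g!r} in config")
                gp = config.groups[g]
                for k, v in overrides.items():
                    if not hasattr(gp, k):
                        raise ValidationError(
                            f"unknown group config key {g}.{k!r}")
                    setattr(gp, k, v)
        elif key in scalar_fields:
            current = getattr(config, key)
            if isinstance(current, tuple) and isinstance(value, list):
                value = tuple(value)
            setattr(config, key, value)
        else:
            raise ValidationError(f"unknown config key {key!r}")
    config.validate()
    return config


def write_manifest(out_dir, stage: str, seed, config, inputs=(),
                   outputs=(), extra=None) -> Path:
    """One manifest JSON per CLI invocation."""
    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "package_version": __version__,
        **(extra or {}),
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# --------------------------------------------------------------------------
# Cohort table


def write_cohort_table(subjects: pd.DataFrame, path) -> Path:
    path = Path(path)
    subjects.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort TSV (one row per subject x timepoint).

    EDSS may be missing for HC rows (disability is assessed in patients
    only); unknown group labels, negative volumes and duplicate
    (subject, timepoint) pairs are named validation errors.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    bad_groups = set(df["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValidationError(
            f"unknown group label(s) {sorted(bad_groups)}; "
            f"valid: {list(GROUPS)}")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        first = df.loc[dup, ["subject_id", "timepoint"]].iloc[0]
        raise ValidationError(
            f"duplicate (subject, timepoint) row: "
            f"{first['subject_id']}/{first['timepoint']}")
    for col in VOLUME_COLUMNS:
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"negative volume in column {col}")
    if "edss" in df.columns:
        patient = df["group"] != "HC"
        if df.loc[patient, "edss"].isna().any():
            raise ValidationError("missing EDSS on patient rows")
    return df


# --------------------------------------------------------------------------
# Fixel template


def write_fixel_template(template: FixelTemplate, fixels_path,
                         streamlines_path) -> tuple[Path, Path]:
    fixels_path, streamlines_path = Path(fixels_path), Path(streamlines_path)
    df = pd.DataFrame({
        "fixel_id": np.arange(template.n_fixels),
        "i": template.voxels[:, 0], "j": template.voxels[:, 1],
        "k": template.voxels[:, 2],
        "dx": template.directions[:, 0], "dy": template.directions[:, 1],
        "dz": template.directions[:, 2],
        "tract": template.tracts,
    })
    header = (f"#grid\t{template.grid_shape[0]}\t{template.grid_shape[1]}"
              f"\t{template.grid_shape[2]}\t{template.voxel_size_mm}\n")
    with open(fixels_path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    with open(streamlines_path, "w") as fh:
        for sl in template.streamlines:
            fh.write(json.dumps([int(f) for f in sl]) + "\n")
    return fixels_path, streamlines_path


def read_fixel_template(fixels_path, streamlines_path) -> FixelTemplate:
    with open(fixels_path) as fh:
        header = fh.readline().strip().split("\t")
        if header[0] != "#grid" or len(header) != 5:
            raise ValidationError("fixel file must start with a #grid line")
        grid = tuple(int(x) for x in header[1:4])
        voxel_size = float(header[4])
        df = pd.read_csv(fh, sep="\t")
    streamlines = []
    with open(streamlines_path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                streamlines.append(np.asarray(json.loads(line),
                                              dtype=np.int64))
    template = FixelTemplate(
        grid_shape=grid, voxel_size_mm=voxel_size,
        voxels=df[["i", "j", "k"]].to_numpy(dtype=np.int64),
        directions=df[["dx", "dy", "dz"]].to_numpy(dtype=float),
        tracts=df["tract"].to_numpy(dtype=object),
        streamlines=streamlines,
    )
    template.validate()
    return template


# --------------------------------------------------------------------------
# Fixel metric tables (long format) and fixel-directory adapter


def write_fixel_metrics(metrics_list, path) -> Path:
    """Long TSV: subject_id, timepoint, fixel_id, fd, fc."""
    path = Path(path)
    frames = []
    for m in metrics_list:
        frames.append(pd.DataFrame({
            "subject_id": m.subject_id, "timepoint": m.timepoint,
            "fixel_id": np.arange(len(m.fd)), "fd": m.fd, "fc": m.fc,
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_fixel_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"subject_id", "timepoint", "fixel_id", "fd", "fc"}
    if not need <= set(df.columns):
        raise ValidationError(f"fixel metric table needs columns {need}")
    if (df["fd"] < 0).any():
        raise ValidationError("negative FD in fixel metric table")
    if (df["fc"] <= 0).any():
        raise ValidationError("non-positive FC in fixel metric table")
    return df


def read_fixel_directory(directory) -> tuple[pd.DataFrame, dict]:
    """Minimal adapter for a fixel-directory layout of per-fixel scalars.

    Expects ``index.tsv`` (fixel_id, i, j, k) plus one ``<name>.tsv``
    per scalar map with columns (fixel_id, value). Returns the index and a
    dict of scalar arrays aligned to fixel_id order.
    """
    directory = Path(directory)
    index_path = directory / "index.tsv"
    if not index_path.exists():
        raise ValidationError("fixel directory lacks index.tsv")
    index = pd.read_csv(index_path, sep="\t")
    scalars = {}
    for f in sorted(directory.glob("*.tsv")):
        if f.name == "index.tsv":
            continue
        tab = pd.read_csv(f, sep="\t")
        if not {"fixel_id", "value"} <= set(tab.columns):
            raise ValidationError(f"{f.name} needs fixel_id/value columns")
        aligned = tab.set_index("fixel_id").reindex(index["fixel_id"])
        scalars[f.stem] = aligned["value"].to_numpy(dtype=float)
    return index, scalars


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path
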