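"""On-disk formats: subject metadata tables, grid/feature containers, fitted
models, and structured run logs.

Two container dialects are supported, selected by file extension:

* ``.h5`` / ``.hdf5`` — HDF5, lossless (bit-exact round trips).
* ``.txt`` / ``.tsv`` — delimited text with a small ``#``-prefixed header,
  round trips within 1e-12 relative error.

Grid vertex order is row-major over ``(u, v)``: the flat row index is
``u * V + v`` for a ``(U, V)`` grid.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

FORMAT_VERSION = 1

METADATA_COLUMNS = [
    "subject_id",
    "cohort",
    "group_label",
    "centiloid",
    "abeta_status",
    "age",
    "sex",
]

VALID_GROUPS = {"AD", "MCI", "CU"}
VALID_STATUS = {"positive", "negative"}


class FormatVersionError(RuntimeError):
    """Raised when a container's on-disk version does not match this code."""


class MetadataError(ValueError):
    """Raised on malformed subject metadata."""


@dataclass
class FeatureContainer:
    """A flat per-vertex payload (vertices x channels) tied to one grid."""

    subject_id: str
    hemisphere: str
    grid_shape: tuple[int, int]
    payload: np.ndarray

    def __post_init__(self) -> None:
        self.payload = np.asarray(self.payload, dtype=np.float64)
        if self.payload.ndim == 1:
            self.payload = self.payload[:, None]
        u, v = self.grid_shape
        if self.payload.shape[0] != u * v:
            raise ValueError(
                f"payload has {self.payload.shape[0]} rows, expected "
                f"{u}*{v}={u * v} for grid_shape={self.grid_shape}"
            )
        if not np.all(np.isfinite(self.payload)):
            raise ValueError("payload contains non-finite values")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")


# ---------------------------------------------------------------------------
# subject metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path, *, centiloid_cutoff: float = 37.1) -> pd.DataFrame:
    """Read a subject metadata CSV into a validated table.

    Requires a ``subject_id`` column and at least one of ``centiloid`` /
    ``abeta_status``.  When both are present, an explicit ``abeta_status``
    wins; a disagreement with the centiloid-derived status emits a warning.
    Missing ``abeta_status`` is derived from ``centiloid`` (>= cutoff is
    positive).  Rows with neither are dropped with a warning.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise MetadataError("missing required column: subject_id")
    if "centiloid" not in df.columns and "abeta_status" not in df.columns:
        raise MetadataError("need at least one of columns: centiloid, abeta_status")

    dupes = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dupes:
        raise MetadataError(f"duplicate subject_id values: {dupes}")

    if "centiloid" not in df.columns:
        df["centiloid"] = np.nan
    if "abeta_status" not in df.columns:
        df["abeta_status"] = pd.NA

    bad_status = df["abeta_status"].dropna()
    bad_status = bad_status[~bad_status.isin(VALID_STATUS)]
    if len(bad_status):
        lines = (bad_status.index + 2).tolist()  # +2: header + 0-based
        raise MetadataError(f"invalid abeta_status values at CSV lines {lines}")

    derived = np.where(
        df["centiloid"].notna(),
        np.where(df["centiloid"].astype(float) >= centiloid_cutoff, "positive", "negative"),
        None,
    )
    for i in df.index:
        explicit = df.at[i, "abeta_status"]
        if pd.isna(explicit):
            if derived[i] is None:
                warnings.warn(
                    f"subject {df.at[i, 'subject_id']}: no centiloid and no "
                    "abeta_status; row excluded",
                    stacklevel=2,
                )
            df.at[i, "abeta_status"] = derived[i]
        elif derived[i] is not None and explicit != derived[i]:
            warnings.warn(
                f"subject {df.at[i, 'subject_id']}: abeta_status={explicit!r} "
                f"disagrees with centiloid-derived {derived[i]!r}; keeping explicit",
                stacklevel=2,
            )
    df = df[df["abeta_status"].notna()].reset_index(drop=True)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[METADATA_COLUMNS]


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grid / feature containers
# ---------------------------------------------------------------------------


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def write_grid(path: str | Path, container: FeatureContainer, *, group: str = "grids") -> None:
    """Write a container; dialect chosen by extension (HDF5 or text)."""
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            g = f.create_group(group)
            ds = g.create_dataset("payload", data=container.payload)
            ds.attrs["subject_id"] = container.subject_id
            ds.attrs["hemisphere"] = container.hemisphere
            ds.attrs["grid_shape"] = container.grid_shape
            f.attrs["format_version"] = FORMAT_VERSION
    else:
        u, v = container.grid_shape
        header = (
            f"# format_version={FORMAT_VERSION}\n"
            f"# subject_id={container.subject_id}\n"
            f"# hemisphere={container.hemisphere}\n"
            f"# grid_shape={u} {v}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, container.payload, fmt="%.17e", delimiter="\t")


def read_grid(path: str | Path, *, group: str = "grids") -> FeatureContainer:
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise FormatVersionError(
                    f"{path}: format_version {version} != expected {FORMAT_VERSION}"
                )
            ds = f[group]["payload"]
            return FeatureContainer(
                subject_id=str(ds.attrs["subject_id"]),
                hemisphere=str(ds.attrs["hemisphere"]),
                grid_shape=tuple(int(x) for x in ds.attrs["grid_shape"]),
                payload=ds[()],
            )
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        payload = np.loadtxt(fh, ndmin=2)
    version = int(meta.get("format_version", -1))
    if version != FORMAT_VERSION:
        raise FormatVersionError(f"{path}: format_version {version} != expected {FORMAT_VERSION}")
    u, v = (int(x) for x in meta["grid_shape"].split())
    if payload.shape[0] != u * v:
        raise ValueError(
            f"{path}: header grid_shape ({u},{v}) implies {u * v} rows, "
            f"payload has {payload.shape[0]}"
        )
    return FeatureContainer(
        subject_id=meta.get("subject_id", ""),
        hemisphere=meta.get("hemisphere", "left"),
        grid_shape=(u, v),
        payload=payload,
    )


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_model(path: str | Path, model: Any) -> None:
    """Persist a fitted (or fresh) sparse-coding model to HDF5, exactly."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("D", data=model.D)
        f.create_dataset("hessian_diag", data=model.hessian_diag)
        f.create_dataset("visit_count", data=model.visit_count)
        if model.codes is not None:
            f.create_dataset("codes", data=model.codes)
        if model.epoch_losses is not None:
            f.create_dataset("epoch_losses", data=np.asarray(model.epoch_losses))
        h = f.create_group("hyper")
        for key, value in model.hyper.as_dict().items():
            h.attrs[key] = value
        f.attrs["epoch"] = model.epoch


def load_model(path: str | Path) -> Any:
    from .pascs_core import PascsHyper, PascsModel

    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"{path}: not a readable model container ({exc})") from exc
    with f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise FormatVersionError(
                f"{path}: format_version {version} != expected {FORMAT_VERSION}"
            )
        hyper = PascsHyper(**{k: f["hyper"].attrs[k] for k in f["hyper"].attrs})
        model = PascsModel(
            D=f["D"][()],
            hyper=hyper,
            hessian_diag=f["hessian_diag"][()],
            visit_count=f["visit_count"][()],
            codes=f["codes"][()] if "codes" in f else None,
            epoch_losses=list(f["epoch_losses"][()]) if "epoch_losses" in f else None,
            epoch=int(f.attrs["epoch"]),
        )
    return model


# ---------------------------------------------------------------------------
# run log
# ---------------------------------------------------------------------------


@dataclass
class RunLogger:
    """Append-only JSON-lines event log.  Best effort: never raises."""

    path: Path | None = None
    run_id: str = "run"
    events: list[dict] = field(default_factory=list)

    def log(self, event: str, **payload: Any) -> None:
        record = {"run_id": self.run_id, "time": time.time(), "event": event, **payload}
        self.events.append(record)
        if self.path is None:
            return
        try:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(record, default=_jsonify) + "\n")
        except OSError:
            pass


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def run_log(event: str, path: str | Path | None = None, **payload: Any) -> dict:
    """One-shot structured log append; returns the record."""
    logger = RunLogger(path=Path(path) if path else None)
    logger.log(event, **payload)
    return logger.events[-1]
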