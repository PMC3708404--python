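"""Readers and writers for volume stacks, labels and fitted models.

Supported dataset forms: a directory of NIfTI volumes (one file per
sample, id = file stem), a single ``.npz`` archive, or an HDF5 file.
Volumes are cast to 64-bit floats on load for the stability of the
eigen-solves, and shape homogeneity is enforced.  NIfTI affines are read
but ignored with a warning when non-identity: volumes are assumed
pre-registered to a common shape, and no resampling is performed.

Model archives hold every field of a fitted model plus a format version
tag.  The ``.npz`` writer is deterministic (fixed zip timestamps, stored
uncompressed), so identical fits produce bitwise-identical files; HDF5
archives disable object time tracking for the same reason.
"""

from __future__ import annotations

import io as _stdio
import logging
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .gndpca import GNDPCAModel
from .ltc import LTCModel
from .tensor_core import RankOneBasis

__all__ = [
    "Dataset",
    "load_dataset",
    "save_dataset",
    "load_labels",
    "save_labels",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

FORMAT_VERSION = "1"

NIFTI_SUFFIXES = (".nii", ".nii.gz")


@dataclass
class Dataset:
    """A stack of same-shaped volumes with stable ids and optional labels."""

    ids: list[str]
    volumes: list[np.ndarray]
    labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.volumes):
            raise ValueError("ids and volumes must have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            detail = ", ".join(
                f"{i}: {v.shape}" for i, v in zip(self.ids, self.volumes)
            )
            raise ValueError(f"heterogeneous volume shapes ({detail})")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.float64).ravel()
            if self.labels.size != len(self.ids):
                raise ValueError("labels must match the number of samples")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape if self.volumes else ()

    def __len__(self) -> int:
        return len(self.volumes)


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "nifti_dir"
    name = path.name.lower()
    if name.endswith(".npz"):
        return "npz"
    if name.endswith((".h5", ".hdf5")):
        return "hdf5"
    raise ValueError(f"cannot infer dataset format from {path}")


def load_dataset(path: str | Path, format: str | None = None) -> Dataset:
    """Load a volume stack; sample order is lexicographic by id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt == "nifti_dir":
        files = sorted(
            p for p in path.iterdir() if p.name.lower().endswith(NIFTI_SUFFIXES)
        )
        if not files:
            raise ValueError(f"no NIfTI volumes found in {path}")
        ids, vols = [], []
        for p in files:
            img = nib.load(str(p))
            if not np.allclose(img.affine, np.eye(4)):
                warnings.warn(
                    f"{p.name}: non-identity affine ignored; volumes are "
                    "assumed pre-registered",
                    UserWarning,
                )
            vols.append(np.asarray(img.get_fdata(), dtype=np.float64))
            stem = p.name
            for suf in NIFTI_SUFFIXES:
                if stem.lower().endswith(suf):
                    stem = stem[: -len(suf)]
                    break
            ids.append(stem)
    elif fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            ids = [str(s) for s in z["ids"]]
            stack = np.asarray(z["volumes"], dtype=np.float64)
        vols = list(stack)
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][()]]
            vols = list(np.asarray(f["volumes"][()], dtype=np.float64))
    else:
        raise ValueError(f"unknown dataset format {fmt!r}")

    order = np.argsort(ids, kind="stable")
    ids = [ids[i] for i in order]
    vols = [vols[i] for i in order]
    ds = Dataset(ids=ids, volumes=vols, provenance={"source": str(path), "format": fmt})
    log.info("loaded %d volumes of shape %s from %s", len(ds), ds.shape, path)
    return ds


def save_dataset(ds: Dataset, path: str | Path, format: str | None = None) -> None:
    """Write a volume stack in the requested (or extension-inferred) format."""
    path = Path(path)
    fmt = format or ("nifti_dir" if path.suffix == "" else _detect_format(path))
    if fmt == "nifti_dir":
        path.mkdir(parents=True, exist_ok=True)
        for sid, vol in zip(ds.ids, ds.volumes):
            nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path / f"{sid}.nii"))
    elif fmt == "npz":
        _write_npz_deterministic(
            path,
            {"ids": np.array(ds.ids), "volumes": np.stack(ds.volumes)},
        )
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset(
                "ids", data=np.array(ds.ids, dtype="S"), track_times=False
            )
            f.create_dataset("volumes", data=np.stack(ds.volumes), track_times=False)
    else:
        raise ValueError(f"unknown dataset format {fmt!r}")


def load_labels(path: str | Path) -> pd.Series:
    """Two-column CSV (sample_id, label) with labels in {-1, +1}."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("labels CSV needs columns: sample_id, label")
    ids = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1].astype(float)
    if not set(labels.unique()) <= {-1.0, 1.0}:
        raise ValueError("labels must take values in {-1, +1}")
    return pd.Series(labels.values, index=ids.values, name="label")


def save_labels(ids: Sequence[str], labels: Sequence[float], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(ids), "label": np.asarray(labels, dtype=int)}).to_csv(
        path, index=False
    )


# --------------------------------------------------------------------------
# model archives


def _write_npz_deterministic(path: Path, arrays: Mapping[str, np.ndarray]) -> None:
    """np.load-compatible .npz with fixed timestamps and no compression."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = _stdio.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]), allow_pickle=False)
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def _model_arrays(model: GNDPCAModel | LTCModel) -> dict[str, np.ndarray]:
    if isinstance(model, GNDPCAModel):
        arrays = {
            "kind": np.array("gndpca"),
            "version": np.array(FORMAT_VERSION),
            "mean": model.mean,
            "core_ranks": np.array(model.core_ranks, dtype=np.int64),
            "converged": np.array(model.converged),
            "iterations": np.array(model.iterations),
            "objective_trace": np.array(model.objective_trace),
            "subtract_mean": np.array(model.subtract_mean),
        }
        for n, u in enumerate(model.factors):
            arrays[f"factor_{n}"] = u
        return arrays
    if isinstance(model, LTCModel):
        arrays = {
            "kind": np.array("ltc"),
            "version": np.array(FORMAT_VERSION),
            "mean": model.mean,
            "coefficients": model.coefficients,
            "residual_trace": np.array(model.residual_trace),
            "threshold": np.array(model.threshold),
            "relative": np.array(model.relative),
            "subtract_mean": np.array(model.subtract_mean),
        }
        # factors of basis j live in row j of each per-mode matrix
        for n in range(len(model.shape)):
            arrays[f"basis_factors_{n}"] = (
                np.stack([b.factors[n] for b in model.bases])
                if model.bases
                else np.zeros((0, model.shape[n]))
            )
        return arrays
    raise TypeError(f"cannot persist object of type {type(model).__name__}")


def save_model(model: GNDPCAModel | LTCModel, path: str | Path) -> None:
    """Persist a fitted model; format chosen by extension (.npz, .h5/.hdf5)."""
    path = Path(path)
    arrays = _model_arrays(model)
    fmt = _detect_format(path)
    if fmt == "npz":
        _write_npz_deterministic(path, arrays)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            for name in sorted(arrays):
                a = np.asarray(arrays[name])
                if a.dtype.kind == "U":
                    a = a.astype("S")
                f.create_dataset(name, data=a, track_times=False)
    else:
        raise ValueError(f"unsupported model format {fmt!r}")


def _read_arrays(path: Path) -> dict[str, np.ndarray]:
    fmt = _detect_format(path)
    try:
        if fmt == "npz":
            with np.load(path, allow_pickle=False) as z:
                return {k: z[k] for k in z.files}
        if fmt == "hdf5":
            with h5py.File(path, "r") as f:
                return {k: np.asarray(f[k][()]) for k in f.keys()}
    except Exception as exc:
        raise IOError(f"cannot read model archive {path}: {exc}") from exc
    raise ValueError(f"unsupported model format {fmt!r}")


def _scalar_str(a: np.ndarray) -> str:
    v = a.item() if a.shape == () else a
    return v.decode() if isinstance(v, bytes) else str(v)


def load_model(path: str | Path) -> GNDPCAModel | LTCModel:
    """Load a model archive written by :func:`save_model`."""
    path = Path(path)
    arrays = _read_arrays(path)
    for key in ("kind", "version", "mean"):
        if key not in arrays:
            raise IOError(f"truncated or invalid model archive: missing {key!r}")
    version = _scalar_str(arrays["version"])
    if version != FORMAT_VERSION:
        raise ValueError(
            f"model archive version {version!r} not supported (expected {FORMAT_VERSION!r})"
        )
    kind = _scalar_str(arrays["kind"])
    if kind == "gndpca":
        factors = []
        n = 0
        while f"factor_{n}" in arrays:
            factors.append(np.asarray(arrays[f"factor_{n}"], dtype=np.float64))
            n += 1
        if not factors:
            raise IOError("truncated model archive: no factor matrices")
        return GNDPCAModel(
            factors=factors,
            core_ranks=tuple(int(j) for j in arrays["core_ranks"]),
            mean=np.asarray(arrays["mean"], dtype=np.float64),
            converged=bool(arrays["converged"]),
            iterations=int(arrays["iterations"]),
            objective_trace=[float(v) for v in arrays["objective_trace"]],
            subtract_mean=bool(arrays["subtract_mean"]),
        )
    if kind == "ltc":
        mean = np.asarray(arrays["mean"], dtype=np.float64)
        per_mode = []
        n = 0
        while f"basis_factors_{n}" in arrays:
            per_mode.append(np.asarray(arrays[f"basis_factors_{n}"], dtype=np.float64))
            n += 1
        if len(per_mode) != mean.ndim:
            raise IOError("truncated model archive: basis factor matrices missing")
        n_bases = per_mode[0].shape[0]
        bases = [
            RankOneBasis([pm[j] for pm in per_mode]) for j in range(n_bases)
        ]
        return LTCModel(
            mean=mean,
            bases=bases,
            coefficients=np.asarray(arrays["coefficients"], dtype=np.float64),
            residual_trace=[float(v) for v in arrays["residual_trace"]],
            threshold=float(arrays["threshold"]),
            relative=bool(arrays["relative"]),
            subtract_mean=bool(arrays["subtract_mean"]),
        )
    raise ValueError(f"unknown model kind {kind!r}")
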