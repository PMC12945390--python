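"""Serialization: delimited text, HDF5 and NIfTI-1 round-trips.

Conventions: delimited text is comma-separated UTF-8 with units as rows, a
header of state labels and the unit label in the first column; HDF5 layouts
use the dataset names documented per function; volumes are NIfTI-1 via
nibabel with the mask's affine carried through.  Every writer can emit a JSON
provenance sidecar (package version, config, seed) next to its output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .core import ActivityMatrix
from .fmri import AUCMatrix, BetaSet
from .ratemaps import RateMapStack

__all__ = [
    "read_activity_csv",
    "write_activity_csv",
    "read_activity_h5",
    "write_activity_h5",
    "read_ratemaps_h5",
    "write_ratemaps_h5",
    "read_betaset_h5",
    "write_betaset_h5",
    "read_betaset_nifti",
    "write_volume_nifti",
    "read_volume_nifti",
    "write_auc_matrix",
    "read_auc_matrix",
    "write_distribution",
    "write_provenance",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _corrupt(path, what: str) -> ValueError:
    return ValueError(f"cannot parse {path}: missing or invalid {what}")


# ---------------------------------------------------------------------------
# ActivityMatrix

def write_activity_csv(A: ActivityMatrix, path) -> None:
    df = pd.DataFrame(A.values, index=A.unit_labels, columns=A.state_labels)
    df.to_csv(path, index_label="unit", encoding="utf-8")


def read_activity_csv(path) -> ActivityMatrix:
    try:
        df = pd.read_csv(path, index_col=0, encoding="utf-8")
        values = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as err:
        raise _corrupt(path, "numeric matrix body") from err
    return ActivityMatrix(values, [str(x) for x in df.index], [str(c) for c in df.columns])


def write_activity_h5(A: ActivityMatrix, path, group: str = "/") -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for key in ("values", "unit_labels", "state_labels"):
            if key in g:
                del g[key]
        g.create_dataset("values", data=A.values)
        g.create_dataset("unit_labels", data=A.unit_labels, dtype=_STR)
        g.create_dataset("state_labels", data=A.state_labels, dtype=_STR)


def read_activity_h5(path, group: str = "/") -> ActivityMatrix:
    with h5py.File(path, "r") as f:
        g = f[group]
        for key in ("values", "unit_labels", "state_labels"):
            if key not in g:
                raise _corrupt(path, f"dataset {group}/{key}")
        return ActivityMatrix(
            g["values"][()],
            [s.decode() if isinstance(s, bytes) else str(s) for s in g["unit_labels"][()]],
            [s.decode() if isinstance(s, bytes) else str(s) for s in g["state_labels"][()]],
        )


# ---------------------------------------------------------------------------
# RateMapStack

def write_ratemaps_h5(stack: RateMapStack, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=stack.maps)
        f.create_dataset("cell_labels", data=stack.cell_labels, dtype=_STR)
        for name in ("bin_edges_x", "bin_edges_y", "occupancy"):
            arr = getattr(stack, name)
            if arr is not None:
                f.create_dataset(name, data=arr)


def read_ratemaps_h5(path) -> RateMapStack:
    with h5py.File(path, "r") as f:
        if "maps" not in f:
            raise _corrupt(path, "dataset /maps")
        opt = {
            name: f[name][()] if name in f else None
            for name in ("bin_edges_x", "bin_edges_y", "occupancy")
        }
        labels = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in f["cell_labels"][()]
        ]
        return RateMapStack(f["maps"][()], labels, **opt)


# ---------------------------------------------------------------------------
# BetaSet

def write_betaset_h5(bs: BetaSet, path) -> None:
    """Layout: /betas/run{r}/{graph} activity groups, /mask, /affine."""
    with h5py.File(path, "w") as f:
        for (r, g), mat in bs.betas.items():
            grp = f.create_group(f"betas/run{r}/{g}")
            grp.create_dataset("values", data=mat.values)
            grp.create_dataset("unit_labels", data=mat.unit_labels, dtype=_STR)
            grp.create_dataset("state_labels", data=mat.state_labels, dtype=_STR)
        if bs.mask is not None:
            f.create_dataset("mask", data=bs.mask.astype(np.uint8))
        if bs.affine is not None:
            f.create_dataset("affine", data=bs.affine)


def read_betaset_h5(path) -> BetaSet:
    with h5py.File(path, "r") as f:
        if "betas" not in f:
            raise _corrupt(path, "group /betas")
        betas = {}
        for run_name, run_grp in f["betas"].items():
            r = int(run_name.removeprefix("run"))
            for g, grp in run_grp.items():
                betas[(r, g)] = ActivityMatrix(
                    grp["values"][()],
                    [s.decode() if isinstance(s, bytes) else str(s) for s in grp["unit_labels"][()]],
                    [s.decode() if isinstance(s, bytes) else str(s) for s in grp["state_labels"][()]],
                )
        mask = f["mask"][()].astype(bool) if "mask" in f else None
        affine = f["affine"][()] if "affine" in f else None
    return BetaSet(betas, mask=mask, affine=affine)


def read_betaset_nifti(
    volume_paths: Mapping[tuple[int, str], str], mask_path
) -> BetaSet:
    """Searchlight-mode input: one 4-D NIfTI (x, y, z, conditions) per
    (run, graph) plus a binary mask volume; rows follow argwhere(mask)."""
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    betas = {}
    for (r, g), p in volume_paths.items():
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4 or data.shape[:3] != mask.shape:
            raise _corrupt(p, "4-D volume matching the mask geometry")
        vals = data[mask]  # (n_mask, n_conditions)
        betas[(r, g)] = ActivityMatrix(
            vals,
            [f"v{i}" for i in range(vals.shape[0])],
            [f"cond{c}" for c in range(vals.shape[1])],
        )
    return BetaSet(betas, mask=mask, affine=np.asarray(mask_img.affine))


def write_volume_nifti(volume: np.ndarray, affine, path) -> None:
    import nibabel as nib

    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def read_volume_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.affine)


# ---------------------------------------------------------------------------
# AUC matrices, distributions, provenance

def write_auc_matrix(m: AUCMatrix, path) -> None:
    pd.DataFrame(m.values, index=m.graphs, columns=m.graphs).to_csv(
        path, index_label="pc_graph", encoding="utf-8"
    )


def read_auc_matrix(path) -> AUCMatrix:
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    return AUCMatrix(df.to_numpy(dtype=float), [str(g) for g in df.index])


def write_distribution(values: np.ndarray, path, metadata: dict | None = None) -> None:
    """Values as one-per-line text with a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(values, dtype=float))
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(metadata, indent=2, default=str)
        )


def write_provenance(path, config: dict) -> None:
    """JSON sidecar recording the package version and the full run config
    (including the seed) next to an output artifact."""
    from . import __version__

    sidecar = Path(str(path) + ".provenance.json")
    sidecar.write_text(
        json.dumps({"subgen_version": __version__, "config": config}, indent=2, default=str)
    )
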