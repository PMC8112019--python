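"""Readers and writers for the pipeline's on-disk formats.

Matrices and tables travel as TSV with a header row of region ids; larger
matrix stacks can use the binary container (.npy) — either way a JSON
sidecar carries region ids, provenance and any seeds.  Volumes are NIfTI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import RegionAtlas

__all__ = [
    "read_atlas",
    "read_grey_matter",
    "read_fmri",
    "read_region_names",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_matrix_npy",
    "read_matrix_npy",
    "write_covariates_tsv",
    "read_covariates",
]


def read_atlas(path, names_path=None) -> RegionAtlas:
    """Load an integer-labelled atlas NIfTI, optionally with a names TSV."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path}: atlas volume has non-integer labels")
        data = rounded.astype(np.int32)
    names = read_region_names(names_path) if names_path else None
    return RegionAtlas(label_volume=data, region_names=names, affine=img.affine)


def read_grey_matter(path):
    """Load a grey-matter volume/probability NIfTI as a float array."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(float)


def read_fmri(path):
    """Load a 4-D fMRI NIfTI as a float array (x, y, z, t)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4-D volume, got ndim={data.ndim}")
    return data


def read_region_names(path) -> dict[int, str]:
    """Two-column TSV (region id, name) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "name"])
    return {int(r.id): str(r.name) for r in df.itertuples()}


def _sidecar(path: Path, meta: dict) -> None:
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, default=str)
    )


def write_matrix_tsv(path, values, region_ids, meta: dict | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame(np.asarray(values), columns=[str(r) for r in region_ids])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    _sidecar(path, {"region_ids": list(region_ids), **(meta or {})})
    return path


def read_matrix_tsv(path) -> tuple[np.ndarray, tuple[int, ...]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), tuple(int(c) for c in df.columns)


def write_matrix_npy(path, values, region_ids, meta: dict | None = None) -> Path:
    path = Path(path)
    np.save(path, np.asarray(values, dtype=float))
    _sidecar(path, {"region_ids": list(region_ids), **(meta or {})})
    return path


def read_matrix_npy(path) -> np.ndarray:
    return np.load(path)


def write_covariates_tsv(path, records) -> Path:
    rows = []
    for r in records:
        for iid in r.instance_ids:
            rows.append(
                {
                    "subject_id": r.subject_id, "group": r.group, "sex": r.sex,
                    "collection": r.collection, "age": r.age,
                    "mean_fwd": r.mean_fwd, "icv": r.icv, "instance_id": iid,
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_covariates(path):
    """Covariate CSV/TSV -> list of SubjectRecord (delimiter sniffed)."""
    from .matching import records_from_frame

    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return records_from_frame(pd.read_csv(path, sep=sep))
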