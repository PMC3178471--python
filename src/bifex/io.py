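"""Reading and writing masks, marker tables and cohort tables.

Masks round-trip through NIfTI (nibabel) or MetaImage (SimpleITK) with an
axis-aligned affine so world coordinates (mm) are preserved.  Array axis
order is (x, y, z) internally; MetaImage files store (z, y, x) and are
transposed on the way in/out.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .phantoms import BRANCH_LABELS, GroundTruth, LabeledMask

__all__ = [
    "save_mask",
    "load_mask",
    "save_markers",
    "load_markers",
    "save_cohort",
    "load_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ["subject_id", "side", "r_cca_mm", "r_ica_mm", "r_eca_mm"]

_LABEL_NAMES = {v: k for k, v in BRANCH_LABELS.items()}


def save_mask(mask: LabeledMask, path: str | Path) -> None:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(mask.spacing) + [1.0])
        affine[:3, 3] = mask.origin
        nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(mask.voxels.transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in mask.spacing))
        img.SetOrigin(tuple(float(o) for o in mask.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported mask format: {path.name}")


def load_mask(path: str | Path) -> LabeledMask:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        affine = img.affine
        if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
            raise ValueError("only axis-aligned NIfTI affines are supported")
        spacing = tuple(float(x) for x in np.diag(affine[:3, :3]))
        if any(s <= 0 for s in spacing):
            raise ValueError("negative/zero spacing in affine; reorient the image first")
        origin = tuple(float(x) for x in affine[:3, 3])
        vox = np.asarray(img.dataobj).astype(np.uint8)
        return LabeledMask(voxels=vox, spacing=spacing, origin=origin)
    if path.suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        vox = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.uint8)
        return LabeledMask(
            voxels=vox,
            spacing=tuple(float(s) for s in img.GetSpacing()),
            origin=tuple(float(o) for o in img.GetOrigin()),
        )
    raise ValueError(f"unsupported mask format: {path.name}")


def save_markers(gt: GroundTruth, path: str | Path) -> None:
    """Marker endpoints as CSV (x_mm, y_mm, z_mm, branch, position)."""
    rows = []
    for branch, (prox, dist) in gt.markers.items():
        for pos, p in (("proximal", prox), ("distal", dist)):
            rows.append({"x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
                         "branch": branch, "position": pos})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def load_markers(path: str | Path) -> dict[str, np.ndarray]:
    """Markers as {branch: (2, 3) array} ordered (proximal, distal)."""
    df = pd.read_csv(path)
    out: dict[str, np.ndarray] = {}
    for branch, grp in df.groupby("branch"):
        if "position" in grp.columns:
            grp = grp.set_index("position").loc[["proximal", "distal"]]
        if len(grp) != 2:
            raise ValueError(f"branch {branch!r} needs exactly two marker points")
        out[str(branch)] = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    return out


def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def load_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} lacks columns {missing}")
    bad = df[COHORT_COLUMNS[2:]].le(0).any(axis=1)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"cohort table {path}: non-positive radius at row {row}")
    return df
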