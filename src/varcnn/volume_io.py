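"""NIfTI volume I/O, intensity preprocessing, and hippocampal patch cropping.

Volumes are assumed to be registered upstream to a common template grid
(MNI152, ``181x217x181`` at 1 mm); this module only standardises intensities,
clips outliers to the asymmetric range ``[-1, 2.5]`` used for T1 volumes, and
extracts the rectangular patch (default ``80x100x80``) that encloses both
hippocampi.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Default preprocessing constants: clip range on z-scored intensities and
#: the hippocampal crop (corner/size overridable via the shipped config file).
CLIP_RANGE = (-1.0, 2.5)
PATCH_SIZE = (80, 100, 80)

_LABEL_ALIASES = {"0": 0, "1": 1, "nc": 0, "ad": 1}


@dataclass
class Volume:
    """A 3-D intensity volume with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3-D with positive extents, got shape {self.data.shape}")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VolumePatch:
    """A cropped sub-volume; ``origin`` is the crop corner in source voxels."""

    data: np.ndarray
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.origin = tuple(int(c) for c in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SampleRecord:
    """One subject: preprocessed patch, morphological metric vector, label."""

    patch: VolumePatch
    morph: np.ndarray
    label: int
    subject_id: str

    def __post_init__(self):
        self.morph = np.asarray(self.morph, dtype=float).ravel()
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 (NC) or 1 (AD), got {self.label!r}")


def load_volume(path: str | os.PathLike) -> Volume:
    img = nib.load(str(path))
    return Volume(np.asarray(img.dataobj, dtype=np.float64), img.affine)


def save_volume(vol: Volume, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine), str(path))


def normalize_and_clip(vol: Volume, clip_lo: float = CLIP_RANGE[0],
                       clip_hi: float = CLIP_RANGE[1]) -> Volume:
    """Z-score intensities over all voxels of the volume, then clip.

    The clip range is applied *after* standardisation: the asymmetric default
    ``[-1, 2.5]`` truncates dark outliers at one SD below the mean and bright
    outliers at 2.5 SD above it.

    Raises
    ------
    ValueError
        If the clip range is empty or the volume has zero intensity variance
        (a constant volume cannot be z-scored).
    """
    if not clip_lo < clip_hi:
        raise ValueError(f"clip_lo must be < clip_hi, got ({clip_lo}, {clip_hi})")
    data = np.asarray(vol.data, dtype=np.float64)
    sd = data.std()
    if sd == 0:
        raise ValueError("cannot normalize a constant-intensity volume (SD = 0)")
    z = (data - data.mean()) / sd
    return Volume(np.clip(z, clip_lo, clip_hi), vol.affine)


def crop_patch(vol: Volume, corner: tuple[int, int, int],
               size: tuple[int, int, int] = PATCH_SIZE) -> VolumePatch:
    """Extract ``vol[corner : corner+size)`` (0-based, half-open) as a patch."""
    corner = tuple(int(c) for c in corner)
    size = tuple(int(s) for s in size)
    for ax, (c, s, extent) in enumerate(zip(corner, size, vol.shape)):
        if c < 0 or s < 1 or c + s > extent:
            raise ValueError(
                f"crop out of bounds on axis {ax}: corner {c} + size {s} "
                f"exceeds extent {extent}"
            )
    i, j, k = corner
    si, sj, sk = size
    return VolumePatch(vol.data[i:i + si, j:j + sj, k:k + sk].copy(), origin=corner)


def _parse_label(raw) -> int:
    key = str(raw).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unrecognised label {raw!r} (expected 0/1 or NC/AD)")
    return _LABEL_ALIASES[key]


def load_cohort(image_dir: str | os.PathLike, table_path: str | os.PathLike,
                metric_columns: list[str] | None = None,
                crop_corner: tuple[int, int, int] | None = None,
                crop_size: tuple[int, int, int] = PATCH_SIZE,
                clip: tuple[float, float] = CLIP_RANGE,
                normalize: bool = True):
    """Load a cohort from a label/metric table plus one NIfTI per subject.

    The table must contain ``subject_id`` and ``label`` columns; every other
    column (or the explicit ``metric_columns`` subset, in the stated order) is
    taken as a morphological metric.  Images are looked up as
    ``<image_dir>/<subject_id>.nii.gz`` (or ``.nii``).  Rows whose image is
    missing or whose label cannot be parsed are collected in a rejects report
    instead of aborting the load.

    Returns
    -------
    (records, rejects)
        ``records`` is a list of :class:`SampleRecord` in table-row order;
        ``rejects`` is a list of ``{"subject_id", "reason"}`` dicts.
    """
    image_dir = Path(image_dir)
    table = pd.read_csv(table_path, sep=None, engine="python")
    if table.empty:
        raise ValueError(f"cohort table {table_path} is empty")
    for col in ("subject_id", "label"):
        if col not in table.columns:
            raise ValueError(f"cohort table must have a {col!r} column")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r} in cohort table")
    if metric_columns is None:
        metric_columns = [c for c in table.columns if c not in ("subject_id", "label")]

    records: list[SampleRecord] = []
    rejects: list[dict] = []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        path = image_dir / f"{sid}.nii.gz"
        if not path.exists():
            path = image_dir / f"{sid}.nii"
        if not path.exists():
            rejects.append({"subject_id": sid, "reason": "image not found"})
            continue
        try:
            label = _parse_label(row["label"])
        except ValueError as exc:
            rejects.append({"subject_id": sid, "reason": str(exc)})
            continue
        vol = load_volume(path)
        if normalize:
            vol = normalize_and_clip(vol, *clip)
        corner = crop_corner if crop_corner is not None else (0, 0, 0)
        size = crop_size if crop_corner is not None else vol.shape
        patch = crop_patch(vol, corner, size)
        records.append(SampleRecord(patch=patch, morph=row[metric_columns].to_numpy(dtype=float),
                                    label=label, subject_id=sid))
    return records, rejects
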