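"""Atlas-overlap lesion scoring.

A patient's acute lesion mask and a labeled parcellation atlas live on the
same template voxel grid (registration happens upstream); a region counts
as *affected* as soon as a single lesion voxel carries its label — a binary
involvement measure, with no minimum-fraction threshold.  From one overlay
we obtain:

* ``n_rc``  — number of affected rich-club hub regions (0–12 for the
  canonical template: bilateral precuneus, superior frontal and superior
  parietal cortex, hippocampus, putamen, thalamus),
* ``n_total`` — number of affected labeled regions of any kind,
* ``lesion_volume_cc`` — lesion voxel count times voxel volume, in cm³.

Volumes are NIfTI-1 (read through nibabel); the label table is a TSV
sidecar with columns ``label, name, hemisphere, is_rich_club``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError, GridCompatibilityError, InputError

__all__ = [
    "LabelVolume",
    "BinaryMask",
    "InvolvementResult",
    "GridCheck",
    "read_label_volume",
    "write_label_volume",
    "read_mask",
    "write_mask",
    "check_grid_compatible",
    "count_affected_regions",
    "score_cohort",
]

logger = logging.getLogger(__name__)

LABEL_TABLE_COLUMNS = ["label", "name", "hemisphere", "is_rich_club"]


@dataclass
class LabelVolume:
    """Integer label image plus its label table.

    ``label_table`` maps every nonzero label to (name, hemisphere,
    is_rich_club); 0 is reserved for background.
    """

    labels: np.ndarray
    affine: np.ndarray
    label_table: pd.DataFrame

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("label volume must hold integer labels")
        if self.labels.min() < 0:
            raise FormatError("negative labels are not allowed")
        missing = set(LABEL_TABLE_COLUMNS) - set(self.label_table.columns)
        if missing:
            raise FormatError(f"label table missing columns: {sorted(missing)}")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.label_table["label"].astype(int))
        orphans = present - known
        if orphans:
            raise FormatError(
                f"labels present in volume but absent from label table: "
                f"{sorted(orphans)}"
            )

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        return tuple(nib.affines.voxel_sizes(self.affine))

    @property
    def orientation(self) -> tuple[str, str, str]:
        return nib.aff2axcodes(self.affine)

    @property
    def rich_club_labels(self) -> set[int]:
        tab = self.label_table
        return set(tab.loc[tab["is_rich_club"].astype(bool), "label"].astype(int))


@dataclass
class BinaryMask:
    """Boolean lesion mask on the same lattice as the atlas it is scored against."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        return tuple(nib.affines.voxel_sizes(self.affine))

    @property
    def orientation(self) -> tuple[str, str, str]:
        return nib.aff2axcodes(self.affine)

    @property
    def volume_cc(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.voxel_dims)) / 1000.0


@dataclass(frozen=True)
class InvolvementResult:
    """Region-involvement counts for one lesion/atlas overlay."""

    n_rc: int
    n_total: int
    affected_labels: frozenset
    lesion_volume_cc: float


@dataclass(frozen=True)
class GridCheck:
    ok: bool
    reasons: tuple[str, ...] = field(default=())


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_label_volume(nii_path, label_table_path) -> LabelVolume:
    """Load a NIfTI label volume and join its TSV label-table sidecar."""
    img = nib.load(str(nii_path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise FormatError(f"{nii_path}: non-integer label values present")
        data = rounded.astype(np.int32)
    table = pd.read_csv(label_table_path, sep="\t")
    return LabelVolume(labels=data, affine=img.affine, label_table=table)


def write_label_volume(volume: LabelVolume, nii_path, label_table_path) -> None:
    img = nib.Nifti1Image(volume.labels.astype(np.int16), volume.affine)
    nib.save(img, str(nii_path))
    volume.label_table.to_csv(label_table_path, sep="\t", index=False)


def read_mask(nii_path, atol: float = 1e-6) -> BinaryMask:
    """Load a binary lesion mask; float-encoded 0/1 is accepted within ``atol``."""
    img = nib.load(str(nii_path))
    data = np.asanyarray(img.dataobj).astype(float)
    values = np.unique(data)
    if values.size > 2:
        raise FormatError(
            f"{nii_path}: mask has {values.size} distinct values "
            f"(first few: {values[:5].tolist()}); expected binary"
        )
    ok = np.all(np.isclose(values, 0.0, atol=atol) | np.isclose(values, 1.0, atol=atol))
    if not ok:
        raise FormatError(
            f"{nii_path}: mask values {values.tolist()} are not within "
            f"{atol} of {{0, 1}}"
        )
    return BinaryMask(mask=data > 0.5, affine=img.affine)


def write_mask(mask: BinaryMask, nii_path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.affine)
    nib.save(img, str(nii_path))


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

def check_grid_compatible(mask: BinaryMask, atlas: LabelVolume,
                          voxel_tol: float = 1e-3) -> GridCheck:
    """Verify the mask and atlas share shape, voxel size and orientation."""
    reasons = []
    if mask.mask.shape != atlas.labels.shape:
        reasons.append("shape")
    if not np.allclose(mask.voxel_dims, atlas.voxel_dims, atol=voxel_tol):
        reasons.append("voxel_dims")
    if mask.orientation != atlas.orientation:
        reasons.append("orientation")
    return GridCheck(ok=not reasons, reasons=tuple(reasons))


def count_affected_regions(mask: BinaryMask, atlas: LabelVolume,
                           restrict_to_rich_club: bool = False) -> InvolvementResult:
    """Count atlas regions overlapped by the lesion.

    A region is affected iff at least one lesion voxel carries its label.
    ``restrict_to_rich_club`` limits ``affected_labels`` to rich-club
    labels; the counts ``n_rc`` / ``n_total`` always follow their
    definitions.
    """
    check = check_grid_compatible(mask, atlas)
    if not check.ok:
        raise GridCompatibilityError(
            f"mask/atlas grids incompatible: {', '.join(check.reasons)}"
        )
    under = atlas.labels[mask.mask]
    affected = set(int(v) for v in np.unique(under)) - {0}
    rc = atlas.rich_club_labels
    n_rc = len(affected & rc)
    n_total = len(affected)
    reported = affected & rc if restrict_to_rich_club else affected
    return InvolvementResult(
        n_rc=n_rc,
        n_total=n_total,
        affected_labels=frozenset(reported),
        lesion_volume_cc=mask.volume_cc,
    )


def score_cohort(mask_dir, atlas: LabelVolume, cohort: pd.DataFrame,
                 id_column: str = "id") -> pd.DataFrame:
    """Score every patient mask in ``mask_dir`` against the atlas.

    Masks are matched to cohort rows by ``<id>.nii.gz`` (or ``.nii``)
    filename.  Rows without a mask are excluded with a logged count, so the
    returned table only contains fully scored patients; it gains the
    columns ``n_rc``, ``n_total`` and ``dwiv_cc``.
    """
    if cohort[id_column].duplicated().any():
        dupes = cohort.loc[cohort[id_column].duplicated(), id_column].tolist()
        raise InputError(f"duplicate ids in cohort: {dupes[:10]}")
    mask_dir = Path(mask_dir)
    rows = []
    excluded = []
    for _, row in cohort.iterrows():
        pid = row[id_column]
        path = None
        for suffix in (".nii.gz", ".nii"):
            cand = mask_dir / f"{pid}{suffix}"
            if cand.exists():
                path = cand
                break
        if path is None:
            excluded.append(pid)
            continue
        mask = read_mask(path)
        result = count_affected_regions(mask, atlas)
        out = dict(row)
        out["n_rc"] = result.n_rc
        out["n_total"] = result.n_total
        out["dwiv_cc"] = result.lesion_volume_cc
        rows.append(out)
        logger.info("scored %s: n_rc=%d n_total=%d volume=%.2fcc",
                    pid, result.n_rc, result.n_total, result.lesion_volume_cc)
    if excluded:
        logger.warning("excluded %d patients without masks: %s",
                       len(excluded), excluded[:10])
    return pd.DataFrame(rows)
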