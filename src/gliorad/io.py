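"""Reading and writing volumes, masks and clinical tables.

Volumes travel as NIfTI (.nii / .nii.gz) through nibabel.  Only
axis-aligned volumes are supported: an oblique orientation matrix is
rejected with an instruction to resample externally, because all lattice
operations downstream assume the image axes coincide with world axes.

Clinical tables are delimited text (CSV or TSV, sniffed from the
extension) with columns ``patient_id, mgmt, pfs2_months, pfs2_event,
os_months, os_event, cohort``.  Times are months.  A missing or blank
MGMT entry is parsed as status ``missing`` — never silently dropped —
so the modelling stage can decide per endpoint what to do with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import ALIGNMENT_TOL_MM, GridAlignmentError, VoiMask, VoxelGrid

MGMT_STATUSES = ("methylated", "unmethylated", "missing")
COHORTS = ("training", "validation")

CLINICAL_COLUMNS = (
    "patient_id",
    "mgmt",
    "pfs2_months",
    "pfs2_event",
    "os_months",
    "os_event",
    "cohort",
)


class VolumeFormatError(ValueError):
    """A file is not a usable axis-aligned 3D scalar volume."""


class ClinicalTableError(ValueError):
    """A clinical table row violates the schema."""


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical endpoints and cohort membership."""

    patient_id: str
    mgmt: str  # methylated / unmethylated / missing
    pfs2_months: float
    pfs2_event: bool
    os_months: float
    os_event: bool
    cohort: str  # training / validation

    def __post_init__(self) -> None:
        if self.mgmt not in MGMT_STATUSES:
            raise ClinicalTableError(f"unknown MGMT status {self.mgmt!r}")
        if self.cohort not in COHORTS:
            raise ClinicalTableError(f"unknown cohort label {self.cohort!r}")
        if self.pfs2_months < 0 or self.os_months < 0:
            raise ClinicalTableError(
                f"negative survival time for patient {self.patient_id!r}"
            )


def _affine_from_grid(grid: VoxelGrid | VoiMask) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def _grid_geometry(img: nib.Nifti1Image, path) -> tuple[tuple, tuple]:
    affine = img.affine
    rot = affine[:3, :3]
    # off-diagonal terms mean an oblique/rotated orientation
    off = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off)) > ALIGNMENT_TOL_MM:
        raise VolumeFormatError(
            f"{path}: oblique orientation matrix; resample the volume to an "
            "axis-aligned grid externally before loading"
        )
    spacing = tuple(float(abs(d)) for d in np.diag(rot))
    if any(s <= 0 for s in spacing):
        raise VolumeFormatError(f"{path}: missing or non-positive voxel spacing")
    origin = tuple(float(t) for t in affine[:3, 3])
    return spacing, origin


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a NIfTI scalar volume as a :class:`VoxelGrid`."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got {data.ndim}D")
    spacing, origin = _grid_geometry(img, path)
    return VoxelGrid(np.asarray(data, dtype=np.float32), spacing, origin)


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), _affine_from_grid(grid))
    nib.save(img, str(path))


def write_mask(mask: VoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine_from_grid(mask))
    nib.save(img, str(path))


def read_mask(path: str | Path, reference: VoxelGrid, role: str) -> VoiMask:
    """Read a binary mask and bind it to its reference grid and role.

    Values must already be in {0, 1}; the mask must align with
    ``reference`` within :data:`~gliorad.grids.ALIGNMENT_TOL_MM`.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D mask, got {data.ndim}D")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise VolumeFormatError(f"{path}: mask is not binary, found values {uniq[:10]}")
    spacing, origin = _grid_geometry(img, path)
    mask = VoiMask(data.astype(bool), spacing, role, origin)
    if not mask.aligned_with(reference):
        raise GridAlignmentError(
            f"mask {path} does not align with its reference volume: "
            f"shape {mask.shape} vs {reference.shape}, "
            f"spacing {mask.spacing} vs {reference.spacing}, "
            f"origin {mask.origin} vs {reference.origin}"
        )
    return mask


def _parse_mgmt(raw) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "missing"
    text = str(raw).strip().lower()
    if text in ("", "na", "nan", "none", "missing", "no data"):
        return "missing"
    if text in ("methylated", "1", "true"):
        return "methylated"
    if text in ("unmethylated", "0", "false"):
        return "unmethylated"
    raise ClinicalTableError(f"unparseable MGMT status {raw!r}")


def _parse_event(raw, line: int, col: str) -> bool:
    text = str(raw).strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no"):
        return False
    raise ClinicalTableError(f"line {line}: column {col!r} has non-boolean value {raw!r}")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a per-patient clinical table into :class:`ClinicalRecord` rows."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ClinicalTableError(f"{path}: missing required columns {missing_cols}")
    records: list[ClinicalRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            rec = ClinicalRecord(
                patient_id=str(row["patient_id"]).strip(),
                mgmt=_parse_mgmt(row["mgmt"]),
                pfs2_months=float(row["pfs2_months"]),
                pfs2_event=_parse_event(row["pfs2_event"], line, "pfs2_event"),
                os_months=float(row["os_months"]),
                os_event=_parse_event(row["os_event"], line, "os_event"),
                cohort=str(row["cohort"]).strip().lower(),
            )
        except ClinicalTableError as err:
            raise ClinicalTableError(f"{path} line {line}: {err}") from None
        except (TypeError, ValueError) as err:
            raise ClinicalTableError(f"{path} line {line}: {err}") from None
        records.append(rec)
    return records


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "mgmt": [r.mgmt for r in records],
            "pfs2_months": [r.pfs2_months for r in records],
            "pfs2_event": [int(r.pfs2_event) for r in records],
            "os_months": [r.os_months for r in records],
            "os_event": [int(r.os_event) for r in records],
            "cohort": [r.cohort for r in records],
        }
    )
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)
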