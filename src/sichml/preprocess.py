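"""Two-section CT preprocessing into a cohort voxel matrix.

Clinical head CT is often acquired in two blocks — a thick-slice block over
the upper cerebrum and a thin-slice block over the brain base.  After
spatial normalisation the two blocks are joined on a common grid (averaging
where they overlap, leaving a non-sampled "join" where neither covers),
masked inclusively for brain without ventricles, and flattened to one
intensity vector per subject.  Cohort-level cleaning then removes voxels
that are anomalous for brain tissue (< 0 or > 200 HU, or unsampled) in five
or more subjects, imputes rarer anomalies from the remaining subjects'
mean, and finally rescales every subject to the cohort's global mean
intensity.

Arrays are indexed ``[x, y, z]``; flattened vectors use Fortran order so the
x coordinate varies fastest.  Unsampled voxels carry NaN, never a fabricated
Hounsfield value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


UNSAMPLED = np.nan


class SectionKind(str, Enum):
    UPPER = "upper"
    LOWER = "lower"


class RegistrationError(RuntimeError):
    """Rigid alignment failed (no correlated structure found)."""


@dataclass
class CTSection:
    """One acquisition block, on or near the common grid.

    ``origin_offset`` is the z index of the section's first slice within the
    common grid; x/y extents always match the common grid.
    """

    voxels: np.ndarray          # (nx, ny, nz_section) HU
    spacing: tuple[float, float, float]   # mm
    origin_offset: int
    section_kind: SectionKind

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("section contains non-finite HU values")


@dataclass
class JoinedVolume:
    voxels: np.ndarray          # (nx, ny, nz) HU, NaN where unsampled
    sample_count: np.ndarray    # (nx, ny, nz) ints in {0, 1, 2}

    def __post_init__(self) -> None:
        unsampled = self.sample_count == 0
        if not np.all(np.isnan(self.voxels[unsampled])):
            raise ValueError("unsampled voxels must carry the NaN sentinel")


@dataclass
class CohortVoxelMatrix:
    """Subjects x retained-voxels HU matrix plus the cleaning audit trail."""

    values: np.ndarray                  # (n_subjects, n_voxels)
    voxel_index: np.ndarray             # (n_voxels, 3) common-grid coordinates
    deleted_voxels: np.ndarray          # (n_deleted, 3)
    imputed_cells: list[tuple[int, int]] = field(default_factory=list)
    grand_mean: float | None = None     # cohort mean before intensity correction

    def validate(self, hu_low: float = 0.0, hu_high: float = 200.0) -> None:
        if np.any(np.isnan(self.values)):
            raise AssertionError("cleaned matrix contains NaN")
        if np.any(self.values < hu_low) or np.any(self.values > hu_high):
            # intensity correction may rescale slightly past the cleaning
            # bounds; validation is meant for the post-cleaning matrix
            raise AssertionError("cleaned matrix contains out-of-range HU")


def join_sections(upper: CTSection, lower: CTSection) -> JoinedVolume:
    """Join two normalised sections on the common grid.

    Voxels sampled by both sections get the arithmetic mean; voxels sampled
    by one keep that value; voxels sampled by neither are NaN — the black
    "join" seen between acquisition blocks.
    """
    if upper.voxels.shape[:2] != lower.voxels.shape[:2]:
        raise ValueError("sections disagree on in-plane grid size")
    nx, ny = upper.voxels.shape[:2]
    nz = max(upper.origin_offset + upper.voxels.shape[2],
             lower.origin_offset + lower.voxels.shape[2])
    acc = np.zeros((nx, ny, nz))
    count = np.zeros((nx, ny, nz), dtype=np.int8)
    for sec in (upper, lower):
        z0 = sec.origin_offset
        z1 = z0 + sec.voxels.shape[2]
        acc[:, :, z0:z1] += sec.voxels
        count[:, :, z0:z1] += 1
    voxels = np.full((nx, ny, nz), UNSAMPLED)
    sampled = count > 0
    voxels[sampled] = acc[sampled] / count[sampled]
    return JoinedVolume(voxels=voxels, sample_count=count)


def apply_brain_mask(volume: JoinedVolume, mask: np.ndarray) -> np.ndarray:
    """Flatten the joined volume to a vector over mask-true voxels.

    Column order is Fortran (x fastest, then y, then z), so the i-th entry
    of every subject's vector refers to the same common-grid coordinate.
    NaN (unsampled) values pass through for the cleaning stage to handle.
    """
    if mask.shape != volume.voxels.shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("empty brain mask")
    flat = volume.voxels.reshape(-1, order="F")
    mask_flat = mask.reshape(-1, order="F")
    return flat[mask_flat]


def mask_voxel_index(mask: np.ndarray) -> np.ndarray:
    """(n, 3) coordinates of mask-true voxels in the flattening order."""
    nx, ny, nz = mask.shape
    idx = np.flatnonzero(mask.reshape(-1, order="F"))
    x = idx % nx
    y = (idx // nx) % ny
    z = idx // (nx * ny)
    return np.column_stack([x, y, z]).astype(np.int32)


def clean_cohort(vectors: np.ndarray,
                 hu_low: float = 0.0,
                 hu_high: float = 200.0,
                 subject_threshold: int = 5,
                 voxel_index: np.ndarray | None = None) -> CohortVoxelMatrix:
    """Apply the cohort-level anomalous-voxel rule.

    A cell is anomalous iff its value is strictly below ``hu_low``, strictly
    above ``hu_high``, or unsampled (NaN).  Voxels anomalous in
    ``subject_threshold`` or more subjects are deleted outright; in retained
    voxels, anomalous cells are imputed with the mean over that voxel's
    non-anomalous subjects.  Non-sampled join voxels fall under the same
    rule, which is why the join region survives with imputed values when the
    join location varies across subjects.
    """
    vectors = np.asarray(vectors, dtype=float)
    n_subjects, n_voxels = vectors.shape
    if n_subjects < subject_threshold:
        raise ValueError(
            f"need at least {subject_threshold} subjects, got {n_subjects}")
    if voxel_index is None:
        voxel_index = np.column_stack(
            [np.arange(n_voxels), np.zeros(n_voxels), np.zeros(n_voxels)]
        ).astype(np.int32)

    with np.errstate(invalid="ignore"):
        anomalous = np.isnan(vectors) | (vectors < hu_low) | (vectors > hu_high)
    per_voxel = anomalous.sum(axis=0)
    delete = per_voxel >= subject_threshold
    keep = ~delete

    values = vectors[:, keep].copy()
    anom_kept = anomalous[:, keep]
    clean_counts = n_subjects - anom_kept.sum(axis=0)
    assert np.all(clean_counts > 0), "retained voxel with no clean subject"
    col_sums = np.where(anom_kept, 0.0, np.nan_to_num(values)).sum(axis=0)
    col_means = col_sums / clean_counts
    subj_rows, voxel_cols = np.nonzero(anom_kept)
    values[subj_rows, voxel_cols] = col_means[voxel_cols]

    return CohortVoxelMatrix(
        values=values,
        voxel_index=voxel_index[keep],
        deleted_voxels=voxel_index[delete],
        imputed_cells=list(zip(subj_rows.tolist(), voxel_cols.tolist())),
    )


def global_intensity_correct(matrix: CohortVoxelMatrix) -> CohortVoxelMatrix:
    """Scale each subject's vector so its mean equals the cohort grand mean
    (computed before correction).  Multiplicative scaling preserves HU
    ratios and non-negativity."""
    row_means = matrix.values.mean(axis=1)
    if np.any(row_means == 0):
        raise ValueError("subject with zero mean intensity cannot be scaled")
    grand = float(matrix.values.mean())
    values = matrix.values * (grand / row_means)[:, None]
    return CohortVoxelMatrix(
        values=values,
        voxel_index=matrix.voxel_index,
        deleted_voxels=matrix.deleted_voxels,
        imputed_cells=list(matrix.imputed_cells),
        grand_mean=grand,
    )


# ---------------------------------------------------------------------------
# rigid registration (simplified surrogate for template normalisation)

def _rigid_resample(voxels: np.ndarray, shift: np.ndarray, theta: float) -> np.ndarray:
    """Resample under a rigid transform: in-plane rotation ``theta`` (radians,
    about the z axis through the volume centre) followed by ``shift`` voxels.
    Trilinear interpolation; out-of-field voxels read 0 (air)."""
    nx, ny, nz = voxels.shape
    centre = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    # output coord -> input coord: undo shift, then undo rotation
    grid = np.indices((nx, ny, nz), dtype=float).reshape(3, -1)
    coords = rot.T @ (grid - centre[:, None] - np.asarray(shift, float)[:, None])
    coords += centre[:, None]
    out = ndimage.map_coordinates(voxels, coords, order=1, mode="constant", cval=0.0)
    return out.reshape(nx, ny, nz)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def normalize_section(section: CTSection, template: np.ndarray,
                      max_shift: float = 3.0, max_rot_deg: float = 4.0,
                      ncc_floor: float = 0.2,
                      return_transform: bool = False):
    """Rigidly align a jittered section to its template-space rendering.

    Searches 3 translations and 1 in-plane rotation by coarse-to-fine grid
    search maximising normalized cross-correlation, then resamples the
    section onto the common grid with the best inverse transform.  Raises
    :class:`RegistrationError` when even the best correlation stays below
    ``ncc_floor`` (e.g. structureless input).
    """
    if template.shape != section.voxels.shape:
        raise ValueError("template shape must match the section")

    def score(params: np.ndarray) -> float:
        tx, ty, tz, th = params
        moved = _rigid_resample(section.voxels, np.array([tx, ty, tz]), th)
        return _ncc(moved, template)

    best = np.zeros(4)
    best_score = score(best)
    steps = [(max_shift / 2.0, np.deg2rad(max_rot_deg / 2.0)),
             (max_shift / 4.0, np.deg2rad(max_rot_deg / 4.0)),
             (max_shift / 8.0, np.deg2rad(max_rot_deg / 8.0))]
    for t_step, r_step in steps:
        improved = True
        while improved:
            improved = False
            for axis in range(4):
                for sign in (-1.0, 1.0):
                    cand = best.copy()
                    cand[axis] += sign * (r_step if axis == 3 else t_step)
                    if axis < 3 and abs(cand[axis]) > max_shift:
                        continue
                    if axis == 3 and abs(cand[axis]) > np.deg2rad(max_rot_deg):
                        continue
                    sc = score(cand)
                    if sc > best_score + 1e-9:
                        best, best_score = cand, sc
                        improved = True
    if best_score < ncc_floor:
        raise RegistrationError(
            f"best correlation {best_score:.3f} below floor {ncc_floor}")
    aligned = _rigid_resample(section.voxels, best[:3], best[3])
    out = CTSection(voxels=aligned, spacing=section.spacing,
                    origin_offset=section.origin_offset,
                    section_kind=section.section_kind)
    if return_transform:
        return out, {"shift": best[:3].copy(), "rotation_rad": float(best[3]),
                     "ncc": best_score}
    return out


# ---------------------------------------------------------------------------
# I/O

def section_to_nifti(section: CTSection, path: str | Path) -> None:
    affine = np.diag(list(section.spacing) + [1.0])
    affine[2, 3] = section.origin_offset * section.spacing[2]
    img = nib.Nifti1Image(section.voxels.astype(np.float32), affine)
    nib.save(img, str(path))


def nifti_to_section(path: str | Path, section_kind: SectionKind) -> CTSection:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = int(round(float(img.affine[2, 3]) / spacing[2])) if spacing[2] else 0
    return CTSection(voxels=np.asarray(img.dataobj, dtype=float),
                     spacing=spacing, origin_offset=origin,
                     section_kind=section_kind)


def save_matrix(matrix: CohortVoxelMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "values.npy", matrix.values)
    sidecar = {
        "voxel_order": "x-fastest (Fortran), 0-based",
        "voxel_index": matrix.voxel_index.tolist(),
        "deleted_voxels": matrix.deleted_voxels.tolist(),
        "imputed_cells": [list(c) for c in matrix.imputed_cells],
        "grand_mean": matrix.grand_mean,
    }
    (directory / "sidecar.json").write_text(json.dumps(sidecar))


def load_matrix(directory: str | Path) -> CohortVoxelMatrix:
    directory = Path(directory)
    sidecar = json.loads((directory / "sidecar.json").read_text())
    return CohortVoxelMatrix(
        values=np.load(directory / "values.npy"),
        voxel_index=np.asarray(sidecar["voxel_index"], dtype=np.int32).reshape(-1, 3),
        deleted_voxels=np.asarray(sidecar["deleted_voxels"], dtype=np.int32).reshape(-1, 3),
        imputed_cells=[tuple(c) for c in sidecar["imputed_cells"]],
        grand_mean=sidecar["grand_mean"],
    )
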