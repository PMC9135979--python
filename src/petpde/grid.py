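"""Image containers, NIfTI I/O, resampling and slice-eligibility filtering.

The package works on co-registered 2D axial scalar fields: a pre-radiation
SUV image, a planned dose map and (for training/evaluation) a post-radiation
SUV image, all sharing one pixel grid with known in-plane spacing.

Coordinate convention: pixel-center anchored, row-major, 0-based indexing.
All physical distances are millimetres. The physical position of pixel
(i, j) is (i * spacing_row_mm, j * spacing_col_mm), so two grids over the
same anatomy share the origin at the center of pixel (0, 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import nibabel as nib
from scipy import ndimage
from skimage import measure


class Quantity(str, Enum):
    """Physical interpretation of a scalar field."""

    SUV = "SUV"
    DOSE_GY = "dose_Gy"
    DIMENSIONLESS = "dimensionless"


@dataclass(frozen=True)
class Grid2D:
    """A regular 2D pixel grid with physical in-plane spacing in mm."""

    n_rows: int
    n_cols: int
    spacing_row_mm: float = 1.0
    spacing_col_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError(
                f"grid must be at least 3x3, got {self.n_rows}x{self.n_cols}"
            )
        for s in (self.spacing_row_mm, self.spacing_col_mm):
            if not (np.isfinite(s) and s > 0):
                raise ValueError(f"pixel spacing must be positive and finite, got {s}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of pixel centers along rows and columns."""
        return (
            np.arange(self.n_rows) * self.spacing_row_mm,
            np.arange(self.n_cols) * self.spacing_col_mm,
        )


@dataclass
class ScalarField2D:
    """A 2D scalar image (SUV, dose or dimensionless) on a :class:`Grid2D`."""

    grid: Grid2D
    values: np.ndarray
    quantity: Quantity = Quantity.DIMENSIONLESS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite everywhere")
        if self.quantity in (Quantity.SUV, Quantity.DOSE_GY) and np.any(
            self.values < 0
        ):
            raise ValueError(f"{self.quantity.value} fields must be nonnegative")

    def with_values(self, values: np.ndarray) -> "ScalarField2D":
        return ScalarField2D(self.grid, values, self.quantity)


@dataclass
class PairedCase:
    """One training/evaluation sample: pre-radiation SUV, dose, optional post."""

    pre: ScalarField2D
    dose: ScalarField2D
    body_mask: np.ndarray
    case_id: str
    post: ScalarField2D | None = None
    #: noise-free simulated post image, known only for synthetic cases
    post_clean: ScalarField2D | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = [self.pre.grid, self.dose.grid]
        if self.post is not None:
            grids.append(self.post.grid)
        if self.post_clean is not None:
            grids.append(self.post_clean.grid)
        if any(g != grids[0] for g in grids[1:]):
            raise ValueError("all fields of a case must share one grid")
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        if self.body_mask.shape != self.pre.grid.shape:
            raise ValueError("body_mask shape does not match the grid")
        if not self.body_mask.any():
            raise ValueError("body_mask must contain at least one pixel")


# ---------------------------------------------------------------------------
# NIfTI volume I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, quantity: Quantity = Quantity.SUV) -> list[ScalarField2D]:
    """Read a 3D NIfTI volume as a list of axial slices, superior to inferior.

    The slice axis is the third voxel axis. Slices are ordered superior to
    inferior: if the affine maps increasing slice index to increasing physical
    z (superior), the index order is reversed so the first returned slice is
    the most superior one.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read {path} as a NIfTI volume: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D with shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    grid = Grid2D(data.shape[0], data.shape[1], float(zooms[0]), float(zooms[1]))
    k_order = range(data.shape[2])
    if img.affine[2, 2] > 0:  # k increases toward superior -> reverse
        k_order = reversed(list(k_order))
    return [ScalarField2D(grid, data[:, :, k], quantity) for k in k_order]


def write_volume(path: str | Path, slices: Sequence[ScalarField2D]) -> None:
    """Write axial slices to a NIfTI volume (inverse of :func:`read_volume`)."""
    if not slices:
        raise ValueError("no slices to write")
    grid = slices[0].grid
    if any(s.grid != grid for s in slices):
        raise ValueError("all slices must share one grid")
    data = np.stack([s.values for s in slices], axis=2)
    affine = np.diag([grid.spacing_row_mm, grid.spacing_col_mm, -1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_field(path: str | Path, f: ScalarField2D) -> None:
    """Write one 2D field as a single-slice NIfTI."""
    write_volume(path, [f])


def read_field(path: str | Path, quantity: Quantity = Quantity.SUV) -> ScalarField2D:
    """Read the first slice of a NIfTI file as a 2D field."""
    return read_volume(path, quantity)[0]


def save_case(case: PairedCase, out_dir: str | Path) -> None:
    """Serialize a case as one NIfTI per field plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_field(out / "pre.nii.gz", case.pre)
    write_field(out / "dose.nii.gz", case.dose)
    if case.post is not None:
        write_field(out / "post.nii.gz", case.post)
    if case.post_clean is not None:
        write_field(out / "post_clean.nii.gz", case.post_clean)
    write_field(
        out / "body_mask.nii.gz",
        ScalarField2D(case.pre.grid, case.body_mask.astype(float), Quantity.DIMENSIONLESS),
    )
    sidecar = {"case_id": case.case_id, "ground_truth": case.ground_truth}
    (out / "case.json").write_text(json.dumps(sidecar, indent=2))


def load_case(case_dir: str | Path) -> PairedCase:
    """Load a case written by :func:`save_case`."""
    d = Path(case_dir)
    sidecar = json.loads((d / "case.json").read_text())
    pre = read_field(d / "pre.nii.gz", Quantity.SUV)
    dose = read_field(d / "dose.nii.gz", Quantity.DOSE_GY)
    body = read_field(d / "body_mask.nii.gz", Quantity.DIMENSIONLESS).values > 0.5
    post_path = d / "post.nii.gz"
    post = read_field(post_path, Quantity.SUV) if post_path.exists() else None
    clean_path = d / "post_clean.nii.gz"
    post_clean = read_field(clean_path, Quantity.SUV) if clean_path.exists() else None
    return PairedCase(
        pre=pre,
        dose=dose,
        post=post,
        post_clean=post_clean,
        body_mask=body,
        case_id=sidecar["case_id"],
        ground_truth=sidecar.get("ground_truth", {}),
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_bilinear(f: ScalarField2D, target: Grid2D) -> ScalarField2D:
    """Bilinearly resample a field onto a target grid.

    Both grids are anchored at the same physical origin with pixel-center
    convention. Queries outside the source extent clamp to the nearest edge
    value, which avoids spurious gradients at the field border.
    """
    rows_mm = np.arange(target.n_rows) * target.spacing_row_mm
    cols_mm = np.arange(target.n_cols) * target.spacing_col_mm
    # convert physical mm to fractional source pixel indices
    ri = rows_mm / f.grid.spacing_row_mm
    ci = cols_mm / f.grid.spacing_col_mm
    rr, cc = np.meshgrid(ri, ci, indexing="ij")
    out = ndimage.map_coordinates(
        f.values, [rr, cc], order=1, mode="nearest", prefilter=False
    )
    return ScalarField2D(target, out, f.quantity)


# ---------------------------------------------------------------------------
# Slice eligibility and body mask
# ---------------------------------------------------------------------------

def select_eligible_slices(
    slices: Sequence[ScalarField2D],
    suv_max_threshold: float = 1.5,
    exclusion_masks: Sequence[np.ndarray] | None = None,
) -> list[int]:
    """Indices of slices whose SUVmax (outside an exclusion mask) exceeds a threshold.

    The comparison is a strict inequality: a slice whose maximum equals the
    threshold exactly is excluded. The optional per-slice exclusion masks mark
    regions (e.g. brain) whose uptake must not count toward eligibility.
    """
    if suv_max_threshold < 0:
        raise ValueError("threshold must be nonnegative")
    keep = []
    for i, s in enumerate(slices):
        vals = s.values
        if exclusion_masks is not None:
            mask = np.asarray(exclusion_masks[i], dtype=bool)
            if mask.shape != vals.shape:
                raise ValueError(
                    f"exclusion mask {i} has shape {mask.shape}, slice is {vals.shape}"
                )
            vals = vals[~mask]
            if vals.size == 0:
                continue
        if vals.max() > suv_max_threshold:
            keep.append(i)
    return keep


def extract_body_mask(
    f: ScalarField2D, threshold: float = 0.1, min_component_px: int = 1
) -> np.ndarray:
    """Threshold, keep the largest 4-connected component, fill interior holes."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    fg = f.values >= threshold
    if not fg.any():
        raise ValueError("no pixel at or above the body threshold")
    labels = measure.label(fg, connectivity=1)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    if sizes[largest] < min_component_px:
        raise ValueError(
            f"largest component has {sizes[largest]} px < min_component_px={min_component_px}"
        )
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)
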