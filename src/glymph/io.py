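"""Volumetric image and gradient-table I/O.

All images are carried as :class:`Volume` objects: an N-D scalar grid
(3-D, or 4-D with the frame axis last) together with a voxel-to-world
affine in millimetres.  On load every volume is reoriented to canonical
RAS axes so that the image axes mean x = left-right, y =
anterior-posterior, z = inferior-superior.  That convention is load-bearing:
the perivascular-space (ALPS) analysis is defined on diffusivities along
these fixed anatomical axes, not along eigenvectors.

Gradient tables use the FSL dialect: a ``.bval`` file with one row of
b-values (s/mm^2) and a ``.bvec`` file with three rows (x, y, z components),
one column per diffusion frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "GradientTable",
    "RoiMask",
    "read_volume",
    "write_volume",
    "read_gradient_table",
    "write_gradient_table",
    "resolve_roi",
    "roi_mask_from_spec",
    "read_roi_spec",
]

#: frames whose b-value is within this of a shell centre belong to that shell
#: (scanner-reported b-values jitter around the nominal value), in s/mm^2
SHELL_TOLERANCE = 50.0

_UNIT_NORM_TOL = 1e-4


@dataclass
class Volume:
    """An image grid with voxel spacing, world affine and a unit label.

    Parameters
    ----------
    data : ndarray
        3-D scalar grid, or 4-D with the frame axis last.
    affine : (4, 4) ndarray
        Voxel-index -> world-mm map.  Must be invertible.
    units : str
        Free-text physical unit of the voxel values, e.g. ``"mm^2/s"``,
        ``"kBq/mL"`` or ``"unitless"``.
    allow_nan : bool
        Permit NaN voxels (used for maps carrying an invalid-voxel mask).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units: str = "unitless"
    allow_nan: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3-D or 4-D data, got ndim={self.data.ndim}")
        if min(self.data.shape[:3]) < 1:
            raise ValueError(f"degenerate spatial shape {self.data.shape[:3]}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise ValueError(f"non-positive voxel spacing {self.spacing}")
        if not self.allow_nan and np.isnan(self.data).any():
            raise ValueError("volume contains NaN (pass allow_nan=True to permit)")

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel along each spatial axis (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        """Number of frames (1 for a 3-D volume)."""
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    def frame(self, i: int) -> np.ndarray:
        if self.data.ndim == 3:
            if i != 0:
                raise IndexError("3-D volume has a single frame")
            return self.data
        return self.data[..., i]

    def with_data(self, data: np.ndarray, units: str | None = None,
                  allow_nan: bool | None = None) -> "Volume":
        """A new Volume on the same grid with different voxel values."""
        return Volume(
            np.asarray(data),
            self.affine.copy(),
            self.units if units is None else units,
            self.allow_nan if allow_nan is None else allow_nan,
        )


@dataclass
class GradientTable:
    """Per-frame diffusion weightings and unit directions.

    ``bvals`` are in s/mm^2; ``bvecs`` holds one unit 3-vector per frame
    (the zero vector is allowed, and expected, where b = 0).
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} does not match "
                f"{self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(self.bvecs, axis=1)
        weighted = self.bvals > 0
        bad = weighted & (np.abs(norms - 1.0) > _UNIT_NORM_TOL)
        if bad.any():
            raise ValueError(
                f"non-unit direction for weighted frame(s) {np.nonzero(bad)[0].tolist()}"
            )

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= SHELL_TOLERANCE

    def shell_centers(self, tol: float = SHELL_TOLERANCE) -> list[float]:
        """Nominal nonzero b-values present, clustered within ``tol``."""
        centers: list[float] = []
        for b in sorted(self.bvals[~self.b0_mask]):
            if not centers or b - centers[-1] > tol:
                centers.append(float(b))
        return centers

    def shell_mask(self, center: float, tol: float = SHELL_TOLERANCE) -> np.ndarray:
        return (~self.b0_mask) & (np.abs(self.bvals - center) <= tol)


@dataclass
class RoiMask:
    """Integer label volume plus a legend mapping ROI names to labels."""

    labels: np.ndarray
    legend: dict[str, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")

    @property
    def names(self) -> list[str]:
        return list(self.legend)

    def boolean(self, name: str) -> np.ndarray:
        if name not in self.legend:
            raise KeyError(f"unknown ROI {name!r}; known: {sorted(self.legend)}")
        return self.labels == self.legend[name]


def resolve_roi(mask: RoiMask, name: str) -> np.ndarray:
    """Voxel indices of a named ROI as an (n, 3) int array.

    Raises ``KeyError`` for an unknown name and ``ValueError`` for an
    empty ROI.
    """
    m = mask.boolean(name)
    idx = np.argwhere(m)
    if idx.size == 0:
        raise ValueError(f"ROI {name!r} is empty")
    return idx


# ---------------------------------------------------------------------------
# NIfTI

def read_volume(path: str | Path, units: str = "unitless",
                allow_nan: bool = False) -> Volume:
    """Load a NIfTI-1 volume, reorienting to canonical RAS axes.

    The frame axis of 4-D files stays last (NIfTI stores it last already).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return Volume(data, np.asarray(img.affine, dtype=float), units=units,
                  allow_nan=allow_nan)


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a Volume as NIfTI-1, float64, no scaling (bit-exact round trip)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_data_dtype(np.float64)
    # disable scl_slope/scl_inter so the stored payload is the raw data
    img.header["scl_slope"] = 1.0
    img.header["scl_inter"] = 0.0
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, legend: dict[str, int]) -> RoiMask:
    """Load an integer label volume and attach a legend."""
    vol = read_volume(path)
    labels = np.rint(vol.data).astype(np.int32)
    return RoiMask(labels, dict(legend), vol.affine)


def write_mask(mask: RoiMask, path: str | Path,
               legend_path: str | Path | None = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.labels.astype(np.int16), mask.affine)
    nib.save(img, str(path))
    if legend_path is not None:
        Path(legend_path).write_text(json.dumps(mask.legend, indent=2))
    return path


# ---------------------------------------------------------------------------
# FSL gradient tables

def _read_numeric_rows(path: Path) -> np.ndarray:
    rows = []
    for line in path.read_text().splitlines():
        if line.strip():
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ValueError(f"non-numeric token in {path}: {exc}") from exc
    return np.asarray(rows, dtype=float)


def read_gradient_table(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read FSL-style .bval/.bvec files.

    The .bvec file must have 3 rows and one column per frame.  Directions
    of weighted frames are renormalised to unit length; a zero direction
    on a weighted frame is an error.
    """
    bvals = _read_numeric_rows(Path(bval_path))
    if bvals.shape[0] != 1:
        bvals = bvals.reshape(-1)
    else:
        bvals = bvals[0]
    bvecs = _read_numeric_rows(Path(bvec_path))
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"bvec has {bvecs.shape[1]} frames but bval has {bvals.size}"
        )
    vecs = bvecs.T.copy()
    norms = np.linalg.norm(vecs, axis=1)
    weighted = bvals > SHELL_TOLERANCE
    if np.any(weighted & (norms < _UNIT_NORM_TOL)):
        raise ValueError("zero direction vector on a diffusion-weighted frame")
    nz = norms > 0
    vecs[nz] /= norms[nz, None]
    return GradientTable(bvals, vecs)


def write_gradient_table(table: GradientTable, bval_path: str | Path,
                         bvec_path: str | Path) -> None:
    Path(bval_path).write_text(" ".join(f"{b:.6g}" for b in table.bvals) + "\n")
    lines = [" ".join(f"{v:.17g}" for v in table.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON ROI specs (centre + spherical radius, in voxel coordinates / mm)

def roi_mask_from_spec(spec: list[dict], reference: Volume) -> RoiMask:
    """Build a label volume from JSON-style sphere specs.

    Each entry: ``{"name": str, "center_vox": [i, j, k], "radius_mm": float}``.
    Spheres are rasterised on the reference grid using its voxel spacing;
    later entries overwrite earlier ones where they overlap.
    """
    shape = reference.data.shape[:3]
    labels = np.zeros(shape, dtype=np.int32)
    legend: dict[str, int] = {}
    spacing = reference.spacing
    grid = np.indices(shape).astype(float)
    for n, entry in enumerate(spec, start=1):
        name = entry["name"]
        center = np.asarray(entry["center_vox"], dtype=float)
        radius = float(entry["radius_mm"])
        d2 = sum(((grid[a] - center[a]) * spacing[a]) ** 2 for a in range(3))
        sphere = d2 <= radius**2
        if not sphere.any():
            raise ValueError(f"ROI {name!r} rasterises to zero voxels")
        labels[sphere] = n
        legend[name] = n
    mask = RoiMask(labels, legend, reference.affine.copy())
    for name in legend:
        if not mask.boolean(name).any():
            raise ValueError(f"ROI {name!r} fully overwritten by later spheres")
    return mask


def read_roi_spec(path: str | Path, reference: Volume) -> RoiMask:
    return roi_mask_from_spec(json.loads(Path(path).read_text()), reference)
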