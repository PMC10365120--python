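"""Core I/O and the shared coordinate-system contract.

Conventions used throughout the package:

* world coordinates are RAS+ millimeters;
* voxel indices are 0-based, with the voxel *center* at the integer index;
* the ``affine`` of a dataset maps homogeneous voxel indices to world mm.

Formats: NIfTI-1 via :mod:`nibabel`, FSL-style whitespace ``.bval``/``.bvec``
text, TrackVis ``.trk`` via :mod:`nibabel.streamlines`, and a long-format CSV
schema for tract profiles.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from ._errors import (
    DataError,
    FrameCountMismatchError,
    ProfileSchemaError,
    SingularAffineError,
    TrkParseError,
)

PROFILE_COLUMNS = [
    "subject_id", "group", "tract", "hemisphere", "node", "fa", "md", "ad", "rd",
]

DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2; tolerates nonzero nominal b0 frames


@dataclass
class GradientTable:
    """Diffusion sensitization scheme: b-values plus unit direction vectors.

    Parameters
    ----------
    bvals : (n,) array
        b-values in s/mm^2, one per frame.
    bvecs : (n, 3) array
        Direction cosines. Vectors of diffusion-weighted frames are
        re-normalized to unit length on construction; b=0 frames may carry a
        zero vector.
    b0_threshold : float
        Frames with ``bval <= b0_threshold`` count as b=0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise DataError(f"bvecs must be (n, 3); got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise FrameCountMismatchError(
                f"{len(self.bvals)} b-values but {len(self.bvecs)} b-vectors"
            )
        dw = ~self.b0_mask
        norms = np.linalg.norm(self.bvecs, axis=1)
        if np.any(norms[dw] == 0):
            raise DataError("zero direction vector on a diffusion-weighted frame")
        self.bvecs = self.bvecs.copy()
        self.bvecs[dw] /= norms[dw, None]
        if not dw.any():
            raise DataError("gradient table has no diffusion-weighted frame")
        if dw.all():
            raise DataError("gradient table has no b=0 frame")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    def __len__(self) -> int:
        return len(self.bvals)


@dataclass
class DwiDataset:
    """A 4-D diffusion-weighted volume with its gradient table and geometry."""

    signal: np.ndarray
    affine: np.ndarray
    gtab: GradientTable
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise DataError(f"DWI signal must be 4-D; got {self.signal.ndim}-D")
        if self.signal.shape[3] != len(self.gtab):
            raise FrameCountMismatchError(
                f"image has {self.signal.shape[3]} frames but gradient table "
                f"has {len(self.gtab)}"
            )
        _check_invertible(self.affine)
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.signal.shape[:3]:
                raise DataError("mask shape does not match the spatial grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class Tractogram:
    """A list of streamlines (world-mm polylines) tied to a reference grid."""

    streamlines: list[np.ndarray]
    reference_affine: np.ndarray
    reference_shape: tuple[int, int, int]

    def __post_init__(self):
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        self.reference_affine = np.asarray(self.reference_affine, dtype=float)
        self.reference_shape = tuple(int(d) for d in self.reference_shape)
        for s in self.streamlines:
            validate_streamline(s)

    def __len__(self) -> int:
        return len(self.streamlines)


def validate_streamline(points: np.ndarray) -> None:
    """Check the streamline contract: >=2 finite 3-D points, no repeats."""
    points = np.asarray(points)
    if points.ndim != 2 or points.shape[1] != 3:
        raise DataError(f"streamline must be (n, 3); got {points.shape}")
    if len(points) < 2:
        raise DataError("streamline needs at least 2 points")
    if not np.all(np.isfinite(points)):
        raise DataError("streamline has non-finite coordinates")
    if np.any(np.all(points[1:] == points[:-1], axis=1)):
        raise DataError("streamline has consecutive duplicate points")


def _check_invertible(affine: np.ndarray) -> None:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
        raise SingularAffineError("affine is singular or not 4x4")


def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 affine to an (n, 3) (or (3,)) array of points."""
    _check_invertible(affine)
    points = np.asarray(points, dtype=float)
    return points @ affine[:3, :3].T + affine[:3, 3]


def inverse_affine(affine: np.ndarray) -> np.ndarray:
    _check_invertible(affine)
    return np.linalg.inv(affine)


def _read_fsl_gradient_file(path: str | os.PathLike, n_cols: int) -> np.ndarray:
    """Read an FSL-layout text file, auto-detecting row- vs column-major."""
    arr = np.atleast_2d(np.loadtxt(path, dtype=float))
    if arr.shape[0] == n_cols and arr.shape[1] != n_cols:
        return arr.T
    if arr.shape[1] == n_cols:
        return arr
    # square or ambiguous: FSL convention is one row per coordinate
    return arr.T if arr.shape[0] == n_cols else arr


def load_dwi(
    image_path: str | os.PathLike,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
    mask_path: str | os.PathLike | None = None,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> DwiDataset:
    """Load a 4-D NIfTI plus FSL ``.bval``/``.bvec`` into a :class:`DwiDataset`.

    The bval/bvec layout (one row per coordinate or one column per frame) is
    auto-detected from the array shape. Frame-count disagreement between the
    image and either gradient file is fatal.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DataError(f"expected a 4-D NIfTI; got {data.ndim}-D")
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = _read_fsl_gradient_file(bvec_path, 3)
    if len(bvals) != data.shape[3] or len(bvecs) != data.shape[3]:
        raise FrameCountMismatchError(
            f"image has {data.shape[3]} frames; bval has {len(bvals)}, "
            f"bvec has {len(bvecs)}"
        )
    gtab = GradientTable(bvals, bvecs, b0_threshold=b0_threshold)
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return DwiDataset(signal=data, affine=img.affine, gtab=gtab, mask=mask)


def save_dwi(dwi: DwiDataset, image_path, bval_path, bvec_path) -> None:
    """Write a DwiDataset back to NIfTI + FSL bval/bvec (row-per-coordinate)."""
    nib.save(nib.Nifti1Image(dwi.signal.astype(np.float32), dwi.affine),
             str(image_path))
    np.savetxt(bval_path, dwi.gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, dwi.gtab.bvecs.T, fmt="%.8f")


def save_nifti(volume: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_tractogram(tractogram: Tractogram, path) -> None:
    """Write a TrackVis .trk with header geometry from the reference grid."""
    _check_invertible(tractogram.reference_affine)
    affine = tractogram.reference_affine
    voxel_sizes = np.linalg.norm(affine[:3, :3], axis=0)
    header = {
        "voxel_to_rasmm": affine.astype(np.float32),
        "voxel_sizes": voxel_sizes.astype(np.float32),
        "dimensions": np.asarray(tractogram.reference_shape, dtype=np.int16),
        "voxel_order": "".join(nib.aff2axcodes(affine)),
    }
    sl = [s.astype(np.float32) for s in tractogram.streamlines]
    nib_tg = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(nib_tg, str(path), header=header)


def load_tractogram(path) -> Tractogram:
    """Read a TrackVis .trk back into world-mm streamlines."""
    try:
        trk = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises HeaderError/DataError variants
        raise TrkParseError(f"cannot parse {path}: {exc}") from exc
    header = trk.header
    affine = np.asarray(header["voxel_to_rasmm"], dtype=float)
    shape = tuple(int(d) for d in header["dimensions"])
    streamlines = [np.asarray(s, dtype=float) for s in trk.streamlines]
    return Tractogram(streamlines=streamlines, reference_affine=affine,
                      reference_shape=shape)


def save_profiles(profiles: pd.DataFrame, path) -> None:
    """Write tract profiles as long-format CSV (full float precision)."""
    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise ProfileSchemaError(f"profile table missing columns: {missing}")
    profiles[PROFILE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def load_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileSchemaError(f"profile CSV missing columns: {missing}")
    return df
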