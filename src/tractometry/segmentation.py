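"""Virtual dissection of the superior longitudinal fasciculus (SLF).

Streamlines become members of a named bundle when they intersect both ROIs
of a waypoint pair. The SLF II / SLF III sub-branches share a posterior ROI
on the posterior-commissure coronal plane (MNI y = -25 mm) and are separated
by distinct anterior ROIs on the anterior-commissure plane (MNI y = 2 mm):
SLF II dorsal, SLF III ventral. The whole SLF uses the union of the two
anterior boxes as its anterior waypoint.

The in-plane box extents shipped as defaults are configurable placeholders,
not anatomically validated boundaries; phantom scenes define their own ROIs
in phantom space.

Bundles are then scored against a fiber probability map (mean interpolated
probability along each streamline), cleaned by discarding the lowest-scored
streamlines and length outliers, and a lesion mask can be screened against
the probability map (a lesion touching fiber probability > 0.5 marks the
tract as affected).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._errors import DataError, EmptyBundleError
from .io import Tractogram, apply_affine, inverse_affine


@dataclass(frozen=True)
class PlaneSpec:
    """A coronal-plane box: world y position, in-plane bounds, thickness."""

    y_mm: float
    x_range: tuple[float, float]
    z_range: tuple[float, float]
    thickness_mm: float = 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (
            (np.abs(p[:, 1] - self.y_mm) <= self.thickness_mm / 2)
            & (p[:, 0] >= self.x_range[0]) & (p[:, 0] <= self.x_range[1])
            & (p[:, 2] >= self.z_range[0]) & (p[:, 2] <= self.z_range[1])
        )

    def union(self, other: "PlaneSpec") -> "PlaneSpec":
        if abs(self.y_mm - other.y_mm) > 1e-9:
            raise DataError("cannot union plane ROIs on different planes")
        return PlaneSpec(
            y_mm=self.y_mm,
            x_range=(min(self.x_range[0], other.x_range[0]),
                     max(self.x_range[1], other.x_range[1])),
            z_range=(min(self.z_range[0], other.z_range[0]),
                     max(self.z_range[1], other.z_range[1])),
            thickness_mm=max(self.thickness_mm, other.thickness_mm),
        )


@dataclass
class WaypointRoi:
    """A waypoint region: either an analytic coronal-plane box or a mask.

    Mask geometry carries its own ``affine`` (voxel -> world mm);
    plane geometry is defined directly in world mm.
    """

    name: str
    space: str  # "MNI" | "native" | "phantom"
    plane: PlaneSpec | None = None
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        if (self.plane is None) == (self.mask is None):
            raise DataError("WaypointRoi needs exactly one of plane or mask")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if not self.mask.any():
                raise DataError(f"ROI {self.name!r} mask is empty")
            if self.affine is None:
                raise DataError("mask ROI requires an affine")

    def contains(self, points_world: np.ndarray) -> np.ndarray:
        """Boolean membership for an (n, 3) array of world-mm points."""
        if self.plane is not None:
            return self.plane.contains(points_world)
        vox = np.rint(apply_affine(inverse_affine(self.affine),
                                   points_world)).astype(int)
        shape = np.asarray(self.mask.shape)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        out = np.zeros(len(points_world), dtype=bool)
        v = vox[inside]
        out[inside] = self.mask[v[:, 0], v[:, 1], v[:, 2]]
        return out

    def to_mask(self, affine: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
        """Rasterize onto a reference grid (voxel-center membership)."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        centers = apply_affine(
            affine, np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]))
        return self.contains(centers).reshape(shape)


# Default MNI-space extents for the SLF waypoint boxes. The y coordinates of
# the two coronal planes are the anatomy (anterior / posterior commissure);
# the in-plane boxes are documented, configurable defaults only.
DEFAULT_SLF_ROI_CONFIG = {
    "anterior_y_mm": 2.0,
    "posterior_y_mm": -25.0,
    "thickness_mm": 2.0,
    "x_lateral_range": (15.0, 50.0),  # |x|: lateral band covering the SLF
    "slf2_z_range": (18.0, 45.0),  # dorsal box -> SLF II
    "slf3_z_range": (-4.0, 18.0),  # ventral box -> SLF III
    "posterior_z_range": (-4.0, 45.0),
}


def define_slf_rois(config: dict | None = None,
                    space: str = "MNI") -> dict[str, WaypointRoi]:
    """The six SLF waypoint ROIs (three per hemisphere) as plane boxes.

    Returns a dict keyed ``"{hemi}_SLF_II_anterior"``,
    ``"{hemi}_SLF_III_anterior"``, ``"{hemi}_posterior"`` for hemi in L, R.
    Left/right boxes are mirror images in the midsagittal plane.
    """
    cfg = dict(DEFAULT_SLF_ROI_CONFIG)
    if config:
        cfg.update(config)
    x_lo, x_hi = cfg["x_lateral_range"]
    rois: dict[str, WaypointRoi] = {}
    for hemi, sgn in (("L", -1.0), ("R", 1.0)):
        x_range = tuple(sorted((sgn * x_lo, sgn * x_hi)))
        rois[f"{hemi}_SLF_II_anterior"] = WaypointRoi(
            name=f"{hemi}_SLF_II_anterior", space=space,
            plane=PlaneSpec(cfg["anterior_y_mm"], x_range,
                            tuple(cfg["slf2_z_range"]), cfg["thickness_mm"]))
        rois[f"{hemi}_SLF_III_anterior"] = WaypointRoi(
            name=f"{hemi}_SLF_III_anterior", space=space,
            plane=PlaneSpec(cfg["anterior_y_mm"], x_range,
                            tuple(cfg["slf3_z_range"]), cfg["thickness_mm"]))
        rois[f"{hemi}_posterior"] = WaypointRoi(
            name=f"{hemi}_posterior", space=space,
            plane=PlaneSpec(cfg["posterior_y_mm"], x_range,
                            tuple(cfg["posterior_z_range"]), cfg["thickness_mm"]))
    return rois


def merged_anterior_roi(roi_ii: WaypointRoi, roi_iii: WaypointRoi,
                        name: str = "SLF_anterior") -> WaypointRoi:
    """Union of the SLF II and III anterior boxes: the whole-SLF waypoint."""
    if roi_ii.plane is None or roi_iii.plane is None:
        raise DataError("merged anterior ROI requires plane geometry")
    return WaypointRoi(name=name, space=roi_ii.space,
                       plane=roi_ii.plane.union(roi_iii.plane))


def transform_rois(rois: dict[str, WaypointRoi] | list[WaypointRoi],
                   affine: np.ndarray,
                   target_space: str = "native"):
    """Map ROIs through a voxel-preserving affine into a target space.

    Plane specs transform analytically when the affine keeps coronal planes
    coronal (no shear/rotation mixing y with x/z); otherwise the plane is
    first rasterized implicitly through its ``contains`` test by wrapping it
    in a transformed-mask check. Mask ROIs are resampled nearest-neighbor by
    composing the affine into their voxel->world transform.
    """
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise DataError("ROI transform affine is singular")

    def _one(roi: WaypointRoi) -> WaypointRoi:
        if roi.mask is not None:
            return replace(roi, space=target_space, affine=affine @ roi.affine)
        A, t = affine[:3, :3], affine[:3, 3]
        axis_aligned = (np.allclose(A[1, [0, 2]], 0) and np.allclose(A[[0, 2], 1], 0)
                        and A[1, 1] > 0 and A[0, 0] != 0 and A[2, 2] != 0)
        if not axis_aligned:
            raise DataError(
                f"affine mixes the coronal axis; rasterize ROI {roi.name!r} "
                "to a mask before transforming")
        p = roi.plane
        xs = sorted(A[0, 0] * np.asarray(p.x_range) + t[0])
        zs = sorted(A[2, 2] * np.asarray(p.z_range) + t[2])
        new_plane = PlaneSpec(
            y_mm=A[1, 1] * p.y_mm + t[1],
            x_range=(xs[0], xs[1]), z_range=(zs[0], zs[1]),
            thickness_mm=A[1, 1] * p.thickness_mm)
        return replace(roi, space=target_space, plane=new_plane)

    if isinstance(rois, dict):
        return {k: _one(r) for k, r in rois.items()}
    return [_one(r) for r in rois]


def streamline_lengths(streamlines: list[np.ndarray]) -> np.ndarray:
    return np.array([np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
                     for s in streamlines])


@dataclass
class TractBundle:
    """Streamlines of one named tract, as indices into a tractogram."""

    name: str
    hemisphere: str
    tractogram: Tractogram
    indices: np.ndarray
    scores: np.ndarray | None = None
    lengths: np.ndarray = field(default=None)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.lengths is None:
            self.lengths = streamline_lengths(list(self.streamlines))

    @property
    def streamlines(self) -> list[np.ndarray]:
        return [self.tractogram.streamlines[i] for i in self.indices]

    def __len__(self) -> int:
        return len(self.indices)


def assign_by_waypoints(tractogram: Tractogram, roi_a: WaypointRoi,
                        roi_b: WaypointRoi, name: str = "",
                        hemisphere: str = "") -> TractBundle:
    """Bundle = streamlines with at least one point in each of the two ROIs."""
    members = []
    for i, s in enumerate(tractogram.streamlines):
        if roi_a.contains(s).any() and roi_b.contains(s).any():
            members.append(i)
    if not members:
        warnings.warn(f"waypoint pair ({roi_a.name}, {roi_b.name}) matched "
                      "no streamlines", stacklevel=2)
    return TractBundle(name=name or f"{roi_a.name}&{roi_b.name}",
                       hemisphere=hemisphere, tractogram=tractogram,
                       indices=np.asarray(members, dtype=int))


def score_against_probability_map(bundle: TractBundle, prob_map: np.ndarray,
                                  affine: np.ndarray) -> np.ndarray:
    """Per-streamline mean of trilinearly interpolated map probabilities."""
    prob_map = np.asarray(prob_map, dtype=float)
    if np.nanmin(prob_map) < 0 or np.nanmax(prob_map) > 1:
        raise DataError("probability map values must lie in [0, 1]")
    inv = inverse_affine(affine)
    scores = np.empty(len(bundle))
    for k, s in enumerate(bundle.streamlines):
        vox = apply_affine(inv, s)
        vals = ndimage.map_coordinates(prob_map, vox.T, order=1, mode="constant")
        scores[k] = vals.mean()
    return scores


def clean_bundle(bundle: TractBundle, scores: np.ndarray | None = None,
                 score_quantile: float = 0.05,
                 length_z_max: float = 3.0,
                 max_rounds: int = 5) -> TractBundle:
    """Discard low-probability streamlines and length outliers.

    Streamlines scoring below the ``score_quantile`` quantile of the bundle's
    probability scores are dropped, then streamlines whose length z-score
    exceeds ``length_z_max`` in absolute value are pruned iteratively (the
    z-scores are recomputed each round) until a fixpoint or ``max_rounds``.
    """
    if len(bundle) == 0:
        raise EmptyBundleError("cannot clean an empty bundle")
    keep = np.ones(len(bundle), dtype=bool)
    if scores is not None and score_quantile > 0:
        cutoff = np.quantile(np.asarray(scores, dtype=float), score_quantile)
        keep &= np.asarray(scores) >= cutoff
    lengths = bundle.lengths.copy()
    for _ in range(max_rounds):
        if keep.sum() < 2 or not np.isfinite(length_z_max):
            break
        mu, sd = lengths[keep].mean(), lengths[keep].std(ddof=0)
        if sd == 0:
            break
        z = np.abs(lengths - mu) / sd
        new_keep = keep & (z <= length_z_max)
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
    if not keep.any():
        warnings.warn(f"cleaning emptied bundle {bundle.name!r}", stacklevel=2)
    return TractBundle(
        name=bundle.name, hemisphere=bundle.hemisphere,
        tractogram=bundle.tractogram, indices=bundle.indices[keep],
        scores=None if scores is None else np.asarray(scores)[keep],
        lengths=bundle.lengths[keep])


def lesion_overlap_screen(lesion_mask: np.ndarray, fiber_prob_map: np.ndarray,
                          threshold: float = 0.5,
                          mode: str = "any") -> str:
    """Decide whether a lesion affects a tract from its probability map.

    ``mode="any"`` (default): affected iff any lesion voxel has fiber
    probability strictly above ``threshold``. ``mode="majority"``: affected
    iff more than half the lesion voxels exceed it.
    """
    lesion = np.asarray(lesion_mask).astype(bool)
    prob = np.asarray(fiber_prob_map, dtype=float)
    if lesion.shape != prob.shape:
        raise DataError("lesion mask and probability map shapes differ")
    if not lesion.any():
        warnings.warn("empty lesion mask; reporting not_affected", stacklevel=2)
        return "not_affected"
    over = prob[lesion] > threshold
    if mode == "any":
        hit = over.any()
    elif mode == "majority":
        hit = over.mean() > 0.5
    else:
        raise ValueError(f"unknown lesion screen mode {mode!r}")
    return "affected" if hit else "not_affected"
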