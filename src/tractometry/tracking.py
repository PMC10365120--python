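"""Deterministic whole-brain streamline tracking (FACT).

Fiber Assignment by Continuous Tracking follows, at each step, the principal
eigenvector of the voxel the tracker is currently in (nearest-voxel lookup,
no interpolation), sign-aligned with the previous step direction. Tracking
runs bidirectionally from every seed: the two half-tracks started along +e1
and -e1 of the seed voxel are concatenated.

A half-track terminates when

* the next position falls in a voxel with FA below ``fa_stop`` (the stopping
  point is not appended, so every emitted point lies in a voxel at or above
  the threshold),
* the turning angle between consecutive step directions exceeds
  ``max_angle_deg``,
* the next position leaves the image grid, or
* the streamline would exceed ``max_len_mm``.

Streamlines shorter than ``min_len_mm`` are discarded. Everything is
deterministic given the parameters (jittered seeding draws from a generator
seeded with ``rng_seed``).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._errors import EmptySeedError
from .io import Tractogram, apply_affine, inverse_affine
from .tensor import DiffusionTensorFit, ScalarMaps


@dataclass(frozen=True)
class TrackingParams:
    """Knobs of the deterministic tracker.

    ``step_mm=None`` resolves to half the smallest voxel dimension, so the
    default acquisition geometry (1.5 mm isotropic) steps 0.75 mm: sub-voxel
    stepping keeps the 30-degree angle rule meaningful while the eigenvector
    lookup stays nearest-voxel, as in classical FACT.
    """

    fa_stop: float = 0.2
    max_angle_deg: float = 30.0
    step_mm: float | None = None
    seed_fa_min: float = 0.3
    min_len_mm: float = 20.0
    max_len_mm: float = 250.0
    seeds_per_voxel: int = 1
    jitter: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.fa_stop < 1:
            raise ValueError("fa_stop must be in (0, 1)")
        if not 0 < self.max_angle_deg < 90:
            raise ValueError("max_angle_deg must be in (0, 90)")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not self.min_len_mm < self.max_len_mm:
            raise ValueError("min_len_mm must be below max_len_mm")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")

    def resolve_step(self, affine: np.ndarray) -> float:
        if self.step_mm is not None:
            return float(self.step_mm)
        voxel_sizes = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
        return 0.5 * float(voxel_sizes.min())


def generate_seeds(scalar_maps: ScalarMaps, params: TrackingParams) -> np.ndarray:
    """World-mm seed points: voxel centers with FA >= ``seed_fa_min``.

    Raster-scan (C-order) voxel ordering makes the seed list deterministic.
    With ``seeds_per_voxel > 1`` or ``jitter=True``, seeds are drawn uniformly
    inside each voxel from a generator seeded with ``params.rng_seed``.
    """
    fa = np.nan_to_num(scalar_maps.fa, nan=0.0)
    vox = np.argwhere(fa >= params.seed_fa_min).astype(float)
    if len(vox) == 0:
        raise EmptySeedError(
            f"no voxel has FA >= {params.seed_fa_min}; cannot seed tracking"
        )
    if params.jitter or params.seeds_per_voxel > 1:
        rng = np.random.default_rng(params.rng_seed)
        vox = np.repeat(vox, params.seeds_per_voxel, axis=0)
        vox = vox + rng.uniform(-0.5, 0.5, size=vox.shape)
    return apply_affine(scalar_maps.affine, vox)


def _half_tracks(e1, fa, affine, seeds, init_dirs, step, params):
    """Batch-track one half from every seed; returns (points, counts).

    ``points`` is (n_seeds, max_steps, 3); row k holds ``counts[k]`` valid
    points starting with the seed itself.
    """
    inv = inverse_affine(affine)
    shape = np.asarray(fa.shape)
    cos_thresh = np.cos(np.radians(params.max_angle_deg)) - 1e-12
    max_steps = int(np.ceil(params.max_len_mm / step)) + 1

    n = len(seeds)
    points = np.full((n, max_steps, 3), np.nan)
    points[:, 0] = seeds
    counts = np.ones(n, dtype=int)

    pos = seeds.copy()
    prev = init_dirs.copy()
    length = np.zeros(n)
    active = np.ones(n, dtype=bool)

    for i in range(1, max_steps):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        vox = np.rint(apply_affine(inv, pos[idx])).astype(int)
        # current voxel is guaranteed in-grid (checked before the point was kept)
        e = e1[vox[:, 0], vox[:, 1], vox[:, 2]]
        finite = np.all(np.isfinite(e), axis=1)
        dots = np.einsum("ij,ij->i", e, prev[idx])
        e = np.where(dots[:, None] < 0, -e, e)
        cosang = np.abs(dots)
        keep = finite & (cosang >= cos_thresh)

        new_pos = pos[idx] + step * e
        new_vox = np.rint(apply_affine(inv, new_pos)).astype(int)
        inside = np.all((new_vox >= 0) & (new_vox < shape), axis=1)
        keep &= inside
        fa_next = np.zeros(len(idx))
        ok = np.flatnonzero(inside)
        fa_next[ok] = fa[new_vox[ok, 0], new_vox[ok, 1], new_vox[ok, 2]]
        keep &= fa_next >= params.fa_stop  # NaN FA fails the comparison
        keep &= length[idx] + step <= params.max_len_mm

        kept = idx[keep]
        pos[kept] = new_pos[keep]
        prev[kept] = e[keep]
        points[kept, i] = new_pos[keep]
        counts[kept] += 1
        length[kept] += step
        active[idx[~keep]] = False
    return points, counts


def _assemble(points_a, counts_a, points_b, counts_b, step, min_len):
    """Merge +/- half-tracks (seed appears once); drop short streamlines."""
    streamlines = []
    for pa, ca, pb, cb in zip(points_a, counts_a, points_b, counts_b):
        n_pts = ca + cb - 1
        if n_pts < 2 or (n_pts - 1) * step < min_len:
            streamlines.append(None)
            continue
        streamlines.append(np.vstack([pa[:ca][::-1], pb[1:cb]]))
    return streamlines


def _track_batch(tensor_fit, scalar_maps, seeds, params):
    affine = scalar_maps.affine
    step = params.resolve_step(affine)
    inv = inverse_affine(affine)
    fa = scalar_maps.fa
    e1 = tensor_fit.principal_direction

    vox = np.rint(apply_affine(inv, seeds)).astype(int)
    shape = np.asarray(fa.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    vox_c = np.clip(vox, 0, shape - 1)
    seed_fa = fa[vox_c[:, 0], vox_c[:, 1], vox_c[:, 2]]
    valid = inside & (seed_fa >= params.fa_stop)

    init = np.zeros((len(seeds), 3))
    init[valid] = e1[vox[valid, 0], vox[valid, 1], vox[valid, 2]]
    valid &= np.all(np.isfinite(init), axis=1)
    init[~valid] = 0.0

    sub = np.flatnonzero(valid)
    out: list[np.ndarray | None] = [None] * len(seeds)
    if len(sub):
        pa, ca = _half_tracks(e1, fa, affine, seeds[sub], init[sub], step, params)
        pb, cb = _half_tracks(e1, fa, affine, seeds[sub], -init[sub], step, params)
        merged = _assemble(pa, ca, pb, cb, step, params.min_len_mm)
        for k, s in zip(sub, merged):
            out[k] = s
    return out


def track_streamline(
    tensor_fit: DiffusionTensorFit,
    scalar_maps: ScalarMaps,
    seed: np.ndarray,
    params: TrackingParams,
) -> np.ndarray | None:
    """Track bidirectionally from one world-mm seed; None if degenerate."""
    res = _track_batch(tensor_fit, scalar_maps,
                       np.asarray(seed, dtype=float)[None, :], params)
    return res[0]


def track_whole_brain(
    tensor_fit: DiffusionTensorFit,
    scalar_maps: ScalarMaps,
    params: TrackingParams = TrackingParams(),
) -> Tractogram:
    """FACT tracking from every seed; streamline order follows seed order."""
    seeds = generate_seeds(scalar_maps, params)
    tracked = _track_batch(tensor_fit, scalar_maps, seeds, params)
    streamlines = [s for s in tracked if s is not None]
    return Tractogram(
        streamlines=streamlines,
        reference_affine=scalar_maps.affine,
        reference_shape=scalar_maps.fa.shape,
    )
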