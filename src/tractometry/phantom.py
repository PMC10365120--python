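"""Synthetic DWI phantoms and two-group cohorts.

The generator emulates the acquisition the pipeline is designed for — 3 b=0
frames plus 64 isotropically distributed directions at b = 1,000 s/mm^2 on a
1.5 mm isotropic grid — and a simplified SLF-like geometry: per hemisphere,
two arched tubular bundles (a dorsal "SLF II"-like and a ventral
"SLF III"-like arc) that thread a shared posterior coronal waypoint plane
and separate anterior boxes.

Inside a bundle the ground-truth tensor has its principal eigenvector along
the local centerline tangent with eigenvalues (1.2, 0.45, 0.45)x10^-3 mm^2/s
(FA ~ 0.55, MD 0.7x10^-3 — white-matter-like); the background is isotropic
at 0.7x10^-3 (FA 0, so tracking terminates there). Signals follow the
Stejskal-Tanner forward model with Rician noise (magnitude MRI).

Group effects are injected on the *eigenvalues* over a node range of the
bundle centerline, so FA/MD/AD/RD stay mutually consistent; the true
node-wise metric values are recorded in a ground-truth ledger.

Everything is bit-reproducible given the seeds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from ._errors import DataError
from .io import DwiDataset, GradientTable, apply_affine, inverse_affine
from .segmentation import PlaneSpec, WaypointRoi
from .tensor import DiffusionTensorFit, build_design_matrix, fa_from_eigvals

WM_EIGVALS = np.array([1.2e-3, 0.45e-3, 0.45e-3])  # mm^2/s, FA ~ 0.55
BACKGROUND_EIGVALS = np.array([0.7e-3, 0.7e-3, 0.7e-3])  # isotropic, FA 0


# --------------------------------------------------------------------------
# gradient scheme


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def optimize_directions(n_dirs: int, seed: int = 0, n_iter: int = 300,
                        lr: float = 1e-3) -> np.ndarray:
    """Electrostatic-repulsion direction set (antipodally symmetric energy).

    Deterministic: a Fibonacci-sphere start (plus a tiny seeded jitter to
    break its residual symmetry) refined by projected gradient descent on
    sum_{i<j} 1/|x_i - x_j| + 1/|x_i + x_j|.
    """
    rng = np.random.default_rng(seed)
    x = _fibonacci_sphere(n_dirs)
    x += 1e-3 * rng.standard_normal(x.shape)
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    for _ in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]
        summ = x[:, None, :] + x[None, :, :]
        dd = np.linalg.norm(diff, axis=2)
        ds = np.linalg.norm(summ, axis=2)
        np.fill_diagonal(dd, np.inf)
        np.fill_diagonal(ds, np.inf)
        force = (diff / dd[..., None] ** 3).sum(axis=1) + (
            summ / ds[..., None] ** 3).sum(axis=1)
        force -= x * np.einsum("ij,ij->i", force, x)[:, None]  # tangential
        x = x + lr * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def make_gradient_table(n_dirs: int = 64, n_b0: int = 3, b: float = 1000.0,
                        seed: int = 0) -> GradientTable:
    """The default synthetic acquisition: ``n_b0`` b=0 frames first, then
    ``n_dirs`` repulsion-optimized unit directions at b-value ``b``."""
    if n_dirs < 6:
        raise DataError("need at least 6 diffusion directions")
    dirs = optimize_directions(n_dirs, seed=seed)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)


# --------------------------------------------------------------------------
# bundle geometry


@dataclass(frozen=True)
class BundleSpec:
    """A tubular bundle around a parametric centerline.

    kind "straight": params start, end (world mm).
    kind "arc": circular arc ``center + R (cos(phi) u + sin(phi) v)`` for
        phi in phi_range (radians); u, v orthonormal.
    kind "spline": cubic spline through control_points.

    The centerline is traversed from its anterior end (node 1) to its
    posterior end (node n_nodes) — effects node ranges use this orientation.
    """

    name: str
    kind: str
    params: dict
    radius_mm: float
    eigvals: np.ndarray = field(default_factory=lambda: WM_EIGVALS.copy())

    def __post_init__(self):
        ev = np.asarray(self.eigvals, dtype=float)
        if not (ev[0] >= ev[1] >= ev[2] > 0):
            raise DataError("bundle eigenvalues must satisfy l1>=l2>=l3>0")
        object.__setattr__(self, "eigvals", ev)

    def centerline(self, n: int = 400) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense polyline: (points (n,3), unit tangents (n,3), arc fraction)."""
        if self.kind == "straight":
            a = np.asarray(self.params["start"], dtype=float)
            bb = np.asarray(self.params["end"], dtype=float)
            t = np.linspace(0, 1, n)
            pts = a + t[:, None] * (bb - a)
            tans = np.tile((bb - a) / np.linalg.norm(bb - a), (n, 1))
        elif self.kind == "arc":
            c = np.asarray(self.params["center"], dtype=float)
            u = np.asarray(self.params["u"], dtype=float)
            v = np.asarray(self.params["v"], dtype=float)
            R = float(self.params["radius"])
            p0, p1 = self.params["phi_range"]
            phi = np.linspace(p0, p1, n)
            pts = c + R * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
            tans = -np.sin(phi)[:, None] * u + np.cos(phi)[:, None] * v
            tans *= np.sign(p1 - p0)
        elif self.kind == "spline":
            cp = np.asarray(self.params["control_points"], dtype=float)
            chord = np.concatenate(
                [[0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
            cs = CubicSpline(chord, cp, axis=0)
            t = np.linspace(0, chord[-1], n)
            pts = cs(t)
            tans = cs(t, 1)
            tans /= np.linalg.norm(tans, axis=1, keepdims=True)
        else:
            raise DataError(f"unknown centerline kind {self.kind!r}")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return pts, tans, arc / arc[-1]

    def translated(self, offset: np.ndarray) -> "BundleSpec":
        offset = np.asarray(offset, dtype=float)
        p = dict(self.params)
        for key in ("start", "end", "center"):
            if key in p:
                p[key] = np.asarray(p[key], dtype=float) + offset
        if "control_points" in p:
            p["control_points"] = np.asarray(p["control_points"], dtype=float) + offset
        return replace(self, params=p)

    def with_eigvals(self, eigvals: np.ndarray) -> "BundleSpec":
        return replace(self, eigvals=np.asarray(eigvals, dtype=float))


# --------------------------------------------------------------------------
# effects


@dataclass(frozen=True)
class EffectSpec:
    """A node-localized group effect on one bundle's diffusivity.

    ``factor`` multiplies (mode "multiplicative") or is added to (mode
    "additive") the eigenvalue combination behind ``metric``:
    ad -> l1; rd -> l2, l3; md -> all three; fa -> the eigenvalue deviations
    about their mean are scaled (MD preserved).
    """

    bundle: str
    metric: str  # fa | md | ad | rd
    node_range: tuple[int, int]  # 1-based inclusive, of n_nodes
    factor: float
    group: str
    mode: str = "multiplicative"

    def __post_init__(self):
        a, b = self.node_range
        if not 1 <= a <= b:
            raise DataError("effect node range must satisfy 1 <= a <= b")
        if self.metric not in ("fa", "md", "ad", "rd"):
            raise DataError(f"unknown effect metric {self.metric!r}")

    def apply(self, eigvals: np.ndarray) -> np.ndarray:
        ev = np.asarray(eigvals, dtype=float).copy()
        if self.mode == "multiplicative":
            if self.metric == "ad":
                ev[..., 0] *= self.factor
            elif self.metric == "rd":
                ev[..., 1:] *= self.factor
            elif self.metric == "md":
                ev *= self.factor
            else:  # fa: scale deviations about the mean, preserving MD
                mu = ev.mean(axis=-1, keepdims=True)
                ev = mu + self.factor * (ev - mu)
        elif self.mode == "additive":
            if self.metric == "ad":
                ev[..., 0] += self.factor
            elif self.metric == "rd":
                ev[..., 1:] += self.factor
            elif self.metric == "md":
                ev += self.factor
            else:
                raise DataError("additive FA effects are not defined")
        else:
            raise DataError(f"unknown effect mode {self.mode!r}")
        if not np.all((ev[..., 0] >= ev[..., 1]) & (ev[..., 1] >= ev[..., 2])
                      & (ev[..., 2] > 0)):
            raise DataError("effect breaks eigenvalue ordering/positivity")
        return ev


def true_node_metrics(bundle: BundleSpec, effects: list[EffectSpec],
                      n_nodes: int = 100) -> pd.DataFrame:
    """Ground-truth per-node FA/MD/AD/RD for one bundle under given effects."""
    ev = np.tile(bundle.eigvals, (n_nodes, 1))
    for eff in effects:
        if eff.bundle != bundle.name:
            continue
        a, b = eff.node_range
        sl = slice(a - 1, min(b, n_nodes))
        ev[sl] = eff.apply(ev[sl])
    return pd.DataFrame({
        "node": np.arange(1, n_nodes + 1),
        "fa": fa_from_eigvals(ev),
        "md": ev.mean(axis=1),
        "ad": ev[:, 0],
        "rd": ev[:, 1:].mean(axis=1),
    })


# --------------------------------------------------------------------------
# rasterization and signal simulation


def _orthonormal_frames(tangents: np.ndarray) -> np.ndarray:
    """(n, 3, 3) rotation matrices with column 0 = tangent."""
    e1 = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(e1), 1))
    parallel = np.abs(e1[:, 0]) > 0.9
    ref[parallel] = [0.0, 1.0, 0.0]
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=-1)


def rasterize_tensor_field(
    bundle_specs: list[BundleSpec],
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    background_eigvals: np.ndarray = BACKGROUND_EIGVALS,
    effects: list[EffectSpec] | None = None,
    s0: float = 1000.0,
    n_nodes: int = 100,
    centerline_samples: int = 400,
) -> tuple[DiffusionTensorFit, dict[str, np.ndarray]]:
    """Ground-truth tensor field of tubular bundles on an isotropic grid.

    Voxels within ``radius_mm`` of a bundle centerline get that bundle's
    eigenvalues (with any matching effects applied at the voxel's node
    position) and e1 along the local tangent; overlaps resolve to the
    nearest centerline. Background voxels are isotropic.

    Returns the tensor field plus a dict of per-bundle boolean masks.
    """
    effects = effects or []
    shape = tuple(int(d) for d in grid_shape)
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    centers = apply_affine(affine, idx)  # voxel centers, world mm
    n_vox = len(centers)

    lo, hi = centers.min(axis=0), centers.max(axis=0)
    eigvals = np.tile(np.asarray(background_eigvals, dtype=float), (n_vox, 1))
    eigvecs = np.tile(np.eye(3), (n_vox, 1, 1))
    best_dist = np.full(n_vox, np.inf)
    owner = np.full(n_vox, -1)
    masks: dict[str, np.ndarray] = {}

    for b_i, spec in enumerate(bundle_specs):
        pts, tans, frac = spec.centerline(centerline_samples)
        if np.any(pts.min(axis=0) < lo - spec.radius_mm) or \
           np.any(pts.max(axis=0) > hi + spec.radius_mm):
            raise DataError(f"bundle {spec.name!r} extends outside the grid")
        tree = cKDTree(pts)
        dist, nearest = tree.query(centers)
        inside = (dist <= spec.radius_mm) & (dist < best_dist)
        best_dist[inside] = dist[inside]
        owner[inside] = b_i

        frames = _orthonormal_frames(tans[nearest[inside]])
        eigvecs[inside] = frames
        node = np.clip((frac[nearest[inside]] * n_nodes).astype(int) + 1,
                       1, n_nodes)
        ev = np.tile(spec.eigvals, (inside.sum(), 1))
        for eff in effects:
            if eff.bundle != spec.name:
                continue
            a, bnd = eff.node_range
            in_range = (node >= a) & (node <= bnd)
            if in_range.any():
                ev[in_range] = eff.apply(ev[in_range])
        eigvals[inside] = ev

    for b_i, spec in enumerate(bundle_specs):
        masks[spec.name] = (owner == b_i).reshape(shape)

    tensors = np.einsum("vij,vj,vkj->vik", eigvecs, eigvals, eigvecs)
    coeffs = np.stack([tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2],
                       tensors[:, 0, 1], tensors[:, 0, 2], tensors[:, 1, 2]],
                      axis=1)
    fit = DiffusionTensorFit(
        coeffs=coeffs.reshape(shape + (6,)),
        eigvals=eigvals.reshape(shape + (3,)),
        eigvecs=eigvecs.reshape(shape + (3, 3)),
        s0=np.full(shape, float(s0)),
        affine=np.asarray(affine, dtype=float),
        mask=np.ones(shape, dtype=bool),
    )
    return fit, masks


def simulate_dwi(tensor_field: DiffusionTensorFit, gtab: GradientTable,
                 snr: float | None = 30.0,
                 rng_seed: int = 0) -> DwiDataset:
    """Forward-simulate DWI signals; Rician noise unless ``snr`` is None/inf.

    Noise sigma is ``mean(S0)/snr``; the noisy signal is the magnitude of
    (S + e1) + i e2 with e1, e2 ~ N(0, sigma) — the magnitude-MRI model.
    """
    X = build_design_matrix(gtab)
    shape = tensor_field.s0.shape
    params = np.concatenate(
        [tensor_field.coeffs.reshape(-1, 6),
         np.log(tensor_field.s0.reshape(-1, 1))], axis=1)
    signal = np.exp(params @ X.T).reshape(shape + (len(gtab),))
    if snr is not None and np.isfinite(snr):
        if snr <= 0:
            raise DataError("snr must be positive")
        rng = np.random.default_rng(rng_seed)
        sigma = float(np.nanmean(tensor_field.s0)) / float(snr)
        e1 = rng.normal(0.0, sigma, signal.shape)
        e2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2**2)
    return DwiDataset(signal=signal, affine=tensor_field.affine, gtab=gtab)


# --------------------------------------------------------------------------
# the SLF-like scene


@dataclass
class PhantomScene:
    """Bundles, grid geometry, waypoint ROIs, probability maps and lesions."""

    bundles: list[BundleSpec]
    affine: np.ndarray
    shape: tuple[int, int, int]
    rois: dict[str, WaypointRoi]
    prob_maps: dict[str, np.ndarray]
    lesions: dict[str, np.ndarray]
    anterior_points: dict[str, np.ndarray]

    def bundle(self, name: str) -> BundleSpec:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)


def _grid_affine(shape, voxel_size, z_center=2.0):
    shape = np.asarray(shape, dtype=float)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    affine[:3, 3] = -voxel_size * (shape - 1) / 2 + np.array([0, 0, z_center])
    return affine


def make_slf_like_scene(
    shape: tuple[int, int, int] = (60, 72, 60),
    voxel_size: float = 1.5,
    radius_mm: float = 2.5,
    eigvals: np.ndarray = WM_EIGVALS,
    background_eigvals: np.ndarray = BACKGROUND_EIGVALS,
    smoothing_mm: float = 2.0,
) -> PhantomScene:
    """Two arched bundles per hemisphere with their waypoint ROIs.

    Per hemisphere (mirror-symmetric in x): a dorsal arc ("SLF II"-like) and
    a ventral arc ("SLF III"-like), both sagittally oriented, threading a
    common posterior coronal plane (y = -16 mm) and separate anterior boxes
    (y = +12 mm). Probability maps are kernel-smoothed bundle masks
    normalized to [0, 1]; two lesion spheres are planted in the left
    hemisphere — one on the dorsal bundle (probability > 0.5) and one in
    background (probability < 0.5).
    """
    affine = _grid_affine(shape, voxel_size)
    R, alpha = 32.0, np.deg2rad(45.0)
    u = np.array([0.0, 0.0, 1.0])  # arch "up"
    v = np.array([0.0, 1.0, 0.0])  # anterior
    bundles = []
    for hemi, x0 in (("L", -15.0), ("R", 15.0)):
        for tag, zc in (("SLF_II", -20.0), ("SLF_III", -27.5)):
            bundles.append(BundleSpec(
                name=f"{hemi}_{tag}", kind="arc",
                params={"center": np.array([x0, 0.0, zc]), "u": u, "v": v,
                        "radius": R, "phi_range": (alpha, -alpha)},
                radius_mm=radius_mm, eigvals=np.asarray(eigvals, dtype=float)))

    roi_cfg = {"anterior_y_mm": 12.0, "posterior_y_mm": -16.0,
               "thickness_mm": 3.0, "x_lateral_range": (10.0, 20.0),
               "slf2_z_range": (6.5, 14.5), "slf3_z_range": (-2.5, 6.5),
               "posterior_z_range": (-8.0, 14.0)}
    from .segmentation import define_slf_rois  # avoids a module cycle

    rois = define_slf_rois(roi_cfg, space="phantom")

    _, masks = rasterize_tensor_field(bundles, shape, affine,
                                      background_eigvals=background_eigvals)
    sigma_vox = smoothing_mm / voxel_size
    prob_maps = {}
    for name, mask in masks.items():
        sm = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
        prob_maps[name] = sm / sm.max() if sm.max() > 0 else sm
    for hemi in ("L", "R"):
        combined = np.maximum(prob_maps[f"{hemi}_SLF_II"],
                              prob_maps[f"{hemi}_SLF_III"])
        prob_maps[f"{hemi}_SLF"] = combined

    # lesions: spheres in world mm, rasterized onto the grid
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    centers = apply_affine(affine, idx)
    apex_ii = np.array([-15.0, 0.0, 12.0])  # top of the left dorsal arc
    far = np.array([-15.0, 0.0, -10.0])  # below both arcs, background
    lesions = {
        "left_dorsal_hit": (np.linalg.norm(centers - apex_ii, axis=1) <= 4.0
                            ).reshape(shape),
        "background_miss": (np.linalg.norm(centers - far, axis=1) <= 4.0
                            ).reshape(shape),
    }

    anterior_points = {}
    for b in bundles:
        pts, _, _ = b.centerline(3)
        anterior_points[b.name] = pts[0]  # phi = +alpha end (anterior)

    return PhantomScene(bundles=bundles, affine=affine, shape=tuple(shape),
                        rois=rois, prob_maps=prob_maps, lesions=lesions,
                        anterior_points=anterior_points)


# --------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description of a simulated two-group cohort.

    Defaults follow the emulated protocol: 15 subjects per group, 3 b=0 +
    64 directions at b = 1,000 s/mm^2, 1.5 mm voxels, SNR 30 Rician noise,
    0.5 mm rigid inter-subject jitter.
    """

    n_per_group: int = 15
    groups: tuple[str, str] = ("patient", "control")
    n_dirs: int = 64
    n_b0: int = 3
    b_value: float = 1000.0
    snr: float | None = 30.0
    jitter_sd_mm: float = 0.5
    rng_seed: int = 0
    effects: tuple[EffectSpec, ...] = ()

    def __post_init__(self):
        if self.n_per_group < 2:
            raise DataError("need at least 2 subjects per group")
        if self.snr is not None and self.snr <= 0:
            raise DataError("snr must be positive")


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    dwi: DwiDataset


def simulate_profile_cohort(
    n_per_group: int = 15,
    n_nodes: int = 100,
    mean: float = 0.5,
    subject_sd: float = 0.03,
    node_sd: float = 0.02,
    smooth_nodes: float = 5.0,
    effect_delta: float = 0.0,
    effect_nodes: tuple[int, int] = (40, 60),
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level node profiles drawn directly at the profile level.

    Emulates the statistical structure the node-wise tests see: each
    subject's curve is a shared mean plus a per-subject offset
    (``subject_sd``) plus node-wise noise (``node_sd``) smoothed along nodes
    with a Gaussian kernel of ``smooth_nodes`` (profiles of neighboring
    nodes are correlated). Group A additionally receives ``effect_delta`` on
    the 1-based inclusive ``effect_nodes`` range; ``effect_delta=0`` gives
    the global null (both groups exchangeable).

    Returns ``(group_a, group_b)`` arrays of shape (n_per_group, n_nodes).
    """
    rng = np.random.default_rng(rng_seed)

    def _draw():
        offsets = rng.normal(0.0, subject_sd, size=(n_per_group, 1))
        noise = rng.normal(0.0, 1.0, size=(n_per_group, n_nodes))
        if smooth_nodes > 0:
            noise = ndimage.gaussian_filter1d(noise, smooth_nodes, axis=1)
            noise /= noise.std(axis=1, keepdims=True).mean()
        return mean + offsets + node_sd * noise

    a, b = _draw(), _draw()
    if effect_delta != 0.0:
        lo, hi = effect_nodes
        a[:, lo - 1:hi] += effect_delta
    return a, b


def make_cohort(spec: CohortSpec, scene: PhantomScene | None = None,
                n_nodes: int = 100
                ) -> tuple[list[CohortSubject], pd.DataFrame, PhantomScene]:
    """Simulate a two-group cohort on an SLF-like scene.

    Per subject the bundle geometry is rigidly jittered (translation with
    per-axis SD ``jitter_sd_mm``), the group's effects are applied to the
    eigenvalues over their node ranges, and DWI is simulated with a fresh
    child seed. Returns the subjects, a ground-truth ledger of per-node
    metric values per (group, bundle), and the scene used.
    """
    if scene is None:
        scene = make_slf_like_scene()
    rng = np.random.default_rng(spec.rng_seed)
    gtab = make_gradient_table(spec.n_dirs, spec.n_b0, spec.b_value,
                               seed=spec.rng_seed % 2**31)

    subjects = []
    for group in spec.groups:
        effects = [e for e in spec.effects if e.group == group]
        for i in range(spec.n_per_group):
            offset = rng.normal(0.0, spec.jitter_sd_mm, size=3)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            bundles = [b.translated(offset) for b in scene.bundles]
            field_, _ = rasterize_tensor_field(
                bundles, scene.shape, scene.affine, effects=effects,
                n_nodes=n_nodes)
            dwi = simulate_dwi(field_, gtab, snr=spec.snr, rng_seed=noise_seed)
            subjects.append(CohortSubject(
                subject_id=f"{group}_{i + 1:02d}", group=group, dwi=dwi))

    truth_rows = []
    for group in spec.groups:
        effects = [e for e in spec.effects if e.group == group]
        for b in scene.bundles:
            tm = true_node_metrics(b, effects, n_nodes=n_nodes)
            tm.insert(0, "tract", b.name)
            tm.insert(0, "group", group)
            truth_rows.append(tm)
    truth = pd.concat(truth_rows, ignore_index=True)
    return subjects, truth, scene
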