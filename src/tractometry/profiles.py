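"""Tract profiles: 100-node curves of FA/MD/AD/RD along a bundle.

Each streamline of a cleaned bundle is resampled to ``n_nodes`` points
equally spaced in arc length, oriented anterior-to-posterior so node k means
the same position along the tract for every streamline and subject, and the
scalar maps are sampled at each node point by trilinear interpolation. The
node value is the (optionally distance-weighted) mean across streamlines,
with a standard error across streamlines attached.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._errors import DataError, EmptyBundleError
from .io import PROFILE_COLUMNS, apply_affine, inverse_affine
from .segmentation import TractBundle
from .tensor import ScalarMaps

METRICS = ("fa", "md", "ad", "rd")


def resample_streamline(streamline: np.ndarray, n_nodes: int = 100) -> np.ndarray:
    """Resample a polyline to ``n_nodes`` points equally spaced in arc length.

    Piecewise-linear interpolation at arc-length positions k*L/(n_nodes-1);
    the original endpoints are preserved exactly.
    """
    s = np.asarray(streamline, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
        raise DataError("resampling needs a polyline of >= 2 points")
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise DataError("streamline has zero length")
    targets = np.linspace(0.0, arc[-1], n_nodes)
    out = np.column_stack([np.interp(targets, arc, s[:, d]) for d in range(3)])
    out[0], out[-1] = s[0], s[-1]
    return out


def orient_streamlines(streamlines: list[np.ndarray],
                       anterior_point: np.ndarray | None = None) -> list[np.ndarray]:
    """Order every streamline anterior -> posterior (decreasing world y).

    When a streamline's endpoints tie in y, the end closer to
    ``anterior_point`` (e.g. the anterior ROI centroid) goes first.
    """
    out = []
    for s in streamlines:
        dy = s[0, 1] - s[-1, 1]
        if abs(dy) < 1e-9 and anterior_point is not None:
            d0 = np.linalg.norm(s[0] - anterior_point)
            d1 = np.linalg.norm(s[-1] - anterior_point)
            flip = d1 < d0
        else:
            flip = dy < 0
        out.append(s[::-1].copy() if flip else s)
    return out


def orient_bundle(bundle: TractBundle,
                  anterior_point: np.ndarray | None = None) -> list[np.ndarray]:
    """Oriented copies of a bundle's streamlines (the bundle is not mutated)."""
    if len(bundle) == 0:
        raise EmptyBundleError(f"bundle {bundle.name!r} is empty")
    return orient_streamlines(bundle.streamlines, anterior_point)


@dataclass
class TractProfile:
    """Per-subject, per-bundle node-wise diffusion metric curves."""

    subject_id: str
    group: str
    tract: str
    hemisphere: str
    n_nodes: int
    means: dict[str, np.ndarray]  # metric -> (n_nodes,)
    sems: dict[str, np.ndarray]
    support: np.ndarray  # streamlines contributing finite samples per node
    node_positions: np.ndarray | None = None  # (n_nodes, 3) mean world mm

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format rows matching the shared profile CSV schema."""
        return pd.DataFrame({
            "subject_id": self.subject_id,
            "group": self.group,
            "tract": self.tract,
            "hemisphere": self.hemisphere,
            "node": np.arange(1, self.n_nodes + 1),
            **{m: self.means[m] for m in METRICS},
        })[PROFILE_COLUMNS]


def compute_tract_profile(
    bundle: TractBundle,
    scalar_maps: ScalarMaps,
    n_nodes: int = 100,
    weighting: str = "uniform",
    subject_id: str = "",
    group: str = "",
    anterior_point: np.ndarray | None = None,
) -> TractProfile:
    """Node-wise weighted mean and SE of each scalar map along a bundle.

    ``weighting="uniform"`` averages streamlines equally at each node;
    ``"gaussian_distance"`` down-weights streamlines far from the node's
    cross-streamline mean position with weights exp(-d^2 / (2 sigma^2)),
    sigma being the node's point-cloud RMS spread.
    """
    if weighting not in ("uniform", "gaussian_distance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if len(bundle) == 0:
        raise EmptyBundleError(f"bundle {bundle.name!r} is empty")

    oriented = orient_bundle(bundle, anterior_point)
    nodes = np.stack([resample_streamline(s, n_nodes) for s in oriented])
    m = len(oriented)  # (m, n_nodes, 3)

    center = nodes.mean(axis=0)  # (n_nodes, 3)
    if weighting == "gaussian_distance" and m > 1:
        d2 = np.sum((nodes - center) ** 2, axis=2)  # (m, n_nodes)
        sigma2 = d2.mean(axis=0)  # RMS spread per node
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.exp(-d2 / (2.0 * sigma2))
        w[:, sigma2 == 0] = 1.0
    else:
        w = np.ones((m, n_nodes))

    inv = inverse_affine(scalar_maps.affine)
    vox = apply_affine(inv, nodes.reshape(-1, 3)).T  # (3, m*n_nodes)
    means, sems = {}, {}
    support = None
    for metric in METRICS:
        vol = getattr(scalar_maps, metric)
        vals = ndimage.map_coordinates(np.asarray(vol, dtype=float), vox,
                                       order=1, cval=np.nan).reshape(m, n_nodes)
        finite = np.isfinite(vals)
        if support is None:
            support = finite.sum(axis=0)
            if np.any(support == 0):
                warnings.warn("nodes with zero finite samples produce NaN",
                              stacklevel=2)
        wf = w * finite
        wsum = wf.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(wsum > 0,
                          np.nansum(wf * np.where(finite, vals, 0.0), axis=0) / wsum,
                          np.nan)
            var = np.where(
                wsum > 0,
                np.nansum(wf * (np.where(finite, vals, 0.0) - mu) ** 2, axis=0)
                / wsum, np.nan)
        n_eff = finite.sum(axis=0)
        sem = np.sqrt(var) / np.sqrt(np.maximum(n_eff, 1))
        means[metric], sems[metric] = mu, sem

    return TractProfile(
        subject_id=subject_id, group=group, tract=bundle.name,
        hemisphere=bundle.hemisphere, n_nodes=n_nodes,
        means=means, sems=sems, support=support, node_positions=center)


def profiles_to_dataframe(profiles: list[TractProfile]) -> pd.DataFrame:
    """Stack profiles into one long-format table (the CSV schema)."""
    if not profiles:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    return pd.concat([p.to_dataframe() for p in profiles], ignore_index=True)
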