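"""Subject- and group-level orchestration.

``analyze_subject`` is the in-memory core: tensor fit -> whole-brain FACT
tracking -> waypoint dissection of SLF / SLF II / SLF III in both
hemispheres -> probability-map scoring and cleaning -> 100-node profiles.
``run_subject`` / ``run_group`` wrap it with file I/O (NIfTI, .trk, CSV,
QC JSON) driven by a YAML-serializable :class:`PipelineConfig`. Outputs are
deterministic given the config and seed; reruns overwrite identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigError, EmptyBundleError
from . import io as tio
from .profiles import TractProfile, compute_tract_profile, profiles_to_dataframe
from .segmentation import (
    TractBundle,
    WaypointRoi,
    assign_by_waypoints,
    clean_bundle,
    define_slf_rois,
    merged_anterior_roi,
    score_against_probability_map,
)
from .stats import NodewiseGroupComparison
from .tensor import DiffusionTensorModel
from .tracking import TrackingParams, track_whole_brain

TRACTS = ("SLF", "SLF_II", "SLF_III")
HEMISPHERES = ("L", "R")


@dataclass
class PipelineConfig:
    """Everything a subject/group run needs; YAML round-trips losslessly."""

    dwi_path: str = ""
    bval_path: str = ""
    bvec_path: str = ""
    mask_path: str | None = None
    prob_map_paths: dict[str, str] = field(default_factory=dict)
    roi_config: dict = field(default_factory=dict)
    roi_space_affine: list | None = None  # MNI->native affine rows; None = identity
    out_dir: str = "tractometry_out"
    tracking: dict = field(default_factory=dict)  # TrackingParams overrides
    n_nodes: int = 100
    score_quantile: float = 0.05
    length_z_max: float = 3.0
    weighting: str = "uniform"
    fwe_method: str = "permutation_maxT"
    n_perm: int = 10_000
    alpha: float = 0.05
    min_sig_nodes: int = 10
    rng_seed: int = 0
    log_level: str = "INFO"

    def tracking_params(self) -> TrackingParams:
        return TrackingParams(rng_seed=self.rng_seed, **self.tracking)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for label, p in (("dwi_path", self.dwi_path),
                         ("bval_path", self.bval_path),
                         ("bvec_path", self.bvec_path)):
            if not p or not os.path.exists(p):
                raise ConfigError(f"{label} missing or does not exist: {p!r}")
        if self.mask_path and not os.path.exists(self.mask_path):
            raise ConfigError(f"mask_path does not exist: {self.mask_path!r}")
        for name, p in self.prob_map_paths.items():
            if not os.path.exists(p):
                raise ConfigError(f"probability map {name!r} missing: {p!r}")


def _anterior_roi_point(roi: WaypointRoi) -> np.ndarray | None:
    if roi.plane is None:
        return None
    p = roi.plane
    return np.array([np.mean(p.x_range), p.y_mm, np.mean(p.z_range)])


def dissect_slf(tractogram, rois: dict[str, WaypointRoi]
                ) -> dict[tuple[str, str], TractBundle]:
    """The six SLF bundles (3 tracts x 2 hemispheres) from waypoint pairs."""
    bundles = {}
    import warnings

    for hemi in HEMISPHERES:
        ant_ii = rois[f"{hemi}_SLF_II_anterior"]
        ant_iii = rois[f"{hemi}_SLF_III_anterior"]
        post = rois[f"{hemi}_posterior"]
        ant_slf = merged_anterior_roi(ant_ii, ant_iii,
                                      name=f"{hemi}_SLF_anterior")
        pairs = {"SLF": ant_slf, "SLF_II": ant_ii, "SLF_III": ant_iii}
        for tract, ant in pairs.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bundles[(tract, hemi)] = assign_by_waypoints(
                    tractogram, ant, post, name=tract, hemisphere=hemi)
    return bundles


def analyze_subject(
    dwi: tio.DwiDataset,
    rois: dict[str, WaypointRoi],
    prob_maps: dict[str, np.ndarray] | None = None,
    config: PipelineConfig | None = None,
    subject_id: str = "",
    group: str = "",
    return_bundles: bool = False,
):
    """Run the full subject-level pipeline in memory.

    ``prob_maps`` maps ``"{hemi}_{tract}"`` (e.g. ``"L_SLF_II"``) to a fiber
    probability volume on the DWI grid; bundles without a map skip the
    probability-score pruning and are cleaned on length only.
    Returns the tract profiles and a QC report dict.
    """
    cfg = config or PipelineConfig()
    fit = DiffusionTensorModel(dwi, mask=dwi.mask).fit()
    maps = fit.scalar_maps()
    params = cfg.tracking_params()
    tractogram = track_whole_brain(fit, maps, params)

    qc = {
        "subject_id": subject_id,
        "n_streamlines": len(tractogram),
        "n_clamped_eigenvalues": fit.n_clamped_eigenvalues,
        "bundle_counts": {},
        "empty_bundles": [],
    }
    profiles: list[TractProfile] = []
    bundles = dissect_slf(tractogram, rois)
    cleaned_bundles: dict[tuple[str, str], TractBundle] = {}
    for (tract, hemi), bundle in bundles.items():
        key = f"{hemi}_{tract}"
        qc["bundle_counts"][key] = {"raw": len(bundle)}
        if len(bundle) == 0:
            qc["empty_bundles"].append(key)
            continue
        scores = None
        if prob_maps and key in prob_maps:
            scores = score_against_probability_map(bundle, prob_maps[key],
                                                  maps.affine)
        cleaned = clean_bundle(bundle, scores,
                               score_quantile=cfg.score_quantile,
                               length_z_max=cfg.length_z_max)
        qc["bundle_counts"][key]["cleaned"] = len(cleaned)
        if len(cleaned) == 0:
            qc["empty_bundles"].append(key)
            continue
        cleaned_bundles[(tract, hemi)] = cleaned
        ant_roi = rois.get(f"{hemi}_{tract}_anterior",
                           rois[f"{hemi}_SLF_II_anterior"])
        profiles.append(compute_tract_profile(
            cleaned, maps, n_nodes=cfg.n_nodes, weighting=cfg.weighting,
            subject_id=subject_id, group=group,
            anterior_point=_anterior_roi_point(ant_roi)))
    if return_bundles:
        return profiles, qc, cleaned_bundles
    return profiles, qc


def _bundle_trks(bundles, out_dir, subject_id):
    paths = []
    for (tract, hemi), bundle in bundles.items():
        if len(bundle) == 0:
            continue
        tg = tio.Tractogram(bundle.streamlines,
                            bundle.tractogram.reference_affine,
                            bundle.tractogram.reference_shape)
        path = os.path.join(out_dir, f"{subject_id}_{hemi}_{tract}.trk")
        tio.save_tractogram(tg, path)
        paths.append(path)
    return paths


def run_subject(config: PipelineConfig, subject_id: str,
                group: str = "") -> tuple[list[TractProfile], dict]:
    """File-based subject run: loads inputs, writes profiles CSV, per-bundle
    .trk files and a QC JSON under ``config.out_dir/subject_id``."""
    config.validate_paths()
    dwi = tio.load_dwi(config.dwi_path, config.bval_path, config.bvec_path,
                       mask_path=config.mask_path)
    rois = define_slf_rois(config.roi_config or None)
    if config.roi_space_affine is not None:
        from .segmentation import transform_rois

        rois = transform_rois(rois, np.asarray(config.roi_space_affine,
                                               dtype=float))
    prob_maps = {name: tio.load_nifti(p)[0]
                 for name, p in config.prob_map_paths.items()}

    out_dir = os.path.join(config.out_dir, subject_id)
    os.makedirs(out_dir, exist_ok=True)
    profiles, qc, bundles = analyze_subject(dwi, rois, prob_maps or None,
                                            config, subject_id=subject_id,
                                            group=group, return_bundles=True)

    df = profiles_to_dataframe(profiles)
    csv_path = os.path.join(out_dir, f"{subject_id}_profiles.csv")
    tio.save_profiles(df, csv_path)

    qc["trk_files"] = _bundle_trks(bundles, out_dir, subject_id)
    qc["profiles_csv"] = csv_path
    with open(os.path.join(out_dir, f"{subject_id}_qc.json"), "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
    return profiles, qc


def run_group(config: PipelineConfig, profiles: pd.DataFrame,
              group_a: str, group_b: str, make_figures: bool = True):
    """Group-level stats on an assembled profile table.

    Writes node-level stats CSV, a summary table (CSV + Markdown),
    profile figures with significance asterisks, and a checksummed
    output manifest. Returns the fitted results object.
    """
    if profiles.groupby("group")["subject_id"].nunique().min() < 2:
        raise ConfigError("need at least 2 subjects per group")
    model = NodewiseGroupComparison(profiles, group_a, group_b,
                                    alpha=config.alpha)
    results = model.fit(method=config.fwe_method, n_perm=config.n_perm,
                        rng_seed=config.rng_seed)

    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    written = []

    node_csv = os.path.join(out_dir, "nodewise_stats.csv")
    results.to_dataframe().to_csv(node_csv, index=False)
    written.append(node_csv)

    summary = results.summary(min_sig_nodes=config.min_sig_nodes,
                              scale={"md": 1e3, "ad": 1e3, "rd": 1e3})
    summary_csv = os.path.join(out_dir, "summary_table.csv")
    summary.to_csv(summary_csv, index=False)
    written.append(summary_csv)
    summary_md = os.path.join(out_dir, "summary_table.md")
    with open(summary_md, "w") as fh:
        fh.write(summary.to_markdown(index=False))
    written.append(summary_md)

    if make_figures:
        from .plotting import plot_group_profiles

        for (tract, hemi) in profiles[["tract", "hemisphere"]
                                      ].drop_duplicates().itertuples(index=False):
            fig_path = os.path.join(out_dir, f"profile_{hemi}_{tract}.png")
            plot_group_profiles(profiles, results, tract, hemi,
                                save_path=fig_path)
            written.append(fig_path)

    manifest = {os.path.basename(p): _sha256(p) for p in written}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
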