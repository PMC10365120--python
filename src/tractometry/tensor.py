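"""Per-voxel diffusion tensor estimation and the four scalar maps.

The diffusion signal follows the single-tensor Stejskal-Tanner model

    S(b, g) = S0 * exp(-b * g^T D g)

with D a symmetric positive 3x3 tensor per voxel. Taking logs turns the fit
into a linear least-squares problem in the 6 unique tensor components plus
ln S0, which is solved voxel-wise (ordinary least squares by default, with a
one-pass weighted variant available).

From the sorted eigenvalues lambda1 >= lambda2 >= lambda3 the scalar maps are

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / sqrt(l1^2+l2^2+l3^2)
    MD = (l1 + l2 + l3) / 3
    AD = l1
    RD = (l2 + l3) / 2

FA of the zero tensor is defined as 0. Negative eigenvalues (a noise
artifact) are clamped to 0 and counted in the fit's QC attribute; without the
clamp FA can exceed 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import RankDeficientDesignError
from .io import DwiDataset, GradientTable

# order of the unique tensor components everywhere in this package
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


def build_design_matrix(gtab: GradientTable) -> np.ndarray:
    """Stejskal-Tanner linearization: (frames, 7) design for ln S.

    Row i is ``-b_i * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)``
    followed by a constant 1 for the ln S0 intercept. b=0 rows therefore have
    zero diffusion entries.
    """
    b = gtab.bvals
    g = gtab.bvecs
    X = np.empty((len(gtab), 7), dtype=float)
    X[:, 0] = g[:, 0] ** 2
    X[:, 1] = g[:, 1] ** 2
    X[:, 2] = g[:, 2] ** 2
    X[:, 3] = 2.0 * g[:, 0] * g[:, 1]
    X[:, 4] = 2.0 * g[:, 0] * g[:, 2]
    X[:, 5] = 2.0 * g[:, 1] * g[:, 2]
    X[:, :6] *= -b[:, None]
    X[:, 6] = 1.0
    return X


def _tensors_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    """(…, 6) Dxx..Dyz -> (…, 3, 3) symmetric matrices."""
    dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(coeffs, -1, 0)
    T = np.empty(coeffs.shape[:-1] + (3, 3), dtype=float)
    T[..., 0, 0] = dxx
    T[..., 1, 1] = dyy
    T[..., 2, 2] = dzz
    T[..., 0, 1] = T[..., 1, 0] = dxy
    T[..., 0, 2] = T[..., 2, 0] = dxz
    T[..., 1, 2] = T[..., 2, 1] = dyz
    return T


def fa_from_eigvals(eigvals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (…, 3) eigenvalues; 0 for the zero tensor."""
    l1, l2, l3 = np.moveaxis(np.asarray(eigvals, dtype=float), -1, 0)
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num / den)
    fa = np.where(den > 0, fa, np.where(np.isnan(den), np.nan, 0.0))
    return fa


@dataclass
class ScalarMaps:
    """FA/MD/AD/RD 3-D grids sharing one affine; NaN outside the fit mask."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    affine: np.ndarray

    def to_nifti(self, out_dir, prefix: str = "") -> dict[str, str]:
        """Export the four maps as NIfTI volumes; returns name -> path."""
        import os

        from .io import save_nifti

        paths = {}
        for name in ("fa", "md", "ad", "rd"):
            path = os.path.join(str(out_dir), f"{prefix}{name}.nii.gz")
            save_nifti(getattr(self, name), self.affine, path)
            paths[name] = path
        return paths


class DiffusionTensorModel:
    """Single-tensor model of a DWI dataset.

    Parameters
    ----------
    dwi : DwiDataset
        The 4-D signal, affine and gradient table.
    mask : 3-D bool array, optional
        Voxels to fit; defaults to ``dwi.mask`` or the full grid. Voxels
        outside the mask get NaN outputs.
    fit_method : {"ols", "wls"}
        Ordinary log-linear least squares (default), or one-pass weighted
        least squares using squared OLS-predicted signals as weights.
    """

    def __init__(self, dwi: DwiDataset, mask: np.ndarray | None = None,
                 fit_method: str = "ols"):
        if fit_method not in ("ols", "wls"):
            raise ValueError(f"unknown fit_method {fit_method!r}")
        self.dwi = dwi
        self.mask = mask if mask is not None else dwi.mask
        self.fit_method = fit_method
        self.design = build_design_matrix(dwi.gtab)
        if np.linalg.matrix_rank(self.design) < 7:
            raise RankDeficientDesignError(
                "gradient scheme does not span the 7 tensor design columns"
            )

    def fit(self) -> "DiffusionTensorFit":
        dwi = self.dwi
        shape = dwi.shape
        mask = (np.ones(shape, dtype=bool) if self.mask is None
                else self.mask.astype(bool))

        signal = dwi.signal[mask]  # (V, frames)
        dead = np.all(signal <= 0, axis=1)  # all-zero voxels -> NaN outputs

        b0_signal = dwi.signal[..., dwi.gtab.b0_mask]
        floor = 1e-6 * max(float(b0_signal.max()), 1e-300)
        logs = np.log(np.maximum(signal, floor))

        X = self.design
        params = logs @ np.linalg.pinv(X).T  # (V, 7)
        if self.fit_method == "wls":
            # one-pass WLS: weight rows by squared predicted signal
            w = np.exp(params @ X.T)  # (V, frames)
            XtW = X.T[None, :, :] * (w**2)[:, None, :]  # (V, 7, frames)
            lhs = XtW @ X  # (V, 7, 7)
            rhs = np.einsum("vkf,vf->vk", XtW, logs)
            params = np.linalg.solve(lhs, rhs[..., None])[..., 0]

        coeffs = params[:, :6]
        s0 = np.exp(params[:, 6])
        coeffs[dead] = np.nan
        s0[dead] = np.nan

        tensors = _tensors_from_coeffs(coeffs)
        evals = np.full((len(coeffs), 3), np.nan)
        evecs = np.full((len(coeffs), 3, 3), np.nan)
        ok = ~dead
        if ok.any():
            w_, v_ = np.linalg.eigh(tensors[ok])  # ascending
            evals[ok] = w_[:, ::-1]
            evecs[ok] = v_[:, :, ::-1]
        n_clamped = int(np.sum(evals[ok] < 0)) if ok.any() else 0
        np.clip(evals, 0.0, None, out=evals)

        def unflatten(arr, fill=np.nan):
            out = np.full(shape + arr.shape[1:], fill)
            out[mask] = arr
            return out

        return DiffusionTensorFit(
            coeffs=unflatten(coeffs),
            eigvals=unflatten(evals),
            eigvecs=unflatten(evecs),
            s0=unflatten(s0),
            affine=dwi.affine,
            mask=mask,
            n_clamped_eigenvalues=n_clamped,
        )


@dataclass
class DiffusionTensorFit:
    """Fitted tensor field: coefficients, sorted eigen-pairs, S0 and QC.

    ``eigvals[..., 0] >= eigvals[..., 1] >= eigvals[..., 2]``;
    ``eigvecs[..., :, k]`` is the unit eigenvector of ``eigvals[..., k]``.
    """

    coeffs: np.ndarray  # (X, Y, Z, 6) Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    eigvals: np.ndarray  # (X, Y, Z, 3) descending
    eigvecs: np.ndarray  # (X, Y, Z, 3, 3) columns matched to eigvals
    s0: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    n_clamped_eigenvalues: int = 0

    @property
    def principal_direction(self) -> np.ndarray:
        """(X, Y, Z, 3) unit vector of the largest eigenvalue."""
        return self.eigvecs[..., :, 0]

    @property
    def fa(self) -> np.ndarray:
        return fa_from_eigvals(self.eigvals)

    @property
    def md(self) -> np.ndarray:
        return self.eigvals.mean(axis=-1)

    @property
    def ad(self) -> np.ndarray:
        return self.eigvals[..., 0]

    @property
    def rd(self) -> np.ndarray:
        return self.eigvals[..., 1:].mean(axis=-1)

    def scalar_maps(self) -> ScalarMaps:
        return ScalarMaps(fa=self.fa, md=self.md, ad=self.ad, rd=self.rd,
                          affine=self.affine)


def fit_tensor(dwi: DwiDataset, mask: np.ndarray | None = None,
               fit_method: str = "ols") -> DiffusionTensorFit:
    """Functional wrapper: ``DiffusionTensorModel(dwi, mask).fit()``."""
    return DiffusionTensorModel(dwi, mask=mask, fit_method=fit_method).fit()


def compute_scalar_maps(tensor_fit: DiffusionTensorFit) -> ScalarMaps:
    """Functional wrapper for :meth:`DiffusionTensorFit.scalar_maps`."""
    return tensor_fit.scalar_maps()
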