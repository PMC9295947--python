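"""Voxelwise T2* relaxometry and ROI volumetry.

Multi-echo gradient-echo signal in a voxel is modeled as mono-exponential
decay, ``S(TE) = S0 exp(-TE/T2*)``.  Each voxel is fitted by nonlinear
least squares initialised from the log-linear regression of ln S on TE;
per-voxel relative measurement uncertainty comes from the Gauss-Newton
covariance of the fit.  Placental summaries use the median over ROI voxels
after excluding fitted T2* at or above 250 ms (amniotic-fluid
contamination).  Placental volume is voxel counting per slice with linear
interpolation across slices lost to motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import optimize

from .reference import T2STAR_EXCLUDE_MS

__all__ = [
    "MultiEchoVolume",
    "ROIMask",
    "VoxelFit",
    "T2StarSummary",
    "fit_t2star_voxel",
    "map_t2star",
    "placental_volume",
]


@dataclass
class MultiEchoVolume:
    """4D multi-echo signal (x, y, z, echo) with acquisition metadata."""

    signal: np.ndarray
    echo_times_ms: np.ndarray
    voxel_dims_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float).ravel()
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, echo)")
        if self.signal.shape[3] != self.echo_times_ms.size:
            raise ValueError("echo axis length must equal number of echo times")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signals must be finite")
        if np.any(np.diff(self.echo_times_ms) <= 0) or self.echo_times_ms[0] <= 0:
            raise ValueError("echo times must be positive and strictly increasing")
        if len(self.voxel_dims_mm) != 3 or any(d <= 0 for d in self.voxel_dims_mm):
            raise ValueError("voxel_dims_mm must be three positive lengths")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class ROIMask:
    """Binary placental mask aligned to a MultiEchoVolume.

    ``missing_slices`` lists z indices lost to motion; their mask is all
    False and their voxel counts are interpolated during volumetry.
    """

    mask: np.ndarray
    missing_slices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        for z in self.missing_slices:
            if not 0 <= z < self.mask.shape[2]:
                raise ValueError(f"missing slice index {z} outside mask")
            if self.mask[:, :, z].any():
                raise ValueError(f"slice {z} is flagged missing but has masked voxels")


@dataclass
class VoxelFit:
    """Mono-exponential fit of one voxel's echo train."""

    t2star_ms: float
    s0: float
    rel_uncertainty: float
    valid: bool


@dataclass
class T2StarSummary:
    """Placental T2* summary over ROI voxels after the 250 ms exclusion."""

    median_t2star_ms: float
    n_voxels_used: int
    n_voxels_excluded_over_threshold: int
    median_rel_uncertainty: float

    def to_dict(self) -> dict:
        return {
            "median_t2star_ms": self.median_t2star_ms,
            "n_voxels_used": self.n_voxels_used,
            "n_voxels_excluded_over_threshold": self.n_voxels_excluded_over_threshold,
            "median_rel_uncertainty": self.median_rel_uncertainty,
        }


_INVALID = VoxelFit(np.nan, np.nan, np.nan, False)


def fit_t2star_voxel(signals, echo_times_ms) -> VoxelFit:
    """Fit S(TE) = S0 exp(-TE/T2*) to one voxel.

    Nonlinear least squares initialised by log-linear regression of ln S on
    TE.  Relative uncertainty is the delta-method SD of T2* (from the
    Gauss-Newton covariance ``RSS/(n-2) (J'J)^{-1}``) divided by the
    estimate.  The fit is marked invalid when fewer than three echoes have
    positive signal, the decay slope is non-negative (T2* unbounded or
    negative), or the optimiser fails.
    """
    s = np.asarray(signals, dtype=float).ravel()
    te = np.asarray(echo_times_ms, dtype=float).ravel()
    if s.size != te.size:
        raise ValueError("signals and echo times must have the same length")
    pos = s > 0
    if pos.sum() < 3:
        return _INVALID

    # log-linear init on the positive echoes: ln S = ln S0 - TE/T2*
    slope, intercept = np.polyfit(te[pos], np.log(s[pos]), 1)
    if slope >= -1e-9:  # zero or positive decay: T2* unbounded
        return _INVALID
    t2_init = -1.0 / slope
    s0_init = float(np.exp(intercept))

    def resid(p):
        return p[0] * np.exp(-te / p[1]) - s

    def jac(p):
        e = np.exp(-te / p[1])
        return np.column_stack([e, p[0] * te / p[1] ** 2 * e])

    try:
        res = optimize.least_squares(
            resid, [s0_init, t2_init], jac=jac, method="lm", max_nfev=500
        )
    except Exception:
        return _INVALID
    s0_hat, t2_hat = res.x
    if not res.success or not np.isfinite(t2_hat) or not 0 < t2_hat < 1e9:
        return _INVALID

    rss = float(2.0 * res.cost)
    dof = te.size - 2
    J = jac(res.x)
    try:
        cov = rss / dof * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return _INVALID
    sd_t2 = float(np.sqrt(max(cov[1, 1], 0.0)))
    return VoxelFit(float(t2_hat), float(s0_hat), sd_t2 / float(t2_hat), True)


def map_t2star(
    volume: MultiEchoVolume,
    roi: ROIMask,
    exclude_ms: float = T2STAR_EXCLUDE_MS,
) -> tuple[np.ndarray, T2StarSummary]:
    """Fit every ROI voxel and summarise the placental T2* distribution.

    Returns the voxelwise T2* map (NaN outside the ROI and at invalid
    voxels) and a :class:`T2StarSummary`.  Voxels with fitted T2* at or
    above ``exclude_ms`` (strict >=) are excluded from both the median and
    the uncertainty summary but remain in the map.
    """
    if roi.mask.shape != volume.spatial_shape:
        raise ValueError("mask shape does not match signal spatial dimensions")
    idx = np.argwhere(roi.mask)
    if idx.size == 0:
        raise ValueError("empty ROI")

    t2_map = np.full(volume.spatial_shape, np.nan)
    values, uncertainties = [], []
    n_excluded = 0
    for x, y, z in idx:
        fit = fit_t2star_voxel(volume.signal[x, y, z, :], volume.echo_times_ms)
        if not fit.valid:
            continue
        t2_map[x, y, z] = fit.t2star_ms
        if fit.t2star_ms >= exclude_ms:
            n_excluded += 1
            continue
        values.append(fit.t2star_ms)
        uncertainties.append(fit.rel_uncertainty)

    summary = T2StarSummary(
        median_t2star_ms=float(np.median(values)) if values else np.nan,
        n_voxels_used=len(values),
        n_voxels_excluded_over_threshold=n_excluded,
        median_rel_uncertainty=float(np.median(uncertainties)) if uncertainties else np.nan,
    )
    return t2_map, summary


def placental_volume(roi: ROIMask, voxel_dims_mm) -> float:
    """Placental volume in cm^3 from the binary ROI mask.

    Sums per-slice masked voxel counts times the per-voxel volume.  Counts
    of slices lost to motion are linearly interpolated between the nearest
    present slices on either side (copied from the single nearest present
    slice at the ends).
    """
    dims = tuple(float(d) for d in voxel_dims_mm)
    if len(dims) != 3 or any(d <= 0 for d in dims):
        raise ValueError("voxel_dims_mm must be three positive lengths")
    n_slices = roi.mask.shape[2]
    missing = set(roi.missing_slices)
    if len(missing) >= n_slices:
        raise ValueError("all slices missing: volume undefined")
    counts = roi.mask.sum(axis=(0, 1)).astype(float)
    present = [z for z in range(n_slices) if z not in missing]
    if not roi.mask.any() and not missing:
        raise ValueError("empty ROI")

    for z in sorted(missing):
        below = [p for p in present if p < z]
        above = [p for p in present if p > z]
        if below and above:
            z0, z1 = below[-1], above[0]
            w = (z - z0) / (z1 - z0)
            counts[z] = (1 - w) * counts[z0] + w * counts[z1]
        elif below:
            counts[z] = counts[below[-1]]
        else:
            counts[z] = counts[above[0]]

    voxel_volume_mm3 = dims[0] * dims[1] * dims[2]
    return float(counts.sum() * voxel_volume_mm3 / 1000.0)


# -- NIfTI / JSON interchange ---------------------------------------------

def write_multiecho_nifti(volume: MultiEchoVolume, roi: ROIMask, out_dir, truth_map=None) -> dict:
    """Write signal, mask (and optional truth map) as NIfTI-1 plus an echo-time sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*volume.voxel_dims_mm, 1.0])
    paths = {
        "signal": out / "signal.nii.gz",
        "mask": out / "mask.nii.gz",
        "echoes": out / "echoes.json",
    }
    nib.save(nib.Nifti1Image(volume.signal.astype(np.float32), affine), paths["signal"])
    nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), affine), paths["mask"])
    with open(paths["echoes"], "w") as fh:
        json.dump({"echo_times_ms": list(map(float, volume.echo_times_ms)),
                   "voxel_dims_mm": list(volume.voxel_dims_mm),
                   "missing_slices": list(roi.missing_slices)}, fh, indent=2)
    if truth_map is not None:
        paths["truth"] = out / "t2star_truth.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(truth_map, dtype=np.float32), affine), paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_multiecho_nifti(signal_path, mask_path, echoes_path) -> tuple[MultiEchoVolume, ROIMask]:
    """Load a signal/mask pair written by :func:`write_multiecho_nifti`."""
    with open(echoes_path) as fh:
        meta = json.load(fh)
    sig = np.asarray(nib.load(str(signal_path)).get_fdata())
    mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0.5
    vol = MultiEchoVolume(sig, meta["echo_times_ms"], tuple(meta["voxel_dims_mm"]))
    roi = ROIMask(mask, list(meta.get("missing_slices", [])))
    return vol, roi


def write_t2star_map(t2_map, voxel_dims_mm, path) -> None:
    affine = np.diag([*voxel_dims_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(t2_map, dtype=np.float32), affine), str(path))
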