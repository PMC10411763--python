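"""Registration-quality and phantom QC metrics.

Implements the %RMSE registration-quality metric — the root-mean-square
voxelwise count difference between the reference and the co-registered volume,
expressed as a percentage of the reference's total counts — plus the classic
cylindrical-phantom quality-control triplet:

* integral uniformity, IAEA/NEMA style: 100 x (max - min)/(max + min) over a
  smoothed, eroded in-slice region of the uniform compartment;
* cold-sphere contrast against a user-defined uniform background region
  (both a maximum variant, using the sphere minimum, and a mean variant);
* resolution, as per-rod FWHM from a multi-Gaussian fit to a count profile
  across the cold-rod sectors.

The printed 2-D (per-slice) RMSE form is available via ``per_slice=True``; the
default aggregates over the full 3-D volume.  The %RMSE normalization by total
counts makes the metric invariant under joint rescaling of both volumes and
produces very small percentages on realistic count totals (the denominator is
a sum over millions of voxels).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .errors import GeometryError, VoxdoseError
from .volumes_io import Volume3D

__all__ = [
    "CylindricalROI",
    "LineProfile",
    "RodFit",
    "QCReport",
    "rmse",
    "mse",
    "percent_rmse",
    "uniformity",
    "contrast",
    "resolution_fwhm",
    "fit_profile_fwhm",
    "qc_compare",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class CylindricalROI:
    """In-slice circular region over an axial (z) range, world mm."""

    center_xy_mm: tuple[float, float] = (0.0, 0.0)
    radius_mm: float = 75.0
    z_range_mm: tuple[float, float] = (-30.0, 30.0)


@dataclass(frozen=True)
class LineProfile:
    """Straight sampling line between two world points (mm)."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]


@dataclass
class RodFit:
    fwhm_mm: float
    center_mm: float
    amplitude: float
    success: bool


@dataclass
class QCReport:
    """Container for the QC triplet plus registration quality and metadata."""

    percent_rmse: float | None = None
    uniformity_pct: float | None = None
    per_slice_uniformity: list[float] = field(default_factory=list)
    contrast: list[dict] = field(default_factory=list)   # per sphere
    fwhm_mm: list[float] = field(default_factory=list)   # per resolved rod
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)

    def as_row(self) -> dict:
        """Flat single-row summary (for CSV tables)."""
        row = {
            "percent_rmse": self.percent_rmse,
            "uniformity_pct": self.uniformity_pct,
            "resolution_fwhm_mm": (
                float(np.mean(self.fwhm_mm)) if self.fwhm_mm else None),
            "max_contrast_pct": (
                max(c["max_contrast"] for c in self.contrast) if self.contrast else None),
        }
        row.update(self.metadata)
        return row


def _check_same_grid(reference: Volume3D, registered: Volume3D) -> None:
    if not reference.same_grid(registered):
        raise GeometryError("volumes must share one grid for RMSE")
    if reference.value_kind != registered.value_kind:
        raise GeometryError("volumes must have the same value kind for RMSE")


def mse(reference: Volume3D, registered: Volume3D) -> float:
    _check_same_grid(reference, registered)
    d = reference.values - registered.values
    return float(np.mean(d * d))


def rmse(reference: Volume3D, registered: Volume3D, per_slice: bool = False):
    """Root-mean-square voxel difference; per-slice list with ``per_slice``."""
    _check_same_grid(reference, registered)
    d = reference.values - registered.values
    if per_slice:
        return [float(np.sqrt(np.mean(d[:, :, k] ** 2))) for k in range(d.shape[2])]
    return float(np.sqrt(np.mean(d * d)))


def percent_rmse(reference: Volume3D, registered: Volume3D) -> float:
    """100 x RMSE / total reference counts.

    Both numerator and denominator scale linearly with intensity, so
    %RMSE(k·r, k·g) = %RMSE(r, g) for k > 0.
    """
    total = reference.total()
    if total == 0:
        raise VoxdoseError("reference volume has zero total; %RMSE undefined")
    return 100.0 * rmse(reference, registered) / total


def _slice_indices(volume: Volume3D, z_range_mm: tuple[float, float]) -> np.ndarray:
    nz = volume.shape[2]
    z = np.array([volume.index_to_world((0, 0, k))[2] for k in range(nz)])
    sel = np.flatnonzero((z >= z_range_mm[0]) & (z <= z_range_mm[1]))
    return sel


def _disk_mask(volume: Volume3D, center_xy: tuple[float, float], radius_mm: float) -> np.ndarray:
    nx, ny = volume.shape[:2]
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    idx = np.stack([ii, jj, np.zeros_like(ii)], axis=-1).astype(float)
    w = volume.index_to_world(idx)
    return (w[..., 0] - center_xy[0]) ** 2 + (w[..., 1] - center_xy[1]) ** 2 <= radius_mm ** 2


def uniformity(volume: Volume3D, roi: CylindricalROI, smooth: bool = True,
               erode_voxels: int = 2) -> tuple[float, list[float]]:
    """Integral uniformity 100 x (max - min)/(max + min), IAEA style.

    Each slice in the ROI z-range is smoothed with a 3x3 in-slice mean filter;
    the circular ROI is eroded by ``erode_voxels`` to keep edge voxels out.
    Returns (mean over slices, per-slice values).
    """
    slices = _slice_indices(volume, roi.z_range_mm)
    if len(slices) == 0:
        raise VoxdoseError("uniformity ROI contains no slices")
    r_eff = roi.radius_mm - erode_voxels * max(volume.spacing[:2])
    if r_eff <= 0:
        raise VoxdoseError("ROI radius too small after erosion")
    disk = _disk_mask(volume, roi.center_xy_mm, r_eff)
    if not disk.any():
        raise VoxdoseError("uniformity ROI is empty on this grid")
    per_slice = []
    for k in slices:
        sl = volume.values[:, :, k]
        if smooth:
            sl = ndimage.uniform_filter(sl, size=3)
        v = sl[disk]
        hi, lo = float(v.max()), float(v.min())
        per_slice.append(0.0 if hi + lo == 0 else 100.0 * (hi - lo) / (hi + lo))
    return float(np.mean(per_slice)), per_slice


def contrast(volume: Volume3D, sphere_specs: list[tuple[tuple[float, float, float], float]],
             background_roi: CylindricalROI) -> list[dict]:
    """Cold-sphere contrast against a uniform background region.

    For each (center_mm, radius_mm) sphere: max_contrast = 100 (B - min)/B and
    mean_contrast = 100 (B - mean)/B with B the background mean.  The sphere
    minimum is located automatically within the sphere mask.
    """
    slices = _slice_indices(volume, background_roi.z_range_mm)
    disk = _disk_mask(volume, background_roi.center_xy_mm, background_roi.radius_mm)
    if len(slices) == 0 or not disk.any():
        raise VoxdoseError("background ROI is empty")
    bg = float(np.mean(volume.values[:, :, slices][disk]))
    if bg == 0:
        raise VoxdoseError("background mean is zero; contrast undefined")

    X, Y, Z = volume.world_coordinates()
    out = []
    for center, radius in sphere_specs:
        c = np.asarray(center, dtype=float)
        m = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius ** 2
        if not m.any():
            raise VoxdoseError(f"sphere at {tuple(c)} covers no voxel")
        v = volume.values[m]
        out.append({
            "center_mm": tuple(map(float, c)),
            "radius_mm": float(radius),
            "max_contrast": 100.0 * (bg - float(v.min())) / bg,
            "mean_contrast": 100.0 * (bg - float(v.mean())) / bg,
        })
    return out


def _multi_gaussian(x, baseline, *params):
    y = np.full_like(x, baseline, dtype=float)
    for i in range(0, len(params), 3):
        a, c, s = params[i:i + 3]
        y += a * np.exp(-0.5 * ((x - c) / s) ** 2)
    return y


def fit_profile_fwhm(positions_mm: np.ndarray, values: np.ndarray,
                     min_separation_mm: float | None = None,
                     noise_mad_mult: float = 3.0) -> list[RodFit]:
    """Fit a 1-D profile as baseline + k signed Gaussians; FWHM per component.

    Peak detection: local extrema of the deviation from the median baseline
    exceeding ``noise_mad_mult`` x the MAD-estimated noise, separated by at
    least ``min_separation_mm``.  Components whose nonlinear fit fails are
    returned with ``success=False`` rather than raising.
    """
    x = np.asarray(positions_mm, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 5:
        raise VoxdoseError("profile must be 1-D with at least 5 samples")
    dx = float(np.median(np.diff(x)))
    baseline = float(np.median(y))
    dev = y - baseline
    sigma_noise = 1.4826 * float(np.median(np.abs(dev - np.median(dev))))
    height = max(noise_mad_mult * sigma_noise, 1e-12 * max(abs(y).max(), 1.0))
    distance = max(1, int(round((min_separation_mm or 2 * dx) / dx)))

    peaks_up, _ = signal.find_peaks(dev, height=height, distance=distance)
    peaks_dn, _ = signal.find_peaks(-dev, height=height, distance=distance)
    peaks = sorted(np.concatenate([peaks_up, peaks_dn]).astype(int))
    if len(peaks) == 0:
        return []

    p0 = [baseline]
    lo, hi = [-np.inf], [np.inf]
    sigma0 = (min_separation_mm or 4 * dx) / _FWHM_FACTOR
    for p in peaks:
        p0 += [dev[p], x[p], sigma0]
        amp_bound = 10 * max(abs(dev).max(), 1e-12)
        lo += [-amp_bound, x[0], 0.25 * dx]
        hi += [amp_bound, x[-1], (x[-1] - x[0])]
    try:
        popt, _ = optimize.curve_fit(_multi_gaussian, x, y, p0=p0, bounds=(lo, hi),
                                     maxfev=20000)
        ok = True
    except (RuntimeError, ValueError):
        popt, ok = np.asarray(p0, dtype=float), False

    fits = []
    half_win = (min_separation_mm or 4 * dx)
    for i, p in enumerate(peaks):
        a, c, s = popt[1 + 3 * i: 4 + 3 * i]
        success = ok
        if not ok:
            # joint fit failed: refit this component alone in a local window
            win = (x >= x[p] - half_win) & (x <= x[p] + half_win)
            try:
                popt1, _ = optimize.curve_fit(
                    lambda xx, aa, cc, ss: baseline + aa * np.exp(-0.5 * ((xx - cc) / ss) ** 2),
                    x[win], y[win], p0=[dev[p], x[p], sigma0],
                    bounds=([-10 * abs(dev).max() - 1e-9, x[p] - half_win, 0.25 * dx],
                            [10 * abs(dev).max() + 1e-9, x[p] + half_win, x[-1] - x[0]]),
                    maxfev=10000,
                )
                a, c, s = popt1
                success = True
            except (RuntimeError, ValueError):
                success = False
        fits.append(RodFit(
            fwhm_mm=float(_FWHM_FACTOR * abs(s)),
            center_mm=float(c),
            amplitude=float(a),
            success=success,
        ))
    return fits


def resolution_fwhm(volume: Volume3D, line: LineProfile,
                    min_separation_mm: float | None = None) -> list[RodFit]:
    """Sample a line profile at voxel spacing and fit rod FWHMs (mm)."""
    a = np.asarray(line.start_mm, dtype=float)
    b = np.asarray(line.end_mm, dtype=float)
    length = float(np.linalg.norm(b - a))
    if length == 0:
        raise VoxdoseError("line profile has zero length")
    step = float(min(volume.spacing))
    n = max(int(np.ceil(length / step)) + 1, 5)
    pos = np.linspace(0.0, length, n)
    pts = a[None, :] + (b - a)[None, :] * (pos / length)[:, None]
    idx = volume.world_to_index(pts)
    vals = ndimage.map_coordinates(volume.values, idx.T, order=1, mode="nearest")
    return fit_profile_fwhm(pos, vals, min_separation_mm=min_separation_mm)


def qc_compare(before: QCReport, after: QCReport, rel_floor: float = 0.1) -> dict:
    """Paired metric deltas with relative changes (no hypothesis testing).

    Relative changes are computed against max(|before|, rel_floor) so that
    metrics legitimately near zero (e.g. uniformity of a noiseless uniform
    region) do not produce unbounded percentages.  Mismatched metric sets
    (different sphere or rod counts, metric present on one side only) raise.
    """
    def entry(b, a):
        return {
            "before": b, "after": a, "delta": a - b,
            "rel_change_pct": 100.0 * abs(a - b) / max(abs(b), rel_floor),
        }

    out: dict = {}
    for name in ("percent_rmse", "uniformity_pct"):
        b, a = getattr(before, name), getattr(after, name)
        if (b is None) != (a is None):
            raise VoxdoseError(f"metric '{name}' present on one side only")
        if b is not None:
            out[name] = entry(b, a)
    if len(before.contrast) != len(after.contrast):
        raise VoxdoseError("contrast sphere sets differ between reports")
    out["contrast"] = [
        {k: entry(cb[k], ca[k]) for k in ("max_contrast", "mean_contrast")}
        for cb, ca in zip(before.contrast, after.contrast)
    ]
    if len(before.fwhm_mm) != len(after.fwhm_mm):
        raise VoxdoseError("rod FWHM sets differ between reports")
    out["fwhm_mm"] = [entry(b, a) for b, a in zip(before.fwhm_mm, after.fwhm_mm)]
    return out
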