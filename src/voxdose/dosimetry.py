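"""Voxel S-value dose-point-kernel dosimetry.

A dose kernel tabulates the absorbed dose (mGy) to a voxel at a given offset
per unit time-integrated activity (MBq·s) in the source voxel.  The dose map
is the convolution of the TIA map with the kernel; sources are split by the
tissue of the *source* voxel (bone vs soft tissue, from a 300-HU CT
segmentation), each group convolved with its medium's kernel and the results
summed.  Convolution is FFT-based with zero padding (no wraparound); a
brute-force direct sum serves as the oracle in the test suite.

The shipped analytic kernels are explicit toys — a voxel self-dose plus an
exponential radial fall-off with medium-dependent attenuation — labelled not
for clinical use.  Physically accurate kernels from Monte-Carlo transport can
be dropped in through the same JSON file contract.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, signal, stats

from .errors import ConfigurationError, GeometryError, VoxdoseError
from .volumes_io import ValueKind, Volume3D

__all__ = [
    "RADIONUCLIDES",
    "DoseKernel",
    "TissueMask",
    "VoiStats",
    "segment_bone",
    "generate_toy_kernel",
    "load_kernel",
    "save_kernel",
    "convolve_dose",
    "voi_by_cutoff",
    "pearson",
    "bland_altman",
]

# Toy per-radionuclide parameters: mean emitted beta energy per decay (MeV)
# and a soft-tissue attenuation length (mm) reflecting relative beta range.
RADIONUCLIDES = {
    "I131": {"mean_beta_mev": 0.182, "soft_mu_per_mm": 1.6, "half_life_h": 192.5},
    "Lu177": {"mean_beta_mev": 0.147, "soft_mu_per_mm": 2.2, "half_life_h": 159.5},
    "Y90": {"mean_beta_mev": 0.933, "soft_mu_per_mm": 0.45, "half_life_h": 64.1},
}

_MEDIA = ("soft_tissue", "bone")
_BONE_MU_FACTOR = 1.6       # denser medium -> shorter range
_BONE_DENSITY = 1.85        # g/mL, cortical-ish
_SOFT_DENSITY = 1.0


@dataclass
class DoseKernel:
    """Radionuclide- and medium-tagged voxel S-value table.

    ``values[i, j, k]`` is mGy per MBq·s in the source voxel for a target
    voxel at offset (i - c, j - c, k - c), c the center of the odd-sided cube.
    """

    radionuclide: str
    voxel_spacing: tuple[float, float, float]
    medium: str
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or any(s % 2 == 0 for s in self.values.shape):
            raise ConfigurationError("kernel table must be 3-D with odd sides")
        if np.any(self.values < 0):
            raise ConfigurationError("kernel values must be non-negative")
        c = tuple(s // 2 for s in self.values.shape)
        if self.values[c] < self.values.max():
            raise ConfigurationError("kernel center (self-dose) must be the maximum")
        if self.medium not in _MEDIA:
            raise ConfigurationError(f"medium must be one of {_MEDIA}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def self_dose(self) -> float:
        return float(self.values[tuple(s // 2 for s in self.values.shape)])


@dataclass
class TissueMask:
    """Boolean grid aligned to the dose grid; True marks bone."""

    bone: np.ndarray
    cutoff_hu: float = 300.0

    def __post_init__(self):
        self.bone = np.asarray(self.bone, dtype=bool)
        if self.bone.ndim != 3:
            raise GeometryError("tissue mask must be 3-D")


@dataclass
class VoiStats:
    mask: np.ndarray
    mean_dose_mgy: float
    max_dose_mgy: float
    volume_ml: float
    cutoff_fraction: float


def segment_bone(ct: Volume3D, cutoff_hu: float = 300.0) -> TissueMask:
    """Threshold segmentation: bone = (HU >= cutoff), inclusive at the cutoff."""
    if ct.value_kind != ValueKind.HU:
        raise GeometryError(f"CT must be in HU, got {ct.value_kind.value}")
    return TissueMask(bone=ct.values >= cutoff_hu, cutoff_hu=float(cutoff_hu))


def generate_toy_kernel(radionuclide: str, spacing_mm: tuple[float, float, float],
                        table_side: int = 9, medium: str = "soft_tissue") -> DoseKernel:
    """Analytic stand-in kernel: self-dose + exponential radial fall-off.

    The self-dose deposits the mean beta energy per decay in the source voxel
    mass; off-center voxels receive a 1/r²-weighted exponential fall-off with
    a medium-dependent attenuation length.  Deterministic for fixed inputs.
    Provenance is marked "toy — not for clinical use".
    """
    if radionuclide not in RADIONUCLIDES:
        raise ConfigurationError(f"unknown radionuclide '{radionuclide}'")
    if table_side % 2 == 0 or table_side < 1:
        raise ConfigurationError("table_side must be odd and >= 1")
    if medium not in _MEDIA:
        raise ConfigurationError(f"medium must be one of {_MEDIA}")
    par = RADIONUCLIDES[radionuclide]
    spacing = tuple(float(s) for s in spacing_mm)
    density = _SOFT_DENSITY if medium == "soft_tissue" else _BONE_DENSITY
    voxel_mass_kg = float(np.prod(spacing)) * 1e-3 * density * 1e-3  # mm^3 -> mL -> kg
    # mGy per MBq*s of self-irradiation: 1e6 decays * E[MeV->J] / mass, Gy->mGy
    s0 = par["mean_beta_mev"] * 1.602e-13 * 1e6 / voxel_mass_kg * 1e3

    mu = par["soft_mu_per_mm"] * (1.0 if medium == "soft_tissue" else _BONE_MU_FACTOR)
    half = table_side // 2
    idx = np.arange(-half, half + 1)
    X, Y, Z = np.meshgrid(idx * spacing[0], idx * spacing[1], idx * spacing[2],
                          indexing="ij")
    r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
    vals = np.zeros_like(r)
    off = r > 0
    r_ref = float(min(spacing))
    vals[off] = s0 * np.exp(-mu * (r[off] - r_ref)) * (r_ref / r[off]) ** 2 * 0.1
    vals[~off] = s0
    return DoseKernel(
        radionuclide=radionuclide,
        voxel_spacing=spacing,
        medium=medium,
        values=vals,
        provenance="toy — analytic stand-in kernel, not for clinical use",
    )


def save_kernel(kernel: DoseKernel, path: str | os.PathLike) -> Path:
    path = Path(path)
    payload = {
        "radionuclide": kernel.radionuclide,
        "voxel_spacing_mm": list(kernel.voxel_spacing),
        "medium": kernel.medium,
        "provenance": kernel.provenance,
        "shape": list(kernel.values.shape),
        "values": kernel.values.ravel().tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def load_kernel(path: str | os.PathLike) -> DoseKernel:
    d = json.loads(Path(path).read_text())
    return DoseKernel(
        radionuclide=d["radionuclide"],
        voxel_spacing=tuple(d["voxel_spacing_mm"]),
        medium=d["medium"],
        values=np.asarray(d["values"], dtype=float).reshape(d["shape"]),
        provenance=d.get("provenance", ""),
    )


def convolve_dose(tia: Volume3D, kernels: dict[str, DoseKernel],
                  tissue: TissueMask) -> Volume3D:
    """Dose map (mGy) from a TIA map (MBq·s) by kernel convolution.

    Sources are grouped by the *source* voxel's medium; each group is
    convolved (FFT, zero-padded) with that medium's kernel and the results
    summed, so the map is linear in TIA.  Kernel spacing must match the TIA
    grid exactly — mismatches raise rather than silently resampling.
    """
    if tia.value_kind != ValueKind.TIA_MBQ_S:
        raise GeometryError(f"input must be a TIA map, got {tia.value_kind.value}")
    for m in _MEDIA:
        if m not in kernels:
            raise ConfigurationError(f"kernel for medium '{m}' is missing")
    if tissue.bone.shape != tia.shape:
        raise GeometryError("tissue mask shape does not match the TIA grid")
    for k in kernels.values():
        if not np.allclose(k.voxel_spacing, tia.spacing, rtol=1e-6):
            raise GeometryError(
                f"kernel spacing {k.voxel_spacing} does not match TIA grid {tia.spacing}"
            )

    src_bone = tissue.bone
    dose = np.zeros(tia.shape)
    for medium, src_mask in (("soft_tissue", ~src_bone), ("bone", src_bone)):
        src = tia.values * src_mask
        if not src.any():
            continue
        dose += signal.fftconvolve(src, kernels[medium].values, mode="same")
    dose[np.abs(dose) < 1e-12 * max(dose.max(), 1.0)] = 0.0
    return tia.with_values(np.maximum(dose, 0.0), value_kind=ValueKind.DOSE_MGY)


def voi_by_cutoff(dose: Volume3D, organ_region, cutoff_fraction: float = 0.40) -> VoiStats:
    """Supra-threshold VOI around an organ's dose maximum.

    ``organ_region`` is either a boolean mask (the maximum is taken within it)
    or a world seed point (mm); from a seed, the maximum is located by
    hill-climbing on the 26-neighbourhood.  The VOI is the 26-connected
    component, containing that maximum, of voxels >= cutoff x max (inclusive).
    """
    if dose.value_kind != ValueKind.DOSE_MGY:
        raise GeometryError("voi_by_cutoff expects a dose map")
    if not 0 < cutoff_fraction <= 1:
        raise ConfigurationError("cutoff_fraction must be in (0, 1]")
    vals = dose.values

    if isinstance(organ_region, np.ndarray) and organ_region.dtype == bool:
        if organ_region.shape != dose.shape:
            raise GeometryError("organ mask shape does not match the dose grid")
        if not organ_region.any():
            raise VoxdoseError("organ region is empty")
        flat = np.where(organ_region, vals, -np.inf)
        max_idx = np.unravel_index(np.argmax(flat), vals.shape)
    else:
        seed = np.asarray(organ_region, dtype=float)
        idx = np.round(dose.world_to_index(seed)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(dose.shape)):
            raise VoxdoseError(f"seed point {tuple(seed)} lies outside the grid")
        max_idx = tuple(idx)
        while True:  # steepest-ascent hill climb, 26-neighbourhood
            i, j, k = max_idx
            sl = vals[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2, max(k - 1, 0): k + 2]
            local = np.unravel_index(np.argmax(sl), sl.shape)
            cand = (max(i - 1, 0) + local[0], max(j - 1, 0) + local[1], max(k - 1, 0) + local[2])
            if vals[cand] <= vals[max_idx]:
                break
            max_idx = cand

    vmax = float(vals[max_idx])
    if vmax <= 0:
        raise VoxdoseError("organ region has no positive dose")
    supra = vals >= cutoff_fraction * vmax
    labels, _ = ndimage.label(supra, structure=np.ones((3, 3, 3)))
    voi = labels == labels[max_idx]
    sel = vals[voi]
    return VoiStats(
        mask=voi,
        mean_dose_mgy=float(sel.mean()),
        max_dose_mgy=vmax,
        volume_ml=float(voi.sum()) * dose.voxel_volume_ml,
        cutoff_fraction=float(cutoff_fraction),
    )


def pearson(a, b) -> float:
    """Product-moment correlation of paired dose estimates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise VoxdoseError("pearson needs matching 1-D arrays with n >= 3")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise VoxdoseError("pearson inputs must be finite")
    if a.std() == 0 or b.std() == 0:
        raise VoxdoseError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def bland_altman(a, b) -> dict:
    """Bland–Altman agreement summary for paired estimates (a - b differences).

    Returns the mean difference, ±1.96-SD limits of agreement and the paired
    (mean, difference) table; plotting is left to the caller.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise VoxdoseError("bland_altman needs matching 1-D arrays")
    if len(a) < 2:
        raise VoxdoseError("bland_altman needs n >= 2")
    diff = a - b
    mean = (a + b) / 2.0
    sd = float(diff.std(ddof=1))
    md = float(diff.mean())
    return {
        "mean_difference": md,
        "sd_difference": sd,
        "limits_of_agreement": (md - 1.96 * sd, md + 1.96 * sd),
        "pairs": [{"mean": float(m), "difference": float(d)} for m, d in zip(mean, diff)],
    }
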