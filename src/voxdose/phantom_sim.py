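"""Synthetic SPECT/CT studies with known ground truth.

Two families of digital objects are generated:

* A Jaszczak-style cylindrical quality-control phantom — uniform activity
  compartment, cold spheres (contrast), fan sectors of cold rods (resolution)
  and an optional external fiducial source — imaged under known rigid rotations
  about the bed (z) axis, emulating a rotation experiment of
  3 angles x 3 replicates x {with, without fiducial} = 18 studies.

* A patient-like serial study: organs with ramp-then-biexponential kinetics
  sampled at four post-injection time points, a CT with a bone region, and the
  closed-form per-voxel time-integrated activity (TIA) as ground truth.

Geometry is evaluated analytically at voxel centers (no anti-aliasing):
partial-volume effects enter only through the simulated point-spread function.
Because membership is analytic, a rotated phantom is generated exactly — the
grid coordinates are pulled back through the inverse transform before
classification — so registration ground truth carries no interpolation error.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .transforms import RigidTransform
from .volumes_io import TimeSeriesVolume, ValueKind, Volume3D

__all__ = [
    "FiducialSpec",
    "PhantomSpec",
    "KineticGroundTruth",
    "Organ",
    "PhantomStudy",
    "PatientGroundTruth",
    "CalibrationFactor",
    "make_phantom",
    "simulate_acquisition",
    "make_rotation_study",
    "make_patient_series",
    "default_organs",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class FiducialSpec:
    """External fiducial source: a small sphere outside the phantom body."""

    volume_ml: float = 3.0
    position_mm: tuple[float, float, float] = (125.0, 0.0, 0.0)
    concentration_mbq_per_ml: float = 740.0 / 6100.0

    @property
    def radius_mm(self) -> float:
        return (3.0 * self.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Jaszczak-style phantom geometry and fill.

    Defaults describe a 21.6-cm-bore cylinder whose fillable volume (cylinder
    minus cold inserts) is ~6.1 L, filled with 740 MBq of solution
    (concentration 740/6100 MBq/mL).  Sphere and rod diameters are typical
    cold-insert sets and are fully configurable.
    """

    cylinder_radius: float = 108.0          # mm
    cylinder_height: float = 174.0          # mm (fillable volume minus inserts ~6.1 L)
    activity_concentration: float = 740.0 / 6100.0   # MBq/mL
    sphere_radii: tuple[float, ...] = (4.75, 6.35, 7.95, 9.55, 12.7, 15.9)  # mm
    sphere_ring_radius: float = 60.0        # mm, spheres sit on this circle
    sphere_plane_z: float = 25.0            # mm (uniform compartment above)
    rod_sector_diameters: tuple[float, ...] = (4.8, 6.4, 7.9, 9.5, 11.1, 12.7)  # mm
    rod_region_radius: float = 95.0         # mm, outer radius of the rod fans
    rod_z_range: tuple[float, float] = (-85.0, 3.0)  # mm, rod axial extent
    fiducial: FiducialSpec | None = None
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    shell_thickness: float = 8.0            # mm acrylic wall for the CT
    hu_water: float = 0.0
    hu_air: float = -1000.0
    hu_acrylic: float = 120.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("sphere_radii", "rod_sector_diameters", "rod_z_range",
                    "grid_shape", "voxel_spacing"):
            d[key] = list(d[key])
        if self.fiducial is not None:
            d["fiducial"]["position_mm"] = list(self.fiducial.position_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if d.get("fiducial") is not None:
            fid = dict(d["fiducial"])
            if "position_mm" in fid:
                fid["position_mm"] = tuple(fid["position_mm"])
            d["fiducial"] = FiducialSpec(**fid)
        for key in ("sphere_radii", "rod_sector_diameters", "rod_z_range",
                    "grid_shape", "voxel_spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def validate(self) -> None:
        if self.cylinder_radius <= 0 or self.cylinder_height <= 0:
            raise ConfigurationError("cylinder radius and height must be positive")
        if self.activity_concentration < 0:
            raise ConfigurationError("activity concentration must be non-negative")
        if any(r <= 0 for r in self.sphere_radii):
            raise ConfigurationError("sphere radii must all be positive")
        if any(d <= 0 for d in self.rod_sector_diameters):
            raise ConfigurationError("rod diameters must all be positive")
        if any(n < 32 for n in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be >= 32 per axis, got {self.grid_shape}")
        half_h = self.cylinder_height / 2.0
        for r in self.sphere_radii:
            if self.sphere_ring_radius + r > self.cylinder_radius:
                raise ConfigurationError(
                    f"sphere of radius {r} mm at ring radius {self.sphere_ring_radius} mm "
                    "extends outside the cylinder"
                )
            if abs(self.sphere_plane_z) + r > half_h:
                raise ConfigurationError(f"sphere of radius {r} mm extends past the cylinder end")
        if self.rod_sector_diameters:
            if self.rod_region_radius > self.cylinder_radius:
                raise ConfigurationError("rod region extends outside the cylinder")
            z0, z1 = self.rod_z_range
            if not (-half_h <= z0 < z1 <= half_h):
                raise ConfigurationError(
                    f"rod z range {self.rod_z_range} not inside the cylinder")
        if self.fiducial is not None:
            f = self.fiducial
            d_axis = float(np.hypot(f.position_mm[0], f.position_mm[1]))
            if d_axis - f.radius_mm < self.cylinder_radius:
                raise ConfigurationError(
                    f"fiducial at {f.position_mm} overlaps the cylinder body"
                )
            half_extent = (np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.voxel_spacing)
            if np.any(np.abs(np.asarray(f.position_mm)) + f.radius_mm > half_extent):
                raise ConfigurationError(f"fiducial at {f.position_mm} lies outside the grid")


def _rod_centers(spec: PhantomSpec) -> list[tuple[np.ndarray, float]]:
    """Per sector: (centers (N, 2) array, rod radius). Triangular lattice, pitch 2d."""
    out = []
    n_sect = len(spec.rod_sector_diameters)
    if n_sect == 0:
        return out
    sector_span = 360.0 / n_sect
    r_inner = 12.0
    for s, d in enumerate(spec.rod_sector_diameters):
        pitch = 2.0 * d
        ys = np.arange(-spec.rod_region_radius, spec.rod_region_radius + pitch,
                       pitch * np.sqrt(3.0) / 2.0)
        pts = []
        for row, y in enumerate(ys):
            xs = np.arange(-spec.rod_region_radius, spec.rod_region_radius + pitch, pitch)
            if row % 2:
                xs = xs + pitch / 2.0
            pts.append(np.column_stack([xs, np.full_like(xs, y)]))
        pts = np.concatenate(pts)
        rad = np.hypot(pts[:, 0], pts[:, 1])
        ang = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
        lo, hi = s * sector_span, (s + 1) * sector_span
        with np.errstate(invalid="ignore"):
            margin = np.degrees(np.arcsin(np.clip((d / 2.0 + 1.0) / np.maximum(rad, 1e-9), 0, 1)))
        keep = (
            (rad >= r_inner + d / 2.0)
            & (rad <= spec.rod_region_radius - d / 2.0)
            & (ang >= lo + margin)
            & (ang <= hi - margin)
        )
        out.append((pts[keep], d / 2.0))
    return out


def _sphere_centers(spec: PhantomSpec) -> list[tuple[np.ndarray, float]]:
    n = len(spec.sphere_radii)
    out = []
    for i, r in enumerate(spec.sphere_radii):
        theta = 2.0 * np.pi * i / max(n, 1)
        c = np.array([
            spec.sphere_ring_radius * np.cos(theta),
            spec.sphere_ring_radius * np.sin(theta),
            spec.sphere_plane_z,
        ])
        out.append((c, r))
    return out


def _centered_grid(spec: PhantomSpec) -> Volume3D:
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.voxel_spacing)
    origin = tuple(-(np.asarray(shape) - 1) / 2.0 * np.asarray(spacing))
    return Volume3D(np.zeros(shape), spacing, origin, value_kind=ValueKind.ACTIVITY_MBQ)


def make_phantom(
    spec: PhantomSpec,
    transform: RigidTransform | None = None,
) -> tuple[Volume3D, Volume3D]:
    """Voxelize the phantom; returns (activity, ct).

    ``transform`` (reference→target) generates the phantom as seen in the
    *target* frame: each voxel center is pulled back through the inverse
    transform before analytic membership classification, so rotated studies
    are exact, not interpolated.

    Activity values are MBq per voxel (concentration x voxel volume); CT is in
    HU with water inside, an acrylic shell, and air outside.
    """
    spec.validate()
    grid = _centered_grid(spec)
    X, Y, Z = grid.world_coordinates()
    if transform is not None:
        inv = transform.inverse()
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        pts = inv.apply(pts)
        X = pts[:, 0].reshape(grid.shape)
        Y = pts[:, 1].reshape(grid.shape)
        Z = pts[:, 2].reshape(grid.shape)

    half_h = spec.cylinder_height / 2.0
    rad2 = X ** 2 + Y ** 2
    in_cyl = (rad2 <= spec.cylinder_radius ** 2) & (np.abs(Z) <= half_h)

    cold = np.zeros(grid.shape, dtype=bool)
    for c, r in _sphere_centers(spec):
        cold |= ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) <= r ** 2

    z0, z1 = spec.rod_z_range
    in_rod_z = (Z >= z0) & (Z <= z1) & in_cyl & (rad2 <= spec.rod_region_radius ** 2)
    if in_rod_z.any():
        sel = np.flatnonzero(in_rod_z.ravel())
        xy = np.column_stack([X.ravel()[sel], Y.ravel()[sel]])
        hit = np.zeros(len(sel), dtype=bool)
        for centers, r in _rod_centers(spec):
            if len(centers) == 0:
                continue
            dist, _ = cKDTree(centers).query(xy, k=1)
            hit |= dist <= r
        flat = cold.ravel()
        flat[sel[hit]] = True
        cold = flat.reshape(grid.shape)

    vv_ml = grid.voxel_volume_ml
    activity = np.where(in_cyl & ~cold, spec.activity_concentration * vv_ml, 0.0)

    if spec.fiducial is not None:
        f = spec.fiducial
        p = np.asarray(f.position_mm)
        in_fid = ((X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2) <= f.radius_mm ** 2
        activity = np.where(in_fid, f.concentration_mbq_per_ml * vv_ml, activity)

    shell = (
        (rad2 <= (spec.cylinder_radius + spec.shell_thickness) ** 2)
        & (np.abs(Z) <= half_h + spec.shell_thickness)
        & ~in_cyl
    )
    ct_vals = np.full(grid.shape, spec.hu_air)
    ct_vals[shell] = spec.hu_acrylic
    ct_vals[in_cyl] = spec.hu_water

    act = grid.with_values(activity, value_kind=ValueKind.ACTIVITY_MBQ)
    ct = grid.with_values(ct_vals, value_kind=ValueKind.HU)
    return act, ct


def simulate_acquisition(
    truth: Volume3D,
    psf_fwhm_mm: float = 10.0,
    total_counts: float = 6.0e7,
    seed: int | None = None,
    poisson: bool = True,
) -> Volume3D:
    """Blur with an isotropic Gaussian PSF, scale to ``total_counts`` expected
    counts, and Poisson-sample.

    With ``psf_fwhm_mm=0`` and ``poisson=False`` the output is exactly the
    scaled truth (no-op limit).  The default 10-mm FWHM matches typical
    reconstructed SPECT resolution; the default total of 6e7 counts matches a
    120-view acquisition at 500k counts per view.
    """
    if total_counts <= 0:
        raise ConfigurationError(f"total_counts must be positive, got {total_counts}")
    if psf_fwhm_mm < 0:
        raise ConfigurationError("psf_fwhm_mm must be >= 0")
    vals = truth.values
    if psf_fwhm_mm > 0:
        sigma = [psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in truth.spacing]
        vals = ndimage.gaussian_filter(vals, sigma)
    s = vals.sum()
    if s <= 0:
        raise ConfigurationError("truth volume has no activity to image")
    expected = vals * (total_counts / s)
    if poisson:
        rng = np.random.default_rng(seed)
        out = rng.poisson(expected).astype(float)
    else:
        out = expected
    return truth.with_values(out, value_kind=ValueKind.COUNTS)


@dataclass
class PhantomStudy:
    """One simulated acquisition with its exact ground-truth transform."""

    volume: Volume3D
    ground_truth: RigidTransform
    angle_deg: float
    with_fiducial: bool
    replicate: int
    seed: int


def make_rotation_study(
    spec: PhantomSpec,
    angles_deg: tuple[float, ...] = (0.0, 5.0, 10.0),
    with_fiducial: str = "both",
    replicates: int = 3,
    seed: int = 0,
    psf_fwhm_mm: float = 10.0,
    total_counts: float = 6.0e7,
    poisson: bool = True,
) -> list[PhantomStudy]:
    """Simulate the phantom rotation experiment.

    Each study is the phantom rotated clockwise about the bed (z) axis through
    the volume center — implemented as a positive Euler rz in the grid frame —
    then blurred, scaled and Poisson-sampled.  The exact applied transform is
    stored with each study.  Defaults produce 3 angles x 3 replicates x
    {with, without fiducial} = 18 studies.
    """
    if with_fiducial not in ("both", "with", "without"):
        raise ConfigurationError("with_fiducial must be 'both', 'with' or 'without'")
    fid_states = {"both": (True, False), "with": (True,), "without": (False,)}[with_fiducial]
    if spec.fiducial is not None:
        base_fid = spec.fiducial
    else:  # default marker sits just outside the cylinder wall
        base_fid = FiducialSpec()
        base_fid = dataclasses.replace(
            base_fid,
            position_mm=(spec.cylinder_radius + base_fid.radius_mm + 8.0, 0.0, 0.0),
        )
    rng = np.random.default_rng(seed)

    studies = []
    for has_fid in fid_states:
        s = dataclasses.replace(spec, fiducial=base_fid if has_fid else None)
        for angle in angles_deg:
            t = RigidTransform(rotation_deg=(0.0, 0.0, float(angle)))
            act, _ = make_phantom(s, transform=t if angle != 0.0 else None)
            for rep in range(replicates):
                study_seed = int(rng.integers(0, 2**31 - 1))
                vol = simulate_acquisition(
                    act, psf_fwhm_mm=psf_fwhm_mm, total_counts=total_counts,
                    seed=study_seed, poisson=poisson,
                )
                studies.append(PhantomStudy(vol, t, float(angle), has_fid, rep, study_seed))
    return studies


# ---------------------------------------------------------------------------
# Patient-like serial study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticGroundTruth:
    """Biexponential region kinetics: A(t) = A1 e^(-l1 t) + A2 e^(-l2 t) after
    a linear uptake ramp from zero over ``ramp_h`` hours (region totals, MBq)."""

    A1: float = 25.0          # MBq, fast component amplitude (absolute time)
    lambda1: float = 0.05     # 1/h
    A2: float = 5.0           # MBq, slow component
    lambda2: float = 0.0045   # 1/h (slightly faster than 7-day physical decay)
    ramp_h: float = 1.5

    def __post_init__(self):
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ConfigurationError("decay constants must be positive")
        if self.A1 < 0 or self.A2 < 0:
            raise ConfigurationError("amplitudes must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticGroundTruth":
        return cls(**d)

    def activity(self, t: float) -> float:
        """Region activity (MBq) at time t >= ramp_h."""
        return self.A1 * np.exp(-self.lambda1 * t) + self.A2 * np.exp(-self.lambda2 * t)

    def tia_mbq_h(self) -> float:
        """Closed-form integral 0..inf: trapezoid ramp + analytic biexponential tail."""
        tp = self.ramp_h
        return (
            0.5 * tp * self.activity(tp)
            + self.A1 / self.lambda1 * np.exp(-self.lambda1 * tp)
            + self.A2 / self.lambda2 * np.exp(-self.lambda2 * tp)
        )


@dataclass(frozen=True)
class Organ:
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    kinetics: KineticGroundTruth
    hu: float = 40.0


def default_organs() -> list[Organ]:
    """Two kidney-like spheres and a low-uptake background organ."""
    kidney = KineticGroundTruth(A1=25.0, lambda1=0.05, A2=5.0, lambda2=0.0045)
    liver = KineticGroundTruth(A1=40.0, lambda1=0.08, A2=4.0, lambda2=0.0045)
    return [
        Organ("kidney_left", (45.0, 20.0, 0.0), 24.0, kidney),
        Organ("kidney_right", (-45.0, 20.0, 0.0), 24.0, kidney),
        Organ("liver", (30.0, -40.0, 20.0), 34.0, liver),
    ]


@dataclass(frozen=True)
class CalibrationFactor:
    """Counts→activity conversion; default ~1e5 reconstructed counts per MBq."""

    mbq_per_count: float = 1.0e-5
    reference: str = "synthetic system sensitivity"

    def __post_init__(self):
        if self.mbq_per_count <= 0:
            raise ConfigurationError("calibration factor must be positive")


@dataclass
class PatientGroundTruth:
    """Analytic per-voxel TIA and helpers for dose references."""

    tia_map: Volume3D                       # MBq*s per voxel
    organ_masks: dict[str, np.ndarray]
    organ_kinetics: dict[str, KineticGroundTruth]
    bone_mask: np.ndarray

    def dose_reference(self, kernels: dict, ct: Volume3D | None = None) -> Volume3D:
        """Brute-force dose map from the analytic TIA (spatial-domain
        convolution, independent of the FFT production path).

        ``kernels`` maps medium name ('soft_tissue'/'bone') to DoseKernel.
        """
        soft = kernels["soft_tissue"]
        bone = kernels.get("bone", soft)
        tia = self.tia_map.values
        src_bone = self.bone_mask
        dose = ndimage.convolve(tia * ~src_bone, soft.values[::-1, ::-1, ::-1],
                                mode="constant", cval=0.0)
        dose += ndimage.convolve(tia * src_bone, bone.values[::-1, ::-1, ::-1],
                                 mode="constant", cval=0.0)
        out = self.tia_map.with_values(np.maximum(dose, 0.0), value_kind=ValueKind.DOSE_MGY)
        return out

    def reference_voi_mean(self, dose: Volume3D, organ: str, cutoff: float = 0.40) -> float:
        """Mean dose over the analytic VOI: organ voxels >= cutoff x organ max."""
        mask = self.organ_masks[organ]
        d = dose.values[mask]
        return float(d[d >= cutoff * d.max()].mean())


def make_patient_series(
    kinetics: KineticGroundTruth | None = None,
    times_h: tuple[float, ...] = (1.5, 5.0, 24.0, 240.0),
    organs: list[Organ] | None = None,
    seed: int | None = None,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    body_radius_mm: float = 80.0,
    bone_center_mm: tuple[float, float] = (0.0, -45.0),
    bone_radius_mm: float = 15.0,
    bone_hu: float = 800.0,
    body_hu: float = 40.0,
    calibration: CalibrationFactor = CalibrationFactor(),
    noise: bool = False,
) -> tuple[TimeSeriesVolume, Volume3D, PatientGroundTruth]:
    """Generate a co-registered serial study with known kinetics.

    Returns (count series, CT in HU, ground truth).  Every organ voxel follows
    the ramp-then-biexponential model (region amplitude divided uniformly over
    the organ's voxels); counts are activity / calibration, optionally
    Poisson-sampled.  The default times are the 1–2 h / 4–6 h / 24 h / 240 h
    post-injection sampling of a therapy protocol.
    """
    times = [float(t) for t in times_h]
    if len(times) < 4:
        raise ConfigurationError("at least 4 time points are required")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ConfigurationError(f"times must be strictly increasing, got {times}")
    if organs is None:
        organs = default_organs()
        if kinetics is not None:
            organs = [
                dataclasses.replace(o, kinetics=kinetics) if o.name.startswith("kidney") else o
                for o in organs
            ]

    shape = tuple(int(n) for n in grid_shape)
    spacing = tuple(float(s) for s in voxel_spacing)
    origin = tuple(-(np.asarray(shape) - 1) / 2.0 * np.asarray(spacing))
    grid = Volume3D(np.zeros(shape), spacing, origin, value_kind=ValueKind.ACTIVITY_MBQ)
    X, Y, Z = grid.world_coordinates()

    body = (X ** 2 + Y ** 2) <= body_radius_mm ** 2
    bone = ((X - bone_center_mm[0]) ** 2 + (Y - bone_center_mm[1]) ** 2) <= bone_radius_mm ** 2
    bone &= body
    ct_vals = np.full(shape, -1000.0)
    ct_vals[body] = body_hu
    ct_vals[bone] = bone_hu

    organ_masks: dict[str, np.ndarray] = {}
    organ_kin: dict[str, KineticGroundTruth] = {}
    for o in organs:
        c = np.asarray(o.center_mm)
        m = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) <= o.radius_mm ** 2
        if not m.any():
            raise ConfigurationError(f"organ '{o.name}' covers no voxel on this grid")
        organ_masks[o.name] = m
        organ_kin[o.name] = o.kinetics
        ct_vals[m] = o.hu
    bone &= ct_vals == bone_hu  # organs take precedence where they overlap

    ct = grid.with_values(ct_vals, value_kind=ValueKind.HU)

    rng = np.random.default_rng(seed)
    volumes = []
    for t in times:
        act = np.zeros(shape)
        for o in organs:
            m = organ_masks[o.name]
            n_vox = int(m.sum())
            k = o.kinetics
            if t >= k.ramp_h:
                a = k.activity(t) / n_vox
            else:
                a = k.activity(k.ramp_h) * (t / k.ramp_h) / n_vox
            act[m] += a
        counts = act / calibration.mbq_per_count
        if noise:
            counts = rng.poisson(counts).astype(float)
        volumes.append(
            Volume3D(counts, spacing, origin, value_kind=ValueKind.COUNTS,
                     acquisition_time_h=t)
        )
    series = TimeSeriesVolume(volumes, times)

    tia = np.zeros(shape)
    for o in organs:
        m = organ_masks[o.name]
        tia[m] += o.kinetics.tia_mbq_h() / int(m.sum()) * 3600.0  # MBq*s
    truth = PatientGroundTruth(
        tia_map=grid.with_values(tia, value_kind=ValueKind.TIA_MBQ_S),
        organ_masks=organ_masks,
        organ_kinetics=organ_kin,
        bone_mask=bone,
    )
    return series, ct, truth
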