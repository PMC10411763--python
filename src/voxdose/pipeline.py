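"""End-to-end orchestration: co-registration → time-activity integration →
tissue segmentation → kernel convolution → dose map → VOI reporting, plus the
phantom rotation-experiment harness.

Every file-based stage writes its output before the next stage starts, so a
failed run leaves completed intermediates behind; the manifest records the
configuration hash, seed, per-stage wall times and SHA-256 of every artifact.
Wall times are informational only.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dosimetry, kinetics, quality, registration
from .errors import StageError
from .phantom_sim import (
    CalibrationFactor,
    PhantomSpec,
    PhantomStudy,
    make_rotation_study,
)
from .transforms import RigidTransform
from .volumes_io import (
    TimeSeriesVolume,
    Volume3D,
    read_dicom_series,
    read_nifti,
    resample_to_grid,
    write_dicom_series,
    write_nifti,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_patient_pipeline",
    "run_dosimetry",
    "run_phantom_experiment",
]


@dataclass
class PipelineConfig:
    """Configuration for one dosimetry run; serializes to/from YAML."""

    series_paths: list[str]
    ct_path: str
    times_h: list[float]
    out_dir: str
    mbq_per_count: float = 1.0e-5
    radionuclide: str = "Lu177"
    kernel_paths: dict[str, str] | None = None   # medium -> file; None -> toy kernels
    voi_seeds_mm: list[tuple[float, float, float]] = field(default_factory=list)
    voi_cutoff: float = 0.40
    bone_cutoff_hu: float = 300.0
    noise_floor_fraction: float = 0.01
    registration: registration.RegistrationConfig = field(
        default_factory=registration.RegistrationConfig
    )
    seed: int = 0

    def validate(self) -> None:
        if len(self.series_paths) != len(self.times_h):
            raise StageError("validate", "one acquisition time per series path is required")
        for p in [*self.series_paths, self.ct_path]:
            if not Path(p).exists():
                raise StageError("validate", f"input path does not exist: {p}")
        if self.kernel_paths is not None:
            for m, p in self.kernel_paths.items():
                if not Path(p).exists():
                    raise StageError("kernels", f"kernel file for '{m}' does not exist: {p}")

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["registration"] = dataclasses.asdict(self.registration)
        Path(path).write_text(yaml.safe_dump(d))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        reg = d.pop("registration", None)
        cfg = cls(**d)
        if reg:
            cfg.registration = registration.RegistrationConfig(**reg)
        return cfg

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["registration"] = dataclasses.asdict(self.registration)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def _load_volume(path: str | Path) -> Volume3D:
    p = Path(path)
    if p.is_dir():
        return read_dicom_series(p)
    return read_nifti(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_patient_pipeline(
    series: TimeSeriesVolume,
    ct: Volume3D,
    cal: CalibrationFactor,
    radionuclide: str = "Lu177",
    reg_config: registration.RegistrationConfig | None = None,
    kernels: dict[str, dosimetry.DoseKernel] | None = None,
    voi_seeds_mm: list[tuple[float, float, float]] | None = None,
    voi_cutoff: float = 0.40,
    bone_cutoff_hu: float = 300.0,
    noise_floor_fraction: float = 0.01,
    register: bool = True,
) -> dict:
    """In-memory core of the dosimetry flow; returns all stage products.

    Later time points are registered (and resliced) to the first acquisition;
    the CT is resampled to the emission grid if needed.
    """
    reg_config = reg_config or registration.RegistrationConfig()
    reference = series.volumes[0]

    registered = [reference]
    reg_results = [None]
    if register:
        for v in series.volumes[1:]:
            res = registration.register_rigid(reference, v, reg_config)
            registered.append(registration.reslice(v, res.transform, reference))
            reg_results.append(res)
    else:
        registered = list(series.volumes)
        reg_results = [None] * len(series.volumes)
    reg_series = TimeSeriesVolume(registered, series.times_h)

    tia = kinetics.tia_map(
        reg_series, cal,
        kinetics.TiaConfig(
            noise_floor_fraction=noise_floor_fraction,
            half_life_h=dosimetry.RADIONUCLIDES[radionuclide]["half_life_h"],
        ),
    )

    ct_on_grid = ct if ct.same_grid(reference) else resample_to_grid(ct, reference)
    tissue = dosimetry.segment_bone(ct_on_grid, cutoff_hu=bone_cutoff_hu)

    if kernels is None:
        kernels = {
            m: dosimetry.generate_toy_kernel(radionuclide, reference.spacing, medium=m)
            for m in ("soft_tissue", "bone")
        }
    dose = dosimetry.convolve_dose(tia, kernels, tissue)

    vois = []
    for seed in voi_seeds_mm or []:
        vois.append(dosimetry.voi_by_cutoff(dose, tuple(seed), cutoff_fraction=voi_cutoff))

    return {
        "registered_series": reg_series,
        "registration_results": reg_results,
        "tia": tia,
        "ct_on_grid": ct_on_grid,
        "tissue": tissue,
        "kernels": kernels,
        "dose": dose,
        "vois": vois,
    }


def run_dosimetry(config: PipelineConfig) -> dict:
    """File-based dosimetry run; returns (and writes) the run manifest."""
    t_start = time.time()
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.time()
                logger.info(json.dumps({"stage": name, "event": "start"}))
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                wall = time.time() - self_inner.t0
                manifest["stages"][name] = {"wall_s": wall, "ok": exc_type is None}
                if exc_type is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                logger.info(json.dumps({"stage": name, "event": "end", "wall_s": wall}))
        return _Stage()

    with stage("load"):
        volumes = []
        for p, t in zip(config.series_paths, config.times_h):
            v = _load_volume(p)
            v.acquisition_time_h = float(t)
            volumes.append(v)
        series = TimeSeriesVolume(volumes, list(config.times_h))
        ct = _load_volume(config.ct_path)

    with stage("kernels"):
        if config.kernel_paths is not None:
            kernels = {m: dosimetry.load_kernel(p) for m, p in config.kernel_paths.items()}
        else:
            kernels = None

    with stage("pipeline"):
        result = run_patient_pipeline(
            series, ct,
            CalibrationFactor(mbq_per_count=config.mbq_per_count),
            radionuclide=config.radionuclide,
            reg_config=config.registration,
            kernels=kernels,
            voi_seeds_mm=config.voi_seeds_mm,
            voi_cutoff=config.voi_cutoff,
            bone_cutoff_hu=config.bone_cutoff_hu,
            noise_floor_fraction=config.noise_floor_fraction,
        )

    with stage("write"):
        for i, vol in enumerate(result["registered_series"].volumes):
            path = out_dir / f"registered_t{i}.nii.gz"
            write_nifti(vol, path)
            manifest["outputs"][f"registered_t{i}"] = {
                "path": str(path), "sha256": _sha256(path)}
        for name in ("tia", "dose"):
            path = out_dir / f"{name}.nii.gz"
            write_nifti(result[name], path)
            manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}
        dicom_dir = out_dir / "dose_dicom"
        write_dicom_series(result["dose"], dicom_dir, series_description="voxdose dose map")
        manifest["outputs"]["dose_dicom"] = {"path": str(dicom_dir)}

        reg_report = [
            None if r is None else {
                "transform": r.transform.as_dict(),
                "final_cost": r.final_cost,
                "iterations": r.iterations,
                "converged": r.converged,
                "stop_reason": r.stop_reason,
            }
            for r in result["registration_results"]
        ]
        voi_report = [
            {
                "mean_dose_mGy": v.mean_dose_mgy,
                "max_dose_mGy": v.max_dose_mgy,
                "volume_mL": v.volume_ml,
                "cutoff_fraction": v.cutoff_fraction,
            }
            for v in result["vois"]
        ]
        (out_dir / "registration.json").write_text(json.dumps(reg_report, indent=2))
        (out_dir / "voi.json").write_text(json.dumps(voi_report, indent=2))
        manifest["outputs"]["registration_report"] = {
            "path": str(out_dir / "registration.json"),
            "sha256": _sha256(out_dir / "registration.json"),
        }
        manifest["outputs"]["voi_report"] = {
            "path": str(out_dir / "voi.json"), "sha256": _sha256(out_dir / "voi.json")}

    manifest["wall_s_total"] = time.time() - t_start
    manifest["n_time_points"] = len(config.series_paths)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Phantom rotation experiment
# ---------------------------------------------------------------------------

def _default_qc_inputs(spec: PhantomSpec):
    """ROIs derived from the phantom geometry for the QC triplet."""
    # uniform compartment: top third of the cylinder, above spheres and rods
    z_lo = spec.sphere_plane_z + max(spec.sphere_radii, default=0.0) + 11.0
    z_hi = spec.cylinder_height / 2.0 - 11.0
    uni_roi = quality.CylindricalROI(
        center_xy_mm=(0.0, 0.0),
        radius_mm=0.7 * spec.cylinder_radius,
        z_range_mm=(z_lo, z_hi),
    )
    from .phantom_sim import _sphere_centers  # geometry helper
    spheres = [(tuple(c), r) for c, r in _sphere_centers(spec)]
    largest = max(spec.rod_sector_diameters)
    s = list(spec.rod_sector_diameters).index(largest)
    n_sect = len(spec.rod_sector_diameters)
    mid_deg = np.radians((s + 0.5) * 360.0 / n_sect)
    z_mid = float(np.mean(spec.rod_z_range))
    direction = np.array([np.cos(mid_deg), np.sin(mid_deg), 0.0])
    line = quality.LineProfile(
        start_mm=tuple(direction * 25.0 + np.array([0, 0, z_mid])),
        end_mm=tuple(direction * (spec.rod_region_radius - 10.0) + np.array([0, 0, z_mid])),
    )
    return uni_roi, spheres, line, largest


def _qc_report(volume: Volume3D, spec: PhantomSpec, percent_rmse_val=None,
               metadata=None, transform: RigidTransform | None = None
               ) -> quality.QCReport:
    """QC triplet with ROIs derived from the phantom geometry.

    ``transform`` places the ROIs in the frame of a (rotated, unregistered)
    study so each image is measured where its own phantom actually sits.
    """
    uni_roi, spheres, line, largest_rod = _default_qc_inputs(spec)
    if transform is not None:
        spheres = [(tuple(transform.apply(np.asarray(c))), r) for c, r in spheres]
        line = quality.LineProfile(
            tuple(transform.apply(np.asarray(line.start_mm))),
            tuple(transform.apply(np.asarray(line.end_mm))),
        )
        # the uniformity/background cylinders are symmetric about the bed
        # axis; translate their centers, keep the z extent
        c = transform.apply(np.array([*uni_roi.center_xy_mm, 0.0]))
        uni_roi = quality.CylindricalROI(tuple(c[:2]), uni_roi.radius_mm,
                                         uni_roi.z_range_mm)
    uni, per_slice = quality.uniformity(volume, uni_roi)
    # background for contrast: the same uniform compartment, smaller radius
    bg_roi = quality.CylindricalROI(
        uni_roi.center_xy_mm, 0.5 * spec.cylinder_radius, uni_roi.z_range_mm)
    con = quality.contrast(volume, spheres, bg_roi)
    rods = quality.resolution_fwhm(volume, line, min_separation_mm=2.0 * largest_rod)
    return quality.QCReport(
        percent_rmse=percent_rmse_val,
        uniformity_pct=uni,
        per_slice_uniformity=per_slice,
        contrast=con,
        fwhm_mm=[r.fwhm_mm for r in rods if r.success],
        metadata=metadata or {},
    )


def run_phantom_experiment(
    spec: PhantomSpec | None = None,
    angles_deg: tuple[float, ...] = (0.0, 5.0, 10.0),
    replicates: int = 3,
    seed: int = 0,
    reg_config: registration.RegistrationConfig | None = None,
    psf_fwhm_mm: float = 10.0,
    total_counts: float = 6.0e7,
    qc: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the rotation experiment and register every study to its
    fiducial-matched 0° reference (replicate 0).

    Returns (per-study table, per-group summary): recovered-transform errors,
    %RMSE before/after reslice and the QC triplet, grouped by
    (angle x fiducial state) as mean ± SD — the synthetic analogue of a
    registration-validation report.
    """
    spec = spec or PhantomSpec()
    reg_config = reg_config or registration.RegistrationConfig()
    studies = make_rotation_study(
        spec, angles_deg=angles_deg, replicates=replicates, seed=seed,
        psf_fwhm_mm=psf_fwhm_mm, total_counts=total_counts,
    )
    refs: dict[bool, PhantomStudy] = {}
    for st in studies:
        if st.angle_deg == min(angles_deg) and st.replicate == 0:
            refs[st.with_fiducial] = st

    rows = []
    for st in studies:
        ref = refs[st.with_fiducial]
        res = registration.register_rigid(ref.volume, st.volume, reg_config)
        resliced = registration.reslice(st.volume, res.transform, ref.volume)
        # ground truth relative to the (possibly rotated) reference study
        gt = RigidTransform(
            rotation_deg=(0.0, 0.0, st.angle_deg - ref.angle_deg),
            center=tuple(ref.volume.center_world()),
        )
        rot_err = res.transform.rotation_error_deg(gt)
        trans_err = res.transform.translation_error_mm(gt)
        row = {
            "angle_deg": st.angle_deg,
            "fiducial": st.with_fiducial,
            "replicate": st.replicate,
            "rotation_error_deg": rot_err,
            "translation_error_mm": trans_err,
            "iterations": res.iterations,
            "converged": res.converged,
            "percent_rmse_before": quality.percent_rmse(ref.volume, st.volume),
            "percent_rmse_after": quality.percent_rmse(ref.volume, resliced),
        }
        if qc:
            rep = _qc_report(resliced, spec)
            rep_ref = _qc_report(ref.volume, spec)
            row.update({
                "uniformity_pct": rep.uniformity_pct,
                "uniformity_ref_pct": rep_ref.uniformity_pct,
                "max_contrast_pct": max(c["max_contrast"] for c in rep.contrast),
                "resolution_fwhm_mm": float(np.mean(rep.fwhm_mm)) if rep.fwhm_mm else np.nan,
            })
        rows.append(row)

    table = pd.DataFrame(rows)
    grouped = table.groupby(["angle_deg", "fiducial"])
    agg_cols = [c for c in table.columns
                if c not in ("angle_deg", "fiducial", "replicate", "converged")]
    summary = grouped[agg_cols].agg(["mean", "std"]).reset_index()
    return table, summary
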