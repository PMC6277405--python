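"""File formats and reproducibility plumbing.

Volumes round-trip losslessly through MetaImage (.mhd/.raw, x fastest on
disk) via SimpleITK or NIfTI via nibabel.  Projection sets live in an
HDF5 container with a documented layout:

    /windows/<name>      (n_views, nu, nv) float32 or int32
    /orbit/angles_deg, /orbit/radii_mm     (n_views,)
    attrs: kind, pixel_pitch, rng_seed, time_per_view_s, center_mm,
           collimator (key/value text), meta_json

Run configurations are YAML; every pipeline stage writes a manifest with
the config, seeds and package version so count data can be reproduced
bit-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .collimators import (CollimatorSpec, DetectorOrbit, spec_from_text,
                          spec_to_text)
from .projector import ProjectionSet
from .volumes import VoxelVolume, check_same_grid


def write_volume(path, volume: VoxelVolume) -> None:
    """Write a volume as MetaImage (.mhd) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    if path.suffix == ".mhd":
        import SimpleITK as sitk
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing((volume.voxel_size,) * 3)
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, str(path))
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        affine = np.diag([volume.voxel_size] * 3 + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path, semantics: str = "activity_Bq") -> VoxelVolume:
    path = Path(path)
    if path.suffix == ".mhd":
        import SimpleITK as sitk
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = img.GetSpacing()
        if not np.allclose(spacing, spacing[0]):
            raise ValueError("only isotropic voxels are supported")
        return VoxelVolume(data, float(spacing[0]),
                           np.array(img.GetOrigin()), semantics)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.abs(np.diag(aff)[:3])
        if not np.allclose(spacing, spacing[0]):
            raise ValueError("only isotropic voxels are supported")
        return VoxelVolume(np.asarray(img.dataobj), float(spacing[0]),
                           aff[:3, 3].copy(), semantics)
    raise ValueError(f"unsupported volume format: {path.name}")


def read_paired_volumes(activity_path, density_path):
    """Activity + density with an explicit grid-consistency check."""
    act = read_volume(activity_path, "activity_Bq")
    den = read_volume(density_path, "density")
    check_same_grid(act, den, "activity and density")
    return act, den


def write_projections(path, projections: ProjectionSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("windows")
        for name, arr in projections.windows.items():
            g.create_dataset(name, data=arr)
        o = f.create_group("orbit")
        o.create_dataset("angles_deg", data=projections.orbit.angles_deg)
        o.create_dataset("radii_mm", data=projections.orbit.radii_mm)
        f.attrs["kind"] = projections.kind
        f.attrs["pixel_pitch"] = projections.pixel_pitch
        f.attrs["time_per_view_s"] = projections.orbit.time_per_view_s
        f.attrs["center_mm"] = projections.orbit.center_mm
        f.attrs["collimator"] = spec_to_text(projections.spec)
        f.attrs["rng_seed"] = -1 if projections.rng_seed is None \
            else projections.rng_seed
        f.attrs["meta_json"] = json.dumps(projections.meta)


def read_projections(path) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        windows = {name: ds[...] for name, ds in f["windows"].items()}
        orbit = DetectorOrbit(
            angles_deg=f["orbit/angles_deg"][...],
            radii_mm=f["orbit/radii_mm"][...],
            time_per_view_s=float(f.attrs["time_per_view_s"]),
            center_mm=np.asarray(f.attrs["center_mm"]))
        seed = int(f.attrs["rng_seed"])
        return ProjectionSet(
            windows=windows, kind=str(f.attrs["kind"]), orbit=orbit,
            spec=spec_from_text(str(f.attrs["collimator"])),
            pixel_pitch=float(f.attrs["pixel_pitch"]),
            rng_seed=None if seed < 0 else seed,
            meta=json.loads(str(f.attrs["meta_json"])))


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    phantom: dict = field(default_factory=lambda: {
        "preset": "liver", "grid": [128, 128, 90], "voxel_mm": 4.7,
        "total_activity_mbq": 100.0, "tumor_radius_mm": 20.0,
        "tumor_uptake_ratio": 5.0, "lung_shunt_fraction": 0.05})
    collimator: dict = field(default_factory=lambda: {
        "kind": "conebeam", "focal_length_cm": 50.0})
    orbit: dict = field(default_factory=lambda: {
        "n_views": 120, "time_per_view_s": 20.0})
    projector: dict = field(default_factory=lambda: {
        "n_scatter_histories": 200000, "max_order": 3})
    recon: dict = field(default_factory=lambda: {
        "n_subsets": 8, "n_iterations": 10, "scatter_mode": "mc"})
    master_seed: int = 0
    output_dir: str = "runs/out"

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def write_manifest(path, stage: str, config: dict, seed,
                   wall_time_s: float) -> None:
    manifest = {
        "stage": stage,
        "config": config,
        "seed": seed,
        "version": __version__,
        "wall_time_s": wall_time_s,
        "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(yaml.safe_dump(manifest))
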