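"""File formats and run configuration.

Volumes: NIfTI (.nii/.nii.gz) via nibabel or MetaImage (.mha/.mhd) via
SimpleITK, spacing and origin honoured, axis order x/y/z in world
millimetres.  Meshes: PLY (preferred; supports per-vertex color) or STL via
trimesh.  Per-vertex maps: diffable CSV (vertex_id, value, valid, label).
The effective configuration of a run is persisted as YAML next to its
outputs so every result can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .surface import CalibratedVolume, SurfaceMesh, VertexMap

__all__ = [
    "read_volume", "write_volume", "read_mesh", "write_mesh",
    "read_map", "write_map", "RunConfig",
]


def read_volume(path, units: str | None = None) -> CalibratedVolume:
    """Load a volume; ``units`` must state "HU" or "mg/cm3" explicitly."""
    if units not in ("HU", "mg/cm3"):
        raise ValueError("unit flag missing: pass units='HU' or 'mg/cm3'")
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(o) for o in aff[:3, 3])
        values = np.asarray(img.dataobj, dtype=float)
    elif path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
    else:
        raise ValueError(f"unknown volume format: {path.name}")
    return CalibratedVolume(values=values, spacing=spacing, origin=origin,
                            units=units)


def write_volume(volume: CalibratedVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        aff = np.diag(list(volume.spacing) + [1.0])
        aff[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.values.astype(np.float32), aff),
                 str(path))
    elif path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            volume.values.transpose(2, 1, 0).astype(np.float32))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown volume format: {path.name}")
    return path


def read_mesh(path, labels_csv=None) -> SurfaceMesh:
    """Load a PLY/STL mesh; vertex labels come from an optional CSV sidecar."""
    import trimesh

    path = Path(path)
    if path.suffix.lower() not in (".ply", ".stl"):
        raise ValueError(f"unknown mesh format: {path.name}")
    tm = trimesh.load(str(path), process=False, force="mesh")
    labels = None
    if labels_csv is not None:
        df = pd.read_csv(labels_csv)
        labels = df.sort_values("vertex_id")["label"].to_numpy(dtype=object)
    return SurfaceMesh(vertices=np.asarray(tm.vertices),
                       faces=np.asarray(tm.faces), labels=labels)


def write_mesh(mesh: SurfaceMesh, path) -> Path:
    import trimesh

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() not in (".ply", ".stl"):
        raise ValueError(f"unknown mesh format: {path.name}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    tm.export(str(path))
    return path


def write_map(vmap: VertexMap, path, mesh: SurfaceMesh | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh = mesh or vmap.mesh
    labels = (mesh.labels if mesh is not None
              else np.full(len(vmap.values), "body", dtype=object))
    pd.DataFrame({
        "vertex_id": np.arange(len(vmap.values)),
        "value": vmap.values,
        "valid": vmap.valid.astype(int),
        "label": labels,
    }).to_csv(path, index=False, float_format="%.17g")
    return path


def read_map(path, name: str | None = None,
             mesh: SurfaceMesh | None = None) -> VertexMap:
    """Load a per-vertex CSV map, validating the vertex index is complete."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"vertex_id", "value", "valid"}
    if not required <= set(df.columns):
        raise ValueError(f"{path.name}: missing columns {required - set(df.columns)}")
    ids = df["vertex_id"].to_numpy()
    expect = np.arange(ids.max() + 1 if len(ids) else 0)
    missing = np.setdiff1d(expect, ids)
    if len(missing):
        raise ValueError(f"{path.name}: missing vertex row(s) {missing[:5].tolist()}")
    if mesh is not None and len(expect) != len(mesh.vertices):
        raise ValueError(f"{path.name}: {len(expect)} rows for a mesh with "
                         f"{len(mesh.vertices)} vertices")
    df = df.sort_values("vertex_id")
    return VertexMap(name=name or path.stem,
                     values=df["value"].to_numpy(float),
                     valid=df["valid"].to_numpy(bool), mesh=mesh)


@dataclass
class RunConfig:
    """Fully serializable description of a pipeline run."""

    seed: int = 0
    # sampling geometry
    depth_out: float = 4.0
    depth_in: float = 8.0
    step: float = 0.2
    # fit
    sigma: float = 1.0
    sigma_policy: str = "fixed"       # fixed | estimate | free
    density_policy: str = "pair"      # pair | estimate | free
    noise_sd: float | None = 25.0
    # smoothing
    smoothing_fwhm: float = 5.0
    # registration
    registration: str = "identity"    # identity | deformable
    tps_smoothing: float = 1.0
    # stats
    alpha: float = 0.05
    n_perm: int = 1000

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self),
                                       sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def fit_config(self):
        from .profiles import FitConfig

        return FitConfig(sigma=self.sigma,
                         sigma_policy="fixed" if self.sigma_policy != "free" else "free",
                         noise_sd=self.noise_sd)
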