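"""Surface-based cortical maps: profile sampling, smoothing, and change maps.

A subject is a calibrated CT volume plus a triangular periosteal surface
mesh.  Density profiles are sampled along the inward normal at every vertex,
fitted (:mod:`bonemap.profiles`), and the resulting per-vertex metrics are
smoothed across the surface with a geodesic Gaussian kernel.  Interior
metrics (Cn.BMD, Ec.Th) are only meaningful on the vertebral body, where the
opposing cortices are far apart, so posterior-element vertices are masked for
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.sparse.csgraph import dijkstra
from scipy.stats import linregress

from .profiles import DensityProfile

__all__ = [
    "CalibratedVolume",
    "SurfaceMesh",
    "VertexMap",
    "BODY_ONLY_METRICS",
    "CHANGE_FLOORS",
    "effective_sigma",
    "sample_profiles",
    "smooth_vertex_map",
    "restrict_to_body",
    "percent_change_map",
    "calibrate_volume",
]

#: metrics reported for the vertebral body only (opposing cortices make the
#: interior compartment meaningless in pedicles and processes)
BODY_ONLY_METRICS = frozenset({"cn_bmd", "ec_th"})

#: per-metric baseline floors below which a per-vertex percentage change is
#: numerically meaningless (flagged invalid, not clamped)
CHANGE_FLOORS = {
    "ec_th": 0.02,     # mm
    "ct_th": 0.05,     # mm
    "ct_bmd": 10.0,    # mg/cm^3
    "cn_bmd": 10.0,    # mg/cm^3
    "cmsd": 1.0,       # mg/cm^2
}


@dataclass
class CalibratedVolume:
    """Axis-aligned voxel grid of densities in world millimetres.

    ``values`` is indexed [i, j, k] along the world x/y/z axes;
    ``spacing``/``origin`` place voxel centres at
    ``origin + index * spacing``.  ``units`` is "mg/cm3" once calibrated or
    "HU" for raw scanner output; ``calibration`` records the applied
    (slope, intercept) of the HU -> BMD line.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "mg/cm3"
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on all axes")
        if self.units not in ("mg/cm3", "HU"):
            raise ValueError(f"unknown unit flag {self.units!r}")

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class SurfaceMesh:
    """Triangular periosteal surface in world millimetres.

    ``labels`` assigns each vertex to the vertebral "body" or the
    "posterior" elements (pedicles, processes).  Normals are unit outward
    vectors; if omitted they are computed by area-weighted triangle-normal
    averaging.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    labels: np.ndarray | None = None  # "body" | "posterior" per vertex

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        if self.normals is None:
            self.normals = self._vertex_normals()
        else:
            self.normals = np.asarray(self.normals, dtype=float)
            norms = np.linalg.norm(self.normals, axis=1, keepdims=True)
            self.normals = self.normals / np.where(norms > 0, norms, 1.0)
        if self.labels is None:
            self.labels = np.full(n, "body", dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != n:
                raise ValueError("labels must cover all vertices")

    def _vertex_normals(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        tri_n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        out = np.zeros_like(v)
        for c in range(3):
            np.add.at(out, f[:, c], tri_n)
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        return out / np.where(norms > 0, norms, 1.0)

    @property
    def body_mask(self) -> np.ndarray:
        return np.asarray([lbl == "body" for lbl in self.labels])

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


@dataclass
class VertexMap:
    """One scalar metric sampled at every mesh vertex."""

    name: str
    values: np.ndarray
    valid: np.ndarray
    mesh: SurfaceMesh | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid flags must align")
        if self.mesh is not None and len(self.values) != len(self.mesh.vertices):
            raise ValueError("map length must match mesh vertex count")

    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out


def effective_sigma(normals: np.ndarray, sigma_inplane: float,
                    sigma_slice: float) -> np.ndarray:
    """Per-vertex PSF width along the profile direction.

    The scanner blur is anisotropic (in-plane vs slice); a profile sampled
    along unit normal n sees a 1-D Gaussian of variance
    ``sigma_ip^2 (nx^2 + ny^2) + sigma_sl^2 nz^2``.
    """
    n = np.asarray(normals, dtype=float)
    return np.sqrt(sigma_inplane**2 * (n[:, 0]**2 + n[:, 1]**2)
                   + sigma_slice**2 * n[:, 2]**2)


def sample_profiles(volume: CalibratedVolume, mesh: SurfaceMesh, *,
                    depth_out: float = 4.0, depth_in: float = 8.0,
                    step: float = 0.2,
                    chord_truncation: bool = True) -> list[DensityProfile]:
    """Sample a density profile along the inward normal at every vertex.

    Positions run from ``-depth_out`` (outside the bone) to ``+depth_in``
    (interior) in ``step`` increments; values are trilinearly interpolated.
    Samples outside the volume are marked missing (NaN).  When
    ``chord_truncation`` is on, samples beyond half the chord length to the
    opposing surface are dropped so the far cortex cannot contaminate the
    fit - the reason interior metrics fail in pedicles and processes.
    """
    if volume.units != "mg/cm3":
        raise ValueError("volume must be calibrated to mg/cm3 before sampling")
    offsets = np.arange(-depth_out, depth_in + 0.5 * step, step)
    inward = -mesh.normals

    chords = np.full(len(mesh.vertices), np.inf)
    if chord_truncation and len(mesh.faces):
        from ._geometry import ray_chord_lengths

        chords = ray_chord_lengths(mesh.vertices, mesh.faces,
                                   mesh.vertices, inward, offset=2 * step)

    profiles = []
    for i, (v, d) in enumerate(zip(mesh.vertices, inward)):
        pts = v[None, :] + offsets[:, None] * d[None, :]
        idx = volume.world_to_index(pts)
        vals = map_coordinates(volume.values, idx.T, order=1,
                               mode="constant", cval=np.nan)
        vals[offsets > 0.5 * chords[i]] = np.nan
        profiles.append(DensityProfile(offsets.copy(), vals, step, vertex_id=i))
    return profiles


def _edge_graph(mesh: SurfaceMesh) -> sparse.csr_matrix:
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    lengths = np.linalg.norm(mesh.vertices[edges[:, 0]]
                             - mesh.vertices[edges[:, 1]], axis=1)
    n = len(mesh.vertices)
    g = sparse.coo_matrix((lengths, (edges[:, 0], edges[:, 1])), shape=(n, n))
    return g.tocsr()


def smooth_vertex_map(vmap: VertexMap, fwhm: float,
                      mesh: SurfaceMesh | None = None) -> VertexMap:
    """Gaussian smoothing over geodesic (graph-distance) neighbourhoods.

    Serves two purposes: noise removal across the surface, and filling in
    vertices whose model fit failed - those receive the renormalized
    weighted average of their valid neighbours within 3 x FWHM.  Vertices
    with no valid neighbour in that radius stay invalid.
    """
    mesh = mesh or vmap.mesh
    if mesh is None:
        raise ValueError("smoothing needs the mesh")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    cutoff = 3.0 * fwhm
    graph = _edge_graph(mesh)
    dist = dijkstra(graph, directed=False, limit=cutoff)
    w = np.exp(-0.5 * (dist / sigma) ** 2)
    w[~np.isfinite(dist)] = 0.0
    np.fill_diagonal(w, 1.0)
    w[:, ~vmap.valid] = 0.0  # weights renormalized over valid vertices only

    totals = w.sum(axis=1)
    vals = np.where(vmap.valid, vmap.values, 0.0)
    out = np.full(len(vals), np.nan)
    ok = totals > 0
    out[ok] = (w[ok] @ vals) / totals[ok]
    return VertexMap(name=vmap.name, values=out, valid=ok, mesh=mesh)


def restrict_to_body(vmap: VertexMap, mesh: SurfaceMesh | None = None) -> VertexMap:
    """Mask posterior-element vertices for interior (body-only) metrics.

    Cn.BMD and Ec.Th cannot be measured within the spinous processes and
    pedicles (opposing cortices), so those vertices are excluded from
    summaries and rendered dark gray.  Cortical metrics pass through
    unchanged.
    """
    mesh = mesh or vmap.mesh
    if vmap.name not in BODY_ONLY_METRICS:
        return vmap
    if mesh is None or mesh.labels is None:
        raise ValueError(f"{vmap.name} is body-only and needs vertex labels")
    body = mesh.body_mask
    return VertexMap(name=vmap.name, values=vmap.values,
                     valid=vmap.valid & body, mesh=mesh)


def percent_change_map(baseline: VertexMap, followup: VertexMap,
                       *, absolute: bool = False) -> VertexMap:
    """Per-vertex change relative to baseline: ``100 (follow - base)/base``.

    Vertices whose baseline sits below the metric's floor (see
    ``CHANGE_FLOORS``) are flagged invalid rather than clamped - near-zero
    baselines (endocortical thickness especially) make the ratio blow up.
    With ``absolute`` the raw difference is returned instead.
    """
    if baseline.name != followup.name:
        raise ValueError("metric mismatch between time points")
    if len(baseline.values) != len(followup.values):
        raise ValueError("maps must live on the same (canonical) mesh")
    floor = CHANGE_FLOORS.get(baseline.name, 0.0)
    valid = baseline.valid & followup.valid & (np.abs(baseline.values) > floor)
    if absolute:
        vals = followup.values - baseline.values
        name = f"{baseline.name}_abs_change"
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 100.0 * (followup.values - baseline.values) / baseline.values
        name = f"{baseline.name}_pct_change"
    vals = np.where(valid, vals, np.nan)
    return VertexMap(name=name, values=vals, valid=valid,
                     mesh=baseline.mesh)


def calibrate_volume(raw: CalibratedVolume, rod_hu, rod_densities) -> CalibratedVolume:
    """Convert a raw HU volume to BMD with a calibration-phantom line.

    The subject lies on a phantom with rods of known equivalent density; an
    ordinary least-squares line through (mean rod HU, known rod density)
    converts every voxel.  Requires at least 3 rods; a rod-line R^2 below
    0.99 warns, below 0.9 the calibration is rejected.
    """
    import warnings

    rod_hu = np.asarray(rod_hu, dtype=float)
    rod_densities = np.asarray(rod_densities, dtype=float)
    if len(rod_hu) != len(rod_densities) or len(rod_hu) < 3:
        raise ValueError("calibration needs at least 3 rods")
    if raw.units != "HU":
        raise ValueError("volume already calibrated (units flag is not HU)")
    fit = linregress(rod_hu, rod_densities)
    r2 = fit.rvalue**2
    if r2 < 0.9:
        raise ValueError(f"calibration rod fit R^2={r2:.3f} < 0.9")
    if r2 < 0.99:
        warnings.warn(f"calibration rod fit R^2={r2:.4f} below 0.99",
                      stacklevel=2)
    values = fit.slope * raw.values + fit.intercept
    return CalibratedVolume(values=values, spacing=raw.spacing,
                            origin=raw.origin, units="mg/cm3",
                            calibration=(float(fit.slope), float(fit.intercept)))
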