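"""Synthetic study inputs with known ground truth.

Emulates the QCT substudy conditions end to end: per-subject baseline
cortical truth drawn from the trial's baseline distributions, per-group
12-month percentage-change distributions, per-vertex spatial heterogeneity,
Gaussian PSF blur in the ~1 mm slice-thickness regime, additive density
noise, and a Mindways-style linear HU calibration.  Every generated object
carries its ground truth so downstream accuracy is always scored against the
generator, never against the pipeline itself.

Three tiers of fixture:

* :func:`gen_profile` - one blurred, noisy 1-D density profile;
* :func:`gen_cohort` - two-time-point cohorts of profile-level subjects
  (the scale used for end-to-end recovery experiments);
* :func:`gen_shell_phantom` - a full 3-D blurred ellipsoidal shell phantom
  with mesh, labels and truth maps (exercises the volume/mesh pipeline).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import CorticalModelParams, eval_blurred
from .profiles import DensityProfile
from .surface import CalibratedVolume, SurfaceMesh, VertexMap

__all__ = [
    "GROUPS",
    "GROUP_SIZES",
    "BASELINE_TRUTH",
    "TREATMENT_EFFECTS",
    "VERTEX_FIELD_CV",
    "PhantomSpec",
    "CohortSpec",
    "SubjectRecord",
    "gen_profile",
    "gen_vertex_fields",
    "gen_subject_profiles",
    "gen_cohort",
    "gen_shell_phantom",
]

GROUPS = ("placebo", "teriparatide", "romosozumab")

#: QCT substudy arm sizes (subjects with L1 evaluable at both time points)
GROUP_SIZES = {"placebo": 20, "teriparatide": 19, "romosozumab": 17}

#: baseline cortical truth across subjects, mean +/- SD per arm
BASELINE_TRUTH = {
    "placebo": {"ct_th": (0.93, 0.08), "ct_bmd": (787.7, 53.7),
                "cn_bmd": (112.2, 17.7), "ec_th": (0.091, 0.051)},
    "teriparatide": {"ct_th": (0.91, 0.07), "ct_bmd": (799.3, 55.0),
                     "cn_bmd": (118.4, 20.4), "ec_th": (0.094, 0.042)},
    "romosozumab": {"ct_th": (0.89, 0.07), "ct_bmd": (793.6, 51.2),
                    "cn_bmd": (113.3, 24.7), "ec_th": (0.087, 0.050)},
}

#: 12-month percentage changes from baseline, mean +/- SD per arm.  CMSD is
#: not drawn - it follows from the Ct.Th and Ct.BMD draws - but its printed
#: distribution is kept for comparisons.
TREATMENT_EFFECTS = {
    "placebo": {"ct_th": (0.6, 3.4), "ct_bmd": (-0.3, 2.6),
                "cn_bmd": (-4.6, 6.1), "ec_th": (8.2, 29.7),
                "cmsd": (0.2, 2.0)},
    "teriparatide": {"ct_th": (4.3, 3.4), "ct_bmd": (-0.1, 2.8),
                     "cn_bmd": (18.1, 14.4), "ec_th": (47.5, 34.5),
                     "cmsd": (3.8, 2.7)},
    "romosozumab": {"ct_th": (10.3, 4.9), "ct_bmd": (2.1, 3.3),
                    "cn_bmd": (22.2, 6.6), "ec_th": (137.6, 80.5),
                    "cmsd": (12.4, 4.7)},
}

#: within-vertebra (per-vertex) spatial variability of the truth fields,
#: log-normal coefficient of variation around the subject mean.  Thickness
#: spreads widely within a vertebra (thin shell vs endplate rims); densities
#: are comparatively homogeneous.
VERTEX_FIELD_CV = {"ct_th": 0.45, "ec_th": 0.60, "ct_bmd": 0.06, "cn_bmd": 0.12}

Y_BG_DEFAULT = 20.0      # mg/cm^3 calibrated soft-tissue background
EC_TH_FLOOR = 0.02       # mm
X0_JITTER = 0.2          # mm; mesh placement error, uniform +/-


@dataclass
class PhantomSpec:
    """Geometry, truth and imaging model for one 3-D shell phantom.

    Truth fields may be scalars (uniform) or callables mapping world points
    (N, 3) to per-point values (spatially varying).  The slice-thickness
    presets of the study regime are 1.0 or 1.25 mm.
    """

    semi_axes: tuple[float, float, float] = (16.0, 12.0, 10.0)
    posterior: bool = False
    posterior_semi_axes: tuple[float, float, float] = (6.0, 6.0, 8.0)
    ct_th: float | object = 0.9
    ec_th: float | object = 0.1
    y_c: float | object = 790.0
    y_t: float | object = 113.0
    y_bg: float = Y_BG_DEFAULT
    sigma_inplane: float = 0.8
    sigma_slice: float = 1.0
    noise_sd: float = 25.0
    voxel: tuple[float, float, float] = (0.6, 0.6, 1.0)
    fine_step: float = 0.2
    hu_slope: float = 1.0
    hu_intercept: float = 0.0
    subdivisions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for v, f in zip(self.voxel, 3 * (self.fine_step,)):
            if abs(v / f - round(v / f)) > 1e-9:
                raise ValueError("voxel spacing must be an integer multiple "
                                 "of fine_step on every axis")
        if np.isscalar(self.ct_th) and self.ct_th <= self.fine_step:
            raise ValueError(f"ct_th={self.ct_th} mm shell is thinner than "
                             "one fine-rasterization step; refine fine_step")


@dataclass
class CohortSpec:
    """Two-time-point profile-level cohort parameterized from the trial.

    ``group_sizes``/``baseline``/``effects`` default to the study's printed
    values.  ``effect_weights`` optionally modulates the per-vertex effect
    multiplicatively (region-weighted mode for localization experiments);
    the default is a spatially uniform change.
    """

    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    baseline: dict = field(default_factory=lambda: BASELINE_TRUTH)
    effects: dict = field(default_factory=lambda: TREATMENT_EFFECTS)
    n_vertices: int = 500
    sigma: float = 1.0
    noise_sd: float = 25.0
    spacing: float = 0.2
    depth_out: float = 4.0
    depth_in: float = 8.0
    vertex_cv: dict = field(default_factory=lambda: dict(VERTEX_FIELD_CV))
    x0_jitter: float = X0_JITTER
    effect_weights: np.ndarray | None = None
    seed: int = 0


@dataclass
class SubjectRecord:
    """One simulated subject: both time points plus full ground truth."""

    group: str
    subject_id: int
    profiles_base: list
    profiles_follow: list
    truth_fields_base: dict     # per-vertex arrays: ct_th, ec_th, ct_bmd, cn_bmd
    truth_fields_follow: dict
    true_pct_change: dict       # injected subject-level % changes (incl. cmsd)
    redraws: int = 0


def gen_profile(truth: CorticalModelParams, *, spacing: float = 0.2,
                depth_out: float = 4.0, depth_in: float = 8.0,
                noise_sd: float = 0.0, seed=None,
                vertex_id: int = -1) -> DensityProfile:
    """One blurred cortical profile on a regular grid plus Gaussian noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.arange(-depth_out, depth_in + 0.5 * spacing, spacing)
    vals = eval_blurred(truth, pos)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, pos.shape)
    return DensityProfile(pos, vals, spacing, vertex_id=vertex_id)


def _lognormal_field(rng, mean, cv, n):
    """Log-normal samples with the requested arithmetic mean and CV."""
    s2 = np.log1p(cv**2)
    return mean * np.exp(rng.normal(-0.5 * s2, np.sqrt(s2), n))


def gen_vertex_fields(rng: np.random.Generator, n_vertices: int,
                      subject_means: dict,
                      vertex_cv: dict | None = None) -> dict:
    """Spatially heterogeneous per-vertex truth around a subject's means.

    Enforces the model's geometric constraints: the endocortical width is
    floored at ``EC_TH_FLOOR`` and capped so the cortex always reaches past
    the middle of the transition (x0 <= x1).
    """
    cv = vertex_cv or VERTEX_FIELD_CV
    f = {k: _lognormal_field(rng, subject_means[k], cv[k], n_vertices)
         for k in ("ct_th", "ec_th", "ct_bmd", "cn_bmd")}
    f["ec_th"] = np.clip(f["ec_th"], EC_TH_FLOOR, 2.0 * f["ct_th"] - 0.05)
    return f


def gen_subject_profiles(rng: np.random.Generator, fields: dict, *,
                         sigma: float = 1.0, noise_sd: float = 25.0,
                         spacing: float = 0.2, depth_out: float = 4.0,
                         depth_in: float = 8.0, x0_jitter: float = X0_JITTER,
                         y_bg: float = Y_BG_DEFAULT) -> list:
    """One scan: a profile for every vertex of a per-vertex truth field."""
    n = len(fields["ct_th"])
    pos = np.arange(-depth_out, depth_in + 0.5 * spacing, spacing)
    profiles = []
    for v in range(n):
        x0 = rng.uniform(-x0_jitter, x0_jitter)
        ct, ec = fields["ct_th"][v], fields["ec_th"][v]
        p = CorticalModelParams(x0, x0 + ct - ec / 2, x0 + ct + ec / 2, y_bg,
                                fields["ct_bmd"][v], fields["cn_bmd"][v],
                                sigma)
        vals = eval_blurred(p, pos) + rng.normal(0.0, noise_sd, pos.shape)
        profiles.append(DensityProfile(pos.copy(), vals, spacing, vertex_id=v))
    return profiles


def _draw_subject_means(rng, baseline_row):
    means = {}
    for k, (m, sd) in baseline_row.items():
        lo = EC_TH_FLOOR if k == "ec_th" else 0.15 * m
        for _ in range(100):
            val = rng.normal(m, sd)
            if val > lo:
                break
        else:
            val = max(m, lo)
        means[k] = max(val, lo)
    return means


def _draw_effects(rng, effect_row):
    """Per-subject % changes; redrawn (bounded) if the follow-up truth would
    become non-positive."""
    out, redraws = {}, 0
    for k, (m, sd) in effect_row.items():
        if k == "cmsd":
            continue  # derived from ct_th x ct_bmd, never drawn
        for _ in range(100):
            pct = rng.normal(m, sd)
            if 1.0 + pct / 100.0 > 0.05:
                break
            redraws += 1
        else:
            pct = m
        out[k] = pct
    return out, redraws


def gen_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Simulate every subject of a two-time-point cohort at profile level.

    Per subject: baseline truth means drawn from the arm's baseline
    distribution, per-vertex heterogeneous fields, per-metric % changes
    drawn from the arm's 12-month distribution and applied multiplicatively
    (optionally region-weighted), and both scans synthesized with the same
    PSF (same scanner at both time points).  All truths are recorded.
    """
    root = np.random.SeedSequence(spec.seed)
    subjects = []
    sid = 0
    group_seqs = root.spawn(len(spec.group_sizes))
    for (group, n_sub), gseq in zip(spec.group_sizes.items(), group_seqs):
        for sub_seq in gseq.spawn(n_sub):
            rng = np.random.default_rng(sub_seq)
            means = _draw_subject_means(rng, spec.baseline[group])
            fields_b = gen_vertex_fields(rng, spec.n_vertices, means,
                                         spec.vertex_cv)
            effects, redraws = _draw_effects(rng, spec.effects[group])
            w = (np.ones(spec.n_vertices) if spec.effect_weights is None
                 else np.asarray(spec.effect_weights, dtype=float))
            fields_f = {k: fields_b[k] * (1.0 + w * effects[k] / 100.0)
                        for k in fields_b}
            fields_f["ec_th"] = np.clip(fields_f["ec_th"], EC_TH_FLOOR,
                                        2.0 * fields_f["ct_th"] - 0.05)
            kw = dict(sigma=spec.sigma, noise_sd=spec.noise_sd,
                      spacing=spec.spacing, depth_out=spec.depth_out,
                      depth_in=spec.depth_in, x0_jitter=spec.x0_jitter)
            prof_b = gen_subject_profiles(rng, fields_b, **kw)
            prof_f = gen_subject_profiles(rng, fields_f, **kw)
            true_pct = dict(effects)
            # the injected CMSD change is the compound of the Ct.Th and
            # Ct.BMD draws (uniform effects; CMSD = 0.1 ct_th ct_bmd)
            true_pct["cmsd"] = 100.0 * ((1 + effects["ct_th"] / 100.0)
                                        * (1 + effects["ct_bmd"] / 100.0) - 1.0)
            subjects.append(SubjectRecord(
                group=group, subject_id=sid,
                profiles_base=prof_b, profiles_follow=prof_f,
                truth_fields_base=fields_b, truth_fields_follow=fields_f,
                true_pct_change=true_pct, redraws=redraws))
            sid += 1
    return subjects


# --------------------------------------------------------------------------
# 3-D shell phantom


def _ellipsoid_mesh(semi_axes, subdivisions, center=(0.0, 0.0, 0.0)):
    import trimesh

    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    verts = sphere.vertices * np.asarray(semi_axes) + np.asarray(center)
    return verts, sphere.faces.copy()


def _field_values(spec_value, points):
    if callable(spec_value):
        return np.asarray(spec_value(points), dtype=float)
    return np.full(len(points), float(spec_value))


def gen_shell_phantom(spec: PhantomSpec):
    """Rasterize, blur and encode one ellipsoidal shell phantom.

    The layered density model (background, cortical shell of local Ct.Th,
    endocortical ramp of local Ec.Th, cancellous interior) is rasterized by
    signed Euclidean distance to the periosteal surface on a fine grid,
    convolved with the anisotropic Gaussian PSF, block-averaged to the scan
    grid, degraded with noise, and encoded to HU by the inverse calibration.

    Returns ``(volume_in_HU, mesh, truth_maps)`` where truth_maps holds one
    ground-truth VertexMap per metric (including the derived CMSD).
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed)
    f = spec.fine_step
    a = np.asarray(spec.semi_axes)
    post_center = np.array([0.0, -(a[1] + 0.6 * spec.posterior_semi_axes[1]), 0.0])

    margin = 6.0 + 3.0 * max(spec.sigma_inplane, spec.sigma_slice)
    lo = -(a + margin)
    hi = a + margin
    if spec.posterior:
        lo[1] = post_center[1] - spec.posterior_semi_axes[1] - margin
    factors = np.array([round(v / f) for v in spec.voxel], dtype=int)
    # pad the fine grid so it block-averages exactly onto the scan grid
    n_coarse = np.ceil((hi - lo) / np.asarray(spec.voxel)).astype(int)
    n_fine = n_coarse * factors
    axes = [lo[d] + (np.arange(n_fine[d]) + 0.5) * f for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", copy=False)

    def signed_depth(center, semi):
        # first-order signed distance inside the surface: -F/|grad F| of the
        # implicit ellipsoid function.  Exact for spheres, sub-voxel accurate
        # near the surface for ellipsoids (which is where it matters - the
        # density is constant away from the shell).
        u = (X - center[0]) / semi[0]
        v = (Y - center[1]) / semi[1]
        w = (Z - center[2]) / semi[2]
        r = np.sqrt(u**2 + v**2 + w**2)
        g = np.sqrt((u / semi[0])**2 + (v / semi[1])**2 + (w / semi[2])**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (1.0 - r) * r / np.where(g > 0, g, 1.0)
        return np.where(r > 0, d, semi.min()).astype(np.float32)

    depth = signed_depth((0.0, 0.0, 0.0), a)
    if spec.posterior:
        depth = np.maximum(depth,
                           signed_depth(post_center,
                                        np.asarray(spec.posterior_semi_axes)))
    any_callable = any(callable(getattr(spec, k))
                       for k in ("ct_th", "ec_th", "y_c", "y_t"))
    if any_callable:
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    del X, Y, Z

    def field(value):
        if callable(value):
            return np.asarray(value(pts), dtype=np.float32).reshape(depth.shape)
        return np.float32(value)

    ct = field(spec.ct_th)
    ec = field(spec.ec_th)
    yc = field(spec.y_c)
    yt = field(spec.y_t)
    if any_callable:
        del pts
    x1 = ct - 0.5 * ec
    x2 = ct + 0.5 * ec
    frac = np.clip((depth - x1) / np.maximum(x2 - x1, np.float32(1e-6)),
                   0.0, 1.0).astype(np.float32)
    inner = np.where(depth < x1, yc, yc + frac * (yt - yc))
    # voxels average the density over their cell: soften the periosteal step
    # across one fine cell (linear transition = first-order cell average),
    # which makes the rendering converge as the fine step shrinks
    t_outer = np.clip(depth / np.float32(f) + 0.5, 0.0, 1.0).astype(np.float32)
    density = (np.float32(spec.y_bg)
               + t_outer * (inner - np.float32(spec.y_bg))).astype(np.float32)
    del depth, ct, ec, yc, yt, x1, x2, frac, inner, t_outer

    sig = (spec.sigma_inplane / f, spec.sigma_inplane / f, spec.sigma_slice / f)
    blurred = gaussian_filter(density, sigma=sig, mode="nearest")
    del density

    nb = blurred.reshape(n_coarse[0], factors[0], n_coarse[1], factors[1],
                         n_coarse[2], factors[2])
    coarse = nb.mean(axis=(1, 3, 5))
    del blurred, nb
    if spec.noise_sd > 0:
        coarse = coarse + rng.normal(0.0, spec.noise_sd, coarse.shape)
    hu = (coarse - spec.hu_intercept) / spec.hu_slope

    origin = tuple(lo[d] + 0.5 * spec.voxel[d] for d in range(3))
    volume = CalibratedVolume(values=hu, spacing=tuple(spec.voxel),
                              origin=origin, units="HU")

    verts, faces = _ellipsoid_mesh(spec.semi_axes, spec.subdivisions)
    labels = np.full(len(verts), "body", dtype=object)
    if spec.posterior:
        pv, pf = _ellipsoid_mesh(spec.posterior_semi_axes,
                                 max(spec.subdivisions - 1, 1), post_center)
        pf = pf + len(verts)
        verts = np.vstack([verts, pv])
        faces = np.vstack([faces, pf])
        labels = np.concatenate([labels, np.full(len(pv), "posterior",
                                                 dtype=object)])
    mesh = SurfaceMesh(vertices=verts, faces=faces, labels=labels)

    truth_maps = {}
    vals = {k: _field_values(getattr(spec, a_), mesh.vertices)
            for k, a_ in (("ct_th", "ct_th"), ("ec_th", "ec_th"),
                          ("ct_bmd", "y_c"), ("cn_bmd", "y_t"))}
    vals["cmsd"] = 0.1 * vals["ct_th"] * vals["ct_bmd"]
    for k, v in vals.items():
        truth_maps[k] = VertexMap(name=k, values=v,
                                  valid=np.ones(len(v), dtype=bool), mesh=mesh)
    return volume, mesh, truth_maps
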