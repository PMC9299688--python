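"""Per-vertex fitting of the blurred cortical model to sampled CT profiles.

Each mesh vertex contributes one density profile sampled along the inward
surface normal.  The blurred piecewise model (:mod:`bonemap.model`) is fitted
to the samples by bounded nonlinear least squares, recovering cortical
thickness and densities below the scan resolution.  Because jointly fitting
the PSF width and a sub-resolution thickness per profile is ill-posed, the
default policy fixes sigma per scan, estimated once from the thickest,
highest-contrast profiles (:func:`estimate_global_sigma`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares

from .model import (
    CorticalModelParams,
    DerivedMetrics,
    blurred_jacobian,
    derived_metrics,
    eval_blurred_free,
)

__all__ = [
    "DensityProfile",
    "FitConfig",
    "FitResult",
    "initialize_params",
    "fit_profile",
    "fit_profiles",
    "estimate_global_sigma",
    "estimate_global_density",
    "estimate_density_pair",
    "measure_profiles",
    "measure_profile_pair",
    "param_standard_errors",
    "cortical_mass_area",
    "fit_surface",
]

MIN_SAMPLES = 15


@dataclass
class DensityProfile:
    """Calibrated density samples along one surface normal.

    ``positions`` are mm along the inward normal (negative = outside the
    bone), strictly increasing with constant spacing.  ``values`` are
    mg/cm^3; non-finite entries mark missing samples (outside the volume or
    truncated at the opposing cortex).
    """

    positions: np.ndarray
    values: np.ndarray
    spacing: float
    vertex_id: int = -1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be matching 1-D arrays")
        d = np.diff(self.positions)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, self.spacing, rtol=1e-6)):
            raise ValueError("positions must increase with constant spacing")

    @property
    def usable(self) -> bool:
        """At least ``MIN_SAMPLES`` present samples and <30% missing."""
        ok = np.isfinite(self.values)
        return ok.sum() >= MIN_SAMPLES and ok.mean() >= 0.7


@dataclass
class FitConfig:
    """Bounds, PSF policy and screens for profile fitting.

    sigma_policy
        ``"fixed"`` — use ``sigma`` as given (per-scan estimate or known
        PSF); ``"free"`` — fit sigma per profile within ``sigma_bounds``
        (validation mode).
    noise_sd
        Expected density noise SD (mg/cm^3).  If None it is estimated per
        profile from first differences (robust MAD).  Used by the residual
        plausibility screen and the flat-profile check.
    """

    sigma: float = 1.0
    sigma_policy: str = "fixed"
    sigma_bounds: tuple[float, float] = (0.2, 3.0)
    y_c_policy: str = "free"  # "free" | "fixed" (per-scan global density)
    y_c_value: float | None = None
    x0_bounds: tuple[float, float] = (-3.0, 3.0)
    w1_max: float = 5.0  # max plateau width x1 - x0, mm
    w2_max: float = 3.0  # max endocortical slope width x2 - x1, mm
    y_bg_bounds: tuple[float, float] = (-200.0, 500.0)
    y_c_bounds: tuple[float, float] = (100.0, 2000.0)
    y_t_bounds: tuple[float, float] = (0.0, 1200.0)
    ct_th_range: tuple[float, float] = (0.05, 5.0)
    density_range: tuple[float, float] = (0.0, 2000.0)
    min_contrast: float = 50.0  # required y_c - y_t, mg/cm^3
    residual_factor: float = 3.0  # residual_rms <= factor * noise SD
    noise_sd: float | None = None
    xtol: float = 1e-9
    ftol: float = 1e-9
    max_nfev: int = 120


@dataclass
class FitResult:
    """Outcome of fitting one profile."""

    params: CorticalModelParams | None
    metrics: DerivedMetrics | None
    residual_rms: float
    converged: bool
    valid: bool
    vertex_id: int = -1
    message: str = ""


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise estimate from first differences (MAD / sqrt(2))."""
    v = values[np.isfinite(values)]
    if len(v) < 3:
        return 0.0
    d = np.diff(v)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def initialize_params(
    profile: DensityProfile, sigma: float = 1.0, noise_sd: float | None = None
) -> CorticalModelParams | None:
    """Heuristic starting point for the model fit.

    x0 at the maximum positive gradient, y_c at the profile maximum, y_bg
    and y_t as medians of the outer/inner tails, x1 at the maximum negative
    gradient inward of x0, x2 one endocortical-width guess beyond.  Returns
    None when no cortical edge exists (flat or contrast-inverted profile).
    """
    ok = np.isfinite(profile.values)
    pos = profile.positions[ok]
    raw = profile.values[ok]
    if len(raw) < MIN_SAMPLES:
        return None
    floor = noise_sd if noise_sd is not None else max(estimate_noise_sd(raw), 1.0)
    if raw.max() - raw.min() < 4.0 * floor:
        return None  # flat: no edge to fit

    # denoise before locating edges: noise spikes dominate raw gradients
    val = gaussian_filter1d(raw, sigma=1.5, mode="nearest") if floor > 1.0 else raw
    grad = np.gradient(val, pos)
    i0 = int(np.argmax(grad))
    x0 = pos[i0]
    y_c = float(val.max())
    i_pk = int(np.argmax(val))
    # negative gradient inward of the density peak
    inner = np.arange(len(pos)) > i_pk
    if not inner.any():
        return None
    i1 = int(np.argmin(np.where(inner, grad, np.inf)))
    x1 = pos[i1]
    y_bg = float(np.median(val[: max(i0, 2)])) if i0 >= 1 else float(val[0])
    y_t = float(np.median(val[min(i1 + 2, len(val) - 1):])) if i1 + 2 < len(val) else float(val[-1])
    if y_c <= y_t + 1.0 or y_c <= y_bg + 1.0:
        return None  # inverted contrast: interior at least as dense as cortex
    if x1 <= x0:
        x1 = x0 + profile.spacing
    x2 = x1 + 2.0 * profile.spacing
    try:
        return CorticalModelParams(x0, x1, x2, y_bg, y_c, max(y_t, 0.0), sigma)
    except ValueError:
        return None


def _theta_from_params(p: CorticalModelParams, free_sigma: bool) -> np.ndarray:
    theta = [p.x0, p.x1 - p.x0, p.x2 - p.x1, p.y_bg, p.y_c, p.y_t]
    if free_sigma:
        theta.append(p.sigma)
    return np.array(theta)


def _fit_once(pos, val, theta0, bounds, sigma_fixed, config):
    free_sigma = sigma_fixed is None

    def unpack(theta):
        x0, w1, w2 = theta[0], theta[1], theta[2]
        sigma = theta[6] if free_sigma else sigma_fixed
        return x0, x0 + w1, x0 + w1 + w2, theta[3], theta[4], theta[5], sigma

    def resid(theta):
        return eval_blurred_free(pos, *unpack(theta)) - val

    def jac(theta):
        x0, x1, x2, y_bg, y_c, y_t, sigma = unpack(theta)
        J = blurred_jacobian(pos, x0, x1, x2, y_bg, y_c, y_t, sigma,
                             with_sigma=free_sigma)
        # chain rule to (x0, w1, w2) parameterization
        cols = [
            J[:, 0] + J[:, 1] + J[:, 2],
            J[:, 1] + J[:, 2],
            J[:, 2],
            J[:, 3],
            J[:, 4],
            J[:, 5],
        ]
        if free_sigma:
            cols.append(J[:, 6])
        return np.stack(cols, axis=-1)

    x_scale = [1.0, 1.0, 1.0, 100.0, 100.0, 100.0] + ([1.0] if free_sigma else [])
    res = least_squares(
        resid, np.clip(theta0, bounds[0], bounds[1]), jac=jac, bounds=bounds,
        method="trf", x_scale=x_scale, xtol=config.xtol, ftol=config.ftol,
        gtol=1e-10, max_nfev=config.max_nfev,
    )
    return res, unpack(res.x)


def fit_profile(profile: DensityProfile, config: FitConfig | None = None) -> FitResult:
    """Fit the blurred cortical model to one profile.

    Bounded least squares from the heuristic start with analytic Jacobian;
    one multi-start retry (x1 perturbed by +/- 2 samples) on poor
    convergence.  ``valid`` is False when the optimizer failed, plausibility
    screens fail (Ct.Th outside ``ct_th_range``, densities outside
    ``density_range``, cortical-cancellous contrast below ``min_contrast``)
    or the residual exceeds ``residual_factor`` times the noise SD.
    """
    config = config or FitConfig()
    ok = np.isfinite(profile.values)
    if ok.sum() < MIN_SAMPLES:
        return FitResult(None, None, np.nan, False, False, profile.vertex_id,
                         "too few samples")
    pos = profile.positions[ok]
    val = profile.values[ok]
    noise_sd = config.noise_sd if config.noise_sd is not None else estimate_noise_sd(val)

    init = initialize_params(profile, config.sigma, config.noise_sd)
    if init is None:
        return FitResult(None, None, np.nan, False, False, profile.vertex_id,
                         "initialization failed (no cortical edge)")

    free_sigma = config.sigma_policy == "free"
    if config.y_c_policy == "fixed":
        if config.y_c_value is None:
            raise ValueError("y_c_policy='fixed' requires y_c_value")
        yc_lo, yc_hi = config.y_c_value - 1e-9, config.y_c_value + 1e-9
    else:
        yc_lo, yc_hi = config.y_c_bounds
    lo = [config.x0_bounds[0], 0.0, 0.0, config.y_bg_bounds[0],
          yc_lo, config.y_t_bounds[0]]
    hi = [config.x0_bounds[1], config.w1_max, config.w2_max,
          config.y_bg_bounds[1], yc_hi, config.y_t_bounds[1]]
    if free_sigma:
        lo.append(config.sigma_bounds[0])
        hi.append(config.sigma_bounds[1])
    bounds = (np.array(lo), np.array(hi))
    sigma_fixed = None if free_sigma else config.sigma

    theta0 = _theta_from_params(init, free_sigma)
    res, final = _fit_once(pos, val, theta0, bounds, sigma_fixed, config)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    # retry from a perturbed start if the fit stalled or fits poorly
    if (not res.success) or (noise_sd > 0 and rms > 2.0 * noise_sd):
        for shift in (2.0 * profile.spacing, -2.0 * profile.spacing):
            t0 = theta0.copy()
            t0[1] = max(t0[1] + shift, 0.0)
            res2, final2 = _fit_once(pos, val, t0, bounds, sigma_fixed, config)
            rms2 = float(np.sqrt(np.mean(res2.fun**2)))
            if rms2 < rms:
                res, final, rms = res2, final2, rms2
            if res.success and (noise_sd == 0 or rms <= 2.0 * noise_sd):
                break

    converged = bool(res.success)
    x0, x1, x2, y_bg, y_c, y_t, sigma = final
    try:
        params = CorticalModelParams(x0, x1, x2, y_bg, y_c, max(y_t, 0.0), sigma)
    except ValueError as exc:
        return FitResult(None, None, rms, converged, False, profile.vertex_id,
                         f"implausible optimum: {exc}")
    metrics = derived_metrics(params)

    valid = converged
    msg = ""
    if not (config.ct_th_range[0] <= metrics.ct_th <= config.ct_th_range[1]):
        valid, msg = False, "ct_th outside plausible range"
    elif not (config.density_range[0] <= y_c <= config.density_range[1]
              and config.density_range[0] <= y_t <= config.density_range[1]):
        valid, msg = False, "density outside plausible range"
    elif y_c - y_t < config.min_contrast:
        valid, msg = False, "insufficient cortical-cancellous contrast"
    elif noise_sd > 0 and rms > config.residual_factor * noise_sd:
        valid, msg = False, "residual exceeds noise screen"
    elif not converged:
        msg = "optimizer did not converge"
    return FitResult(params, metrics, rms, converged, valid, profile.vertex_id, msg)


def _config_bounds(config: FitConfig):
    if config.y_c_policy == "fixed":
        if config.y_c_value is None:
            raise ValueError("y_c_policy='fixed' requires y_c_value")
        yc_lo, yc_hi = config.y_c_value - 1e-9, config.y_c_value + 1e-9
    else:
        yc_lo, yc_hi = config.y_c_bounds
    lo = np.array([config.x0_bounds[0], 0.0, 0.0, config.y_bg_bounds[0],
                   yc_lo, config.y_t_bounds[0]])
    hi = np.array([config.x0_bounds[1], config.w1_max, config.w2_max,
                   config.y_bg_bounds[1], yc_hi, config.y_t_bounds[1]])
    return lo, hi


def _screen(config, converged, rms, noise_sd, params):
    """Plausibility screens shared by both fit engines."""
    metrics = derived_metrics(params)
    valid = converged
    msg = ""
    if not (config.ct_th_range[0] <= metrics.ct_th <= config.ct_th_range[1]):
        valid, msg = False, "ct_th outside plausible range"
    elif not (config.density_range[0] <= params.y_c <= config.density_range[1]
              and config.density_range[0] <= params.y_t <= config.density_range[1]):
        valid, msg = False, "density outside plausible range"
    elif params.y_c - params.y_t < config.min_contrast:
        valid, msg = False, "insufficient cortical-cancellous contrast"
    elif noise_sd > 0 and rms > config.residual_factor * noise_sd:
        valid, msg = False, "residual exceeds noise screen"
    elif not converged:
        msg = "optimizer did not converge"
    return metrics, valid, msg


def _fit_profiles_batched(profiles, config: FitConfig) -> list[FitResult]:
    """Vectorized fitting of profiles sharing one sample grid."""
    from ._batchfit import fit_batch

    pos = profiles[0].positions
    V = np.stack([p.values for p in profiles])
    mask = np.isfinite(V)
    n = len(profiles)

    results: list[FitResult | None] = [None] * n
    theta0 = np.zeros((n, 6))
    fitted = np.zeros(n, dtype=bool)
    noise = np.empty(n)
    for i, p in enumerate(profiles):
        if mask[i].sum() < MIN_SAMPLES or mask[i].mean() < 0.7:
            results[i] = FitResult(None, None, np.nan, False, False,
                                   p.vertex_id, "too few samples")
            continue
        noise[i] = (config.noise_sd if config.noise_sd is not None
                    else estimate_noise_sd(p.values[mask[i]]))
        init = initialize_params(p, config.sigma, config.noise_sd)
        if init is None:
            results[i] = FitResult(None, None, np.nan, False, False,
                                   p.vertex_id, "initialization failed (no cortical edge)")
            continue
        theta0[i] = _theta_from_params(init, False)
        fitted[i] = True

    idx = np.where(fitted)[0]
    if len(idx) == 0:
        return results  # type: ignore[return-value]
    lo, hi = _config_bounds(config)
    bftol = max(config.ftol, 1e-8)
    bxtol = max(config.xtol, 1e-6)
    theta, cost, conv = fit_batch(V[idx], pos, theta0[idx], lo, hi, config.sigma,
                                  mask=mask[idx], ftol=bftol, xtol=bxtol)
    npts = mask[idx].sum(1)
    rms = np.sqrt(cost / npts)
    # one multi-start retry for stalled or poorly fitting profiles
    bad = (~conv) | ((noise[idx] > 0) & (rms > 2.0 * noise[idx]))
    if bad.any():
        for shift in (2.0 * profiles[0].spacing, -2.0 * profiles[0].spacing):
            sub = np.where(bad)[0]
            t0 = theta0[idx[sub]].copy()
            t0[:, 1] = np.maximum(t0[:, 1] + shift, 0.0)
            th2, c2, cv2 = fit_batch(V[idx[sub]], pos, t0, lo, hi, config.sigma,
                                     mask=mask[idx[sub]], ftol=bftol, xtol=bxtol)
            better = c2 < cost[sub]
            theta[sub[better]] = th2[better]
            cost[sub[better]] = c2[better]
            conv[sub[better]] = cv2[better]
            rms[sub] = np.sqrt(cost[sub] / npts[sub])
            bad[sub] &= ~(cv2 & better)
            if not bad.any():
                break

    for k, i in enumerate(idx):
        p = profiles[i]
        x0, w1, w2 = theta[k, 0], theta[k, 1], theta[k, 2]
        try:
            params = CorticalModelParams(x0, x0 + w1, x0 + w1 + w2, theta[k, 3],
                                         theta[k, 4], max(theta[k, 5], 0.0),
                                         config.sigma)
        except ValueError as exc:
            results[i] = FitResult(None, None, float(rms[k]), bool(conv[k]),
                                   False, p.vertex_id, f"implausible optimum: {exc}")
            continue
        metrics, valid, msg = _screen(config, bool(conv[k]), float(rms[k]),
                                      noise[i], params)
        results[i] = FitResult(params, metrics, float(rms[k]), bool(conv[k]),
                               valid, p.vertex_id, msg)
    return results  # type: ignore[return-value]


def fit_profiles(profiles, config: FitConfig | None = None,
                 engine: str = "auto") -> list[FitResult]:
    """Fit every profile independently (order-equivariant).

    With ``engine="auto"`` profiles sharing one sample grid are fitted by the
    vectorized batch optimizer; otherwise (or with ``engine="scipy"``) each
    profile goes through :func:`fit_profile`.  Sigma must be fixed for the
    batch path; the free-sigma validation mode always uses scipy.
    """
    config = config or FitConfig()
    profiles = list(profiles)
    if (engine == "auto" and len(profiles) > 1
            and config.sigma_policy != "free"
            and all(p.positions.shape == profiles[0].positions.shape
                    and np.allclose(p.positions, profiles[0].positions)
                    for p in profiles)):
        return _fit_profiles_batched(profiles, config)
    return [fit_profile(p, config) for p in profiles]


def estimate_global_sigma(profiles, config: FitConfig | None = None) -> float:
    """Per-scan PSF width from the most informative profiles.

    Sigma is only well determined where the cortex is thick and
    high-contrast, so the top quartile of profiles by density range is
    fitted with sigma free and the median fitted sigma returned.  Falls
    back to ``config.sigma`` with a warning when fewer than 10 free fits
    succeed.
    """
    config = config or FitConfig()
    profiles = list(profiles)
    if len(profiles) < 50:
        raise ValueError("estimate_global_sigma needs at least 50 profiles")
    ranges = []
    for p in profiles:
        v = p.values[np.isfinite(p.values)]
        ranges.append(v.max() - v.min() if len(v) else 0.0)
    ranges = np.asarray(ranges)
    cut = np.quantile(ranges, 0.75)
    subset = [p for p, r in zip(profiles, ranges) if r >= cut]

    free_cfg = replace(config, sigma_policy="free")
    sigmas = []
    for p in subset:
        r = fit_profile(p, free_cfg)
        # only trust sigma from fits with a resolvable (thick) cortex
        if r.valid and r.metrics.ct_th >= r.params.sigma:
            sigmas.append(r.params.sigma)
    # one scanner has one PSF: the estimate is trusted only when (a) the
    # majority of candidate profiles support a resolvable free fit - thin
    # cortices mostly fail the screens - and (b) the accepted sigmas agree.
    disperse = (len(sigmas) >= 2
                and np.subtract(*np.percentile(sigmas, [75, 25]))
                > 0.25 * np.median(sigmas))
    if len(sigmas) < max(10, int(0.5 * len(subset))) or disperse:
        warnings.warn(
            "global sigma estimation failed (cortices too thin or fits "
            f"unstable); falling back to config default {config.sigma} mm",
            stacklevel=2,
        )
        return config.sigma
    return float(np.median(sigmas))


def param_standard_errors(result: FitResult, noise_sd: float,
                          positions: np.ndarray, *,
                          frozen_ec: bool = False) -> dict | None:
    """Linearized standard errors of the fitted parameters.

    Evaluates the analytic Jacobian at the solution and inverts the
    Gauss-Newton normal matrix; returns SEs for x0, ct_th, ec_th, y_c, y_t,
    or None when the normal matrix is singular.  With ``frozen_ec`` the
    endocortical width is treated as fixed (the anchor-fit model), which
    substantially improves the conditioning of the density SE.  These are
    local (CRLB-style) errors; near-degenerate thin-cortex fits report very
    large SEs, which is exactly what the global-density estimator uses to
    weight profiles.
    """
    if result.params is None:
        return None
    p = result.params
    J = blurred_jacobian(positions, p.x0, p.x1, p.x2, p.y_bg, p.y_c, p.y_t,
                         p.sigma)
    # chain to (x0, w1[, w2], y_bg, y_c, y_t)
    cols = [J[:, 0] + J[:, 1] + J[:, 2], J[:, 1] + J[:, 2]]
    if not frozen_ec:
        cols.append(J[:, 2])
    cols += [J[:, 3], J[:, 4], J[:, 5]]
    Jr = np.stack(cols, axis=-1)
    try:
        cov = noise_sd**2 * np.linalg.inv(Jr.T @ Jr)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)
    if np.any(var < 0):
        return None
    if frozen_ec:
        g_ct = np.array([0.0, 1.0, 0.0, 0.0, 0.0])  # ct_th = w1 (+const)
        se_ec = np.nan
        i_yc, i_yt = 3, 4
    else:
        g_ct = np.array([0.0, 1.0, 0.5, 0.0, 0.0, 0.0])  # ct_th = w1 + w2/2
        g_ec = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])
        se_ec = float(np.sqrt(g_ec @ cov @ g_ec))
        i_yc, i_yt = 4, 5
    return {
        "x0": float(np.sqrt(var[0])),
        "ct_th": float(np.sqrt(g_ct @ cov @ g_ct)),
        "ec_th": se_ec,
        "y_c": float(np.sqrt(var[i_yc])),
        "y_t": float(np.sqrt(var[i_yt])),
    }


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def cortical_mass_area(profile: DensityProfile) -> float:
    """Integrated density above the soft-tissue/interior baseline, mg/cm^3*mm.

    A PSF- and ridge-robust proxy for cortical mass (0.1 x area is close to
    CMSD): Gaussian blur conserves the integral, so the area ranks profiles
    by cortical mass without fitting.  Used to select density-anchor
    vertices.
    """
    ok = np.isfinite(profile.values)
    v = profile.values[ok]
    if len(v) < MIN_SAMPLES:
        return 0.0
    k = max(3, len(v) // 6)
    base = min(np.median(v[:k]), np.median(v[-k:]))
    return float(np.maximum(v - base, 0.0).sum() * profile.spacing)


# Anchor fits: the endocortical width is frozen (pure two-step model) because
# its freedom is what leaks noise into the plateau estimate; the resulting
# model mismatch is second order in ec_th/sigma.
_ANCHOR_MIN_CT = 1.2       # mm; anchors need a cortex >= ~1.2 x the PSF width
_ANCHOR_REF_DENSITY = 800.0  # mg/cm^3; typical vertebral Ct.BMD for the area cut
_ANCHOR_QUANTILE = 0.85    # never anchor on more than the top 15% by area
_ANCHOR_SE_FLOOR = 50.0    # mg/cm^3; cap on per-anchor precision weights


def _anchor_selection(areas: np.ndarray) -> np.ndarray:
    thr = max(_ANCHOR_MIN_CT * _ANCHOR_REF_DENSITY * 0.1,
              np.quantile(areas[areas > 0], _ANCHOR_QUANTILE))
    sel = np.where(areas >= thr)[0]
    if len(sel) < 10:  # thin-everywhere scan: fall back to the widest few
        sel = np.argsort(areas)[-15:]
    return sel


def _anchor_fits(profiles, config: FitConfig):
    """Frozen-endocortex free-density fits with inverse-variance weights."""
    anchor_cfg = replace(config, w2_max=1e-9, y_c_policy="free")
    out = []
    for p, r in zip(profiles, fit_profiles(profiles, anchor_cfg)):
        if not (r.valid and r.params is not None):
            out.append((np.nan, np.inf))
            continue
        noise = (config.noise_sd if config.noise_sd is not None
                 else estimate_noise_sd(p.values[np.isfinite(p.values)]))
        se = param_standard_errors(r, max(noise, 1.0),
                                   p.positions[np.isfinite(p.values)],
                                   frozen_ec=True)
        if se is None or not np.isfinite(se["y_c"]) or se["y_c"] <= 0:
            out.append((np.nan, np.inf))
            continue
        out.append((r.params.y_c, max(se["y_c"], _ANCHOR_SE_FLOOR)))
    return out


def estimate_global_density(profiles, config: FitConfig | None = None, *,
                            min_fits: int = 10) -> float:
    """Per-scan cortical plateau density (Ct.BMD) from anchor profiles.

    Below the PSF width, per-profile thickness and density trade off along a
    near-degenerate ridge, so the plateau density is constrained per scan the
    same way the PSF is: the profiles with the largest integrated cortical
    mass (the thickest cortices, where density *is* locally identifiable) are
    fitted with the density free and the endocortical width frozen, and the
    per-profile densities are combined by an inverse-variance weighted
    median.

    Falls back to the midpoint of ``config.y_c_bounds`` with a warning when
    fewer than ``min_fits`` anchor fits succeed.
    """
    config = config or FitConfig()
    profiles = list(profiles)
    if len(profiles) < 50:
        raise ValueError("estimate_global_density needs at least 50 profiles")

    areas = np.array([cortical_mass_area(p) for p in profiles])
    if not np.any(areas > 0):
        sel = np.array([], dtype=int)
    else:
        sel = _anchor_selection(areas)
    fits = _anchor_fits([profiles[i] for i in sel], config)
    vals = np.array([v for v, _ in fits])
    ws = np.array([1.0 / se**2 for _, se in fits])
    ok = np.isfinite(vals) & (ws > 0)
    if ok.sum() < min_fits:
        fallback = 0.5 * (config.y_c_bounds[0] + config.y_c_bounds[1])
        warnings.warn(
            "global density estimation failed (no informative cortices); "
            f"falling back to {fallback} mg/cm^3", stacklevel=2,
        )
        return fallback
    return _weighted_median(vals[ok], ws[ok])


def estimate_density_pair(profiles_base, profiles_follow,
                          config: FitConfig | None = None, *,
                          n_boot: int = 4, seed: int = 0,
                          min_fits: int = 10) -> tuple[float, float, dict]:
    """Longitudinally coupled per-scan densities for a baseline/follow-up pair.

    The same subject is scanned twice on the same scanner, so the two scans
    share anchor vertices.  The baseline level is the weighted median of the
    baseline anchor densities; the density *change* is the ratio of
    inverse-variance weighted anchor means, which cancels the (common)
    anchor-fit bias between the time points.  A small parametric bootstrap -
    anchors re-simulated from their own fitted parameters at both time
    points - removes the residual cross-talk bias that a thickness change
    induces in the estimated density change.

    Returns ``(y_c_base, y_c_follow, diagnostics)``.
    """
    config = config or FitConfig()
    pb = list(profiles_base)
    pf = list(profiles_follow)
    if len(pb) != len(pf):
        raise ValueError("paired estimation needs matched vertex collections")

    areas = 0.5 * (np.array([cortical_mass_area(p) for p in pb])
                   + np.array([cortical_mass_area(p) for p in pf]))
    sel = _anchor_selection(areas)
    fits_b = _anchor_fits([pb[i] for i in sel], config)
    fits_f = _anchor_fits([pf[i] for i in sel], config)

    def _combine(fb, ff):
        vb = np.array([v for v, _ in fb])
        vf = np.array([v for v, _ in ff])
        w = np.array([1.0 / (sb**2 + sf**2)
                      for (_, sb), (_, sf) in zip(fb, ff)])
        ok = np.isfinite(vb) & np.isfinite(vf) & (w > 0)
        if ok.sum() < min_fits:
            return None
        level = _weighted_median(vb[ok], w[ok])
        dlog = float(np.log((vf[ok] * w[ok]).sum() / (vb[ok] * w[ok]).sum()))
        return level, dlog, int(ok.sum())

    combined = _combine(fits_b, fits_f)
    if combined is None:
        y_c = estimate_global_density(pb + pf, config)
        return y_c, y_c, {"n_anchors": 0, "bias_correction": 0.0}
    level, dlog, n_ok = combined

    # parametric bootstrap: re-simulate the anchors from their fitted
    # parameters under the measured density change and subtract the bias the
    # estimator shows on that known ground truth
    bias = 0.0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pos = pb[sel[0]].positions
        # anchor-shape parameters for the simulation come from the anchor fits
        anchor_cfg = replace(config, w2_max=1e-9, y_c_policy="free")
        rb_full = fit_profiles([pb[i] for i in sel], anchor_cfg)
        rf_full = fit_profiles([pf[i] for i in sel], anchor_cfg)
        dlogs = []
        for _ in range(n_boot):
            sim_b, sim_f = [], []
            for rb, rf in zip(rb_full, rf_full):
                if rb.params is None or rf.params is None:
                    continue
                try:
                    qb = replace(rb.params, y_c=level)
                    qf = replace(rf.params, y_c=level * np.exp(dlog))
                except ValueError:
                    continue
                noise = config.noise_sd if config.noise_sd is not None else 25.0
                vb_sim = _simulate_profile(qb, pos, noise, rng)
                vf_sim = _simulate_profile(qf, pos, noise, rng)
                sim_b.append(DensityProfile(pos, vb_sim, pb[0].spacing))
                sim_f.append(DensityProfile(pos, vf_sim, pb[0].spacing))
            if len(sim_b) < min_fits:
                continue
            c = _combine(_anchor_fits(sim_b, config), _anchor_fits(sim_f, config))
            if c is not None:
                dlogs.append(c[1])
        if dlogs:
            bias = float(np.mean(dlogs) - dlog)

    dlog_corrected = dlog - bias
    y_c_b = level
    y_c_f = level * float(np.exp(dlog_corrected))
    return y_c_b, y_c_f, {"n_anchors": n_ok, "dlog": dlog,
                          "bias_correction": bias}


def _simulate_profile(params: CorticalModelParams, pos, noise_sd, rng):
    from .model import eval_blurred_free

    clean = eval_blurred_free(pos, params.x0, params.x1, params.x2,
                              params.y_bg, params.y_c, params.y_t,
                              params.sigma)
    return clean + rng.normal(0.0, noise_sd, pos.shape)


def measure_profiles(profiles, config: FitConfig | None = None, *,
                     density_policy: str = "estimate") -> tuple[list[FitResult], dict]:
    """Scan-level two-pass measurement of a profile collection.

    Pass 1 estimates the per-scan cortical density
    (:func:`estimate_global_density`) unless ``density_policy`` is "free"
    (per-profile density, validation mode) or config already fixes it;
    pass 2 fits every profile with the density constrained.  Returns the fit
    results and a dict of the effective global settings.
    """
    config = config or FitConfig()
    profiles = list(profiles)
    info = {"sigma": config.sigma, "y_c_global": None}
    if density_policy == "estimate" and config.y_c_policy != "fixed":
        y_c = estimate_global_density(profiles, config)
        config = replace(config, y_c_policy="fixed", y_c_value=y_c)
        info["y_c_global"] = y_c
    elif config.y_c_policy == "fixed":
        info["y_c_global"] = config.y_c_value
    results = fit_profiles(profiles, config)
    return results, info


def measure_profile_pair(profiles_base, profiles_follow,
                         config: FitConfig | None = None, *,
                         seed: int = 0, n_boot: int = 4):
    """Measure a baseline/follow-up pair with longitudinally coupled density.

    Estimates the per-scan densities jointly (:func:`estimate_density_pair`),
    then fits every profile of each time point with its density constrained.
    Returns ``(results_base, results_follow, info)``.
    """
    config = config or FitConfig()
    y_c_b, y_c_f, diag = estimate_density_pair(profiles_base, profiles_follow,
                                               config, seed=seed,
                                               n_boot=n_boot)
    res_b = fit_profiles(profiles_base,
                         replace(config, y_c_policy="fixed", y_c_value=y_c_b))
    res_f = fit_profiles(profiles_follow,
                         replace(config, y_c_policy="fixed", y_c_value=y_c_f))
    info = {"sigma": config.sigma, "y_c_base": y_c_b, "y_c_follow": y_c_f,
            **diag}
    return res_b, res_f, info


def fit_surface(volume, mesh, config: FitConfig | None = None, *,
                depth_out: float = 4.0, depth_in: float = 8.0,
                step: float = 0.2, sigma_policy: str | None = None,
                density_policy: str = "estimate"):
    """Fit every vertex of a mesh against a calibrated volume.

    Samples a profile per vertex (:func:`bonemap.surface.sample_profiles`),
    optionally estimates a per-scan sigma, fits each profile, and returns a
    dict of metric name -> :class:`bonemap.surface.VertexMap` with invalid
    vertices flagged for smoothing fill-in, plus the list of fit results.

    Raises RuntimeError when more than half of the usable profiles fail to
    fit, which indicates a mis-calibrated volume or a mesh/volume mismatch.
    """
    from .surface import VertexMap, sample_profiles  # local import, avoids cycle

    config = config or FitConfig()
    policy = sigma_policy or config.sigma_policy
    profiles = sample_profiles(volume, mesh, depth_out=depth_out,
                               depth_in=depth_in, step=step)
    if policy == "estimate":
        sigma = estimate_global_sigma(profiles, config)
        config = replace(config, sigma=sigma, sigma_policy="fixed")
    results, _ = measure_profiles(profiles, config, density_policy=density_policy)

    n = len(mesh.vertices)
    usable = [r for r in results if r.message != "too few samples"]
    n_valid = sum(r.valid for r in results)
    if usable and n_valid < 0.5 * len(usable):
        raise RuntimeError(
            f"only {n_valid}/{len(usable)} usable vertices produced a valid "
            "fit; check calibration, mesh placement and PSF settings"
        )

    maps = {}
    for name in ("ct_th", "ec_th", "ct_bmd", "cn_bmd", "cmsd"):
        values = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        for r in results:
            if r.valid and r.vertex_id >= 0:
                values[r.vertex_id] = getattr(r.metrics, name)
                valid[r.vertex_id] = True
        maps[name] = VertexMap(name=name, values=values, valid=valid, mesh=mesh)
    return maps, results
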