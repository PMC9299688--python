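"""Piecewise cortical density model with an endocortical slope compartment.

The cortex along a line perpendicular to the periosteal surface is modelled
as a piecewise density profile (all positions in mm along the inward surface
normal, densities in mg/cm^3):

* ``y_bg`` outside the bone (soft tissue), for ``x < x0``;
* a cortical plateau ``y_c`` between the periosteal edge ``x0`` and the start
  of the endocortical transition ``x1``;
* a linear ramp from ``y_c`` down to the cancellous density ``y_t`` over
  ``[x1, x2]`` — the endocortical transition zone;
* ``y_t`` in the trabecular interior, for ``x >= x2``.

A CT scanner observes this profile convolved with its point spread function,
modelled as a Gaussian of standard deviation ``sigma``.  Fitting the blurred
model to sampled CT values recovers the cortical parameters below the spatial
resolution of the scan.

Derived metrics follow the cortical-bone-mapping conventions:

* Ct.Th — cortical thickness, from the periosteal edge to the *midpoint* of
  the endocortical transition: ``(x1 + x2)/2 - x0``.  Cortex and endocortex
  deliberately overlap, as they do histologically.
* Ec.Th — endocortical thickness, the width of the ramp: ``x2 - x1``.
* Ct.BMD — the cortical plateau density ``y_c``.
* Cn.BMD — the cancellous density ``y_t`` directly adjacent to the endocortex.
* CMSD — cortical mass surface density, ``0.1 * Ct.Th * Ct.BMD`` in mg/cm^2:
  the cortical + endocortical mass projected onto unit surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "CorticalModelParams",
    "DerivedMetrics",
    "eval_unblurred",
    "eval_blurred",
    "derived_metrics",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(z):
    """Standard normal density."""
    return np.exp(-0.5 * np.square(z)) / _SQRT2PI


@dataclass(frozen=True)
class CorticalModelParams:
    """Parameters of one cortical density profile.

    Positions are mm along the inward surface normal (x increases from
    outside the bone toward the interior); densities are mg/cm^3.

    Attributes
    ----------
    x0 : float
        Periosteal edge position.  Expected near 0 (the mesh vertex) but
        fitted, not fixed.
    x1 : float
        Start of the endocortical slope (end of the cortical plateau).
    x2 : float
        End of the endocortical slope (start of the cancellous plateau).
    y_bg : float
        Extra-osseous (soft tissue) density.
    y_c : float
        Cortical plateau density (Ct.BMD).
    y_t : float
        Cancellous density adjacent to the endocortex (Cn.BMD).
    sigma : float
        Gaussian PSF standard deviation along the profile, mm.
    """

    x0: float
    x1: float
    x2: float
    y_bg: float
    y_c: float
    y_t: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.x0 <= self.x1 <= self.x2):
            raise ValueError(
                f"edge ordering violated: require x0 <= x1 <= x2, got "
                f"({self.x0}, {self.x1}, {self.x2})"
            )
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.y_c > self.y_bg:
            raise ValueError("cortical density y_c must exceed background y_bg")
        if not self.y_c > self.y_t:
            raise ValueError("cortical density y_c must exceed cancellous y_t")
        if self.y_t < 0:
            raise ValueError("cancellous density y_t must be nonnegative")


@dataclass(frozen=True)
class DerivedMetrics:
    """Per-profile cortical metrics derived from fitted model parameters."""

    ct_th: float  # cortical thickness, mm
    ec_th: float  # endocortical thickness, mm
    ct_bmd: float  # cortical BMD, mg/cm^3
    cn_bmd: float  # cancellous BMD, mg/cm^3
    cmsd: float  # cortical mass surface density, mg/cm^2


def eval_unblurred(params: CorticalModelParams, x):
    """Evaluate the sharp (pre-PSF) piecewise density model at ``x`` (mm).

    Vectorized over ``x``.  With ``x1 == x2`` the model degenerates to the
    classic two-step profile with a sharp endocortical boundary.
    """
    x = np.asarray(x, dtype=float)
    p = params
    out = np.full(x.shape, p.y_bg, dtype=float)
    out[x >= p.x0] = p.y_c
    if p.x2 > p.x1:
        on_slope = (x >= p.x1) & (x < p.x2)
        frac = (x[on_slope] - p.x1) / (p.x2 - p.x1)
        out[on_slope] = p.y_c + frac * (p.y_t - p.y_c)
    out[x >= p.x2] = p.y_t
    return out if out.ndim else float(out)


def _ramp_cdf(a, b, w, sigma):
    """Gaussian-blurred unit ramp 0 -> 1 over width ``w``.

    ``a = x - x1`` and ``b = x - x2``.  Uses the closed form
    ``(Psi(a) - Psi(b)) / w`` with ``Psi(u) = u * Phi(u/s) + s * phi(u/s)``
    (the antiderivative of the normal CDF); for ``w -> 0`` it reduces to a
    blurred step at the midpoint.
    """
    if w < 1e-9:
        return ndtr(0.5 * (a + b) / sigma)
    psi_a = a * ndtr(a / sigma) + sigma * _phi(a / sigma)
    psi_b = b * ndtr(b / sigma) + sigma * _phi(b / sigma)
    return (psi_a - psi_b) / w


def eval_blurred(params: CorticalModelParams, x):
    """Evaluate the PSF-blurred model: ``eval_unblurred`` convolved with a
    unit-area Gaussian of standard deviation ``sigma``.

    Closed form: the sharp model decomposes into a step of height
    ``y_c - y_bg`` at ``x0`` plus a downward unit ramp over ``[x1, x2]``
    scaled by ``y_c - y_t``; each convolves with the Gaussian analytically
    (error-function terms for the step, the standard ramp*Gaussian form for
    the slope).  Vectorized over ``x``.
    """
    p = params
    if not p.sigma > 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    step = ndtr((x - p.x0) / p.sigma)
    ramp = _ramp_cdf(x - p.x1, x - p.x2, p.x2 - p.x1, p.sigma)
    out = p.y_bg + (p.y_c - p.y_bg) * step - (p.y_c - p.y_t) * ramp
    return out if out.ndim else float(out)


def eval_blurred_free(x, x0, x1, x2, y_bg, y_c, y_t, sigma):
    """``eval_blurred`` on raw floats without parameter validation.

    Internal fast path for optimizers, which may probe points where the
    plausibility constraints (e.g. ``y_c > y_t``) are transiently violated.
    Edge ordering ``x0 <= x1 <= x2`` is still assumed.
    """
    step = ndtr((x - x0) / sigma)
    ramp = _ramp_cdf(x - x1, x - x2, x2 - x1, sigma)
    return y_bg + (y_c - y_bg) * step - (y_c - y_t) * ramp


def blurred_jacobian(x, x0, x1, x2, y_bg, y_c, y_t, sigma, *, with_sigma=False):
    """Analytic partial derivatives of :func:`eval_blurred_free`.

    Returns an ``(n, 6)`` array with columns ``d/d(x0, x1, x2, y_bg, y_c,
    y_t)`` (plus ``d/d(sigma)`` as a seventh column when ``with_sigma``).
    Used to supply exact Jacobians to the least-squares fitter.
    """
    x = np.asarray(x, dtype=float)
    u0 = (x - x0) / sigma
    phi0 = _phi(u0)
    step = ndtr(u0)
    a = x - x1
    b = x - x2
    w = x2 - x1
    if w < 1e-9:
        m = 0.5 * (a + b) / sigma
        ramp = ndtr(m)
        dr_dx1 = -0.5 * _phi(m) / sigma
        dr_dx2 = dr_dx1
        dr_ds = -m * _phi(m) / sigma
    else:
        ramp = _ramp_cdf(a, b, w, sigma)
        dr_dx1 = (ramp - ndtr(a / sigma)) / w
        dr_dx2 = (ndtr(b / sigma) - ramp) / w
        dr_ds = (_phi(a / sigma) - _phi(b / sigma)) / w

    dc = y_c - y_t
    cols = [
        -(y_c - y_bg) * phi0 / sigma,  # d/dx0
        -dc * dr_dx1,  # d/dx1
        -dc * dr_dx2,  # d/dx2
        1.0 - step,  # d/dy_bg
        step - ramp,  # d/dy_c
        ramp,  # d/dy_t
    ]
    if with_sigma:
        cols.append(-(y_c - y_bg) * u0 * phi0 / sigma - dc * dr_ds)
    return np.stack(cols, axis=-1)


def derived_metrics(params: CorticalModelParams) -> DerivedMetrics:
    """Cortical metrics implied by one fitted parameter set.

    Ct.Th spans from the periosteal edge to the midpoint of the endocortical
    transition; Ec.Th is the full transition width, so cortex and endocortex
    overlap by ``ec_th / 2``.  CMSD is ``0.1 * ct_th * ct_bmd`` exactly
    (mm * mg/cm^3 -> mg/cm^2).
    """
    p = params
    ct_th = 0.5 * (p.x1 + p.x2) - p.x0
    ec_th = p.x2 - p.x1
    return DerivedMetrics(
        ct_th=ct_th,
        ec_th=ec_th,
        ct_bmd=p.y_c,
        cn_bmd=p.y_t,
        cmsd=0.1 * ct_th * p.y_c,
    )
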