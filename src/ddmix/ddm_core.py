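"""First-passage-time distributions of the Wiener diffusion process.

This module evaluates, for a diffusion process with drift ``v``, noise SD
``s``, absorbing boundaries 0 and ``a`` and starting point ``z``:

* :func:`response_prob` — probability of absorption at a given boundary
  (closed form);
* :func:`fpt_density` — the defective first-passage density at one
  boundary, via the small-time and large-time series representations
  with an automatic switch;
* :func:`defective_cdf` — the defective RT CDF at one boundary with
  across-trial variability in drift (normal, SD ``eta``), starting point
  (uniform, range ``s_z``) and nondecision time (uniform, mean ``t_er``,
  range ``s_t``).

The variability integrals over starting point and nondecision time are
evaluated in closed form (the series integrands are exponentials and
exponential-times-sine terms); only drift variability requires numerical
quadrature (Gauss-Hermite).  :func:`defective_cdf_quadrature` provides an
independent all-quadrature reference used in the test suite.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from . import _kernels
from .params import TrialVariability, WienerParams

__all__ = [
    "response_prob",
    "response_prob_with_variability",
    "fpt_density",
    "decision_cdf",
    "defective_cdf",
    "defective_cdf_quadrature",
    "sample_first_passage",
]

#: Default relative truncation tolerance of the series evaluations.
SERIES_TOL = 1e-9

_BOUNDARIES = ("upper", "lower")


def _check_boundary(boundary: str) -> bool:
    if boundary not in _BOUNDARIES:
        raise ValueError(f"boundary must be one of {_BOUNDARIES}, got {boundary!r}")
    return boundary == "upper"


@lru_cache(maxsize=8)
def _gh_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(order)
    return x, w


def response_prob(params: WienerParams, boundary: str = "upper") -> float:
    """Probability that the process is absorbed at ``boundary``.

    Classical exponential formula: with u = 2 v / s^2,

        P(upper) = (1 - exp(-u z)) / (1 - exp(-u a)),

    reducing to z/a when v = 0.  Upper and lower probabilities sum to 1
    (absorption is almost sure).
    """
    upper = _check_boundary(boundary)
    s2 = params.s**2
    p_lower = _kernels._p_lower_avg(params.v, s2, params.z, params.z, params.a)
    return 1.0 - p_lower if upper else p_lower


def response_prob_with_variability(
    params: WienerParams,
    var: TrialVariability,
    boundary: str = "upper",
    gh_order: int = 20,
) -> float:
    """Absorption probability averaged over drift and starting-point
    variability (nondecision time does not affect which boundary wins)."""
    upper = _check_boundary(boundary)
    var.validate_for(params)
    gh_x, gh_w = _gh_nodes(gh_order)
    p_up = _kernels.prob_upper_var(
        params.a, params.z, params.v, params.s, var.eta, var.s_z, gh_x, gh_w
    )
    return p_up if upper else 1.0 - p_up


def fpt_density(t, params: WienerParams, boundary: str = "lower", tol: float = 1e-7):
    """Defective first-passage density at ``boundary`` (no across-trial
    variability), evaluated at decision time(s) ``t``.

    Uses the small-time and large-time series of the drift-free unit
    density, switching to whichever needs fewer terms for truncation
    error ``tol`` at each time point; drift and geometry enter through
    the usual exponential tilt and time rescaling.  ``t <= 0`` yields 0.
    """
    upper = _check_boundary(boundary)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    a, z, v, s = params.a, params.z, params.v, params.s
    if upper:
        z, v = a - z, -v
    w = z / a
    tt = t * s**2 / a**2  # unit-scaled time

    out = np.zeros_like(t)
    pos = tt > 0
    if np.any(pos):
        ttp = tt[pos]
        f = np.empty_like(ttp)
        # number of terms each series needs for truncation error < tol
        with np.errstate(divide="ignore", invalid="ignore"):
            kl = np.where(
                np.pi * ttp * tol < 1.0,
                np.sqrt(np.maximum(-2.0 * np.log(np.pi * ttp * tol), 0.0) / (np.pi**2 * ttp)),
                0.0,
            )
            kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(ttp)))
            ks = np.where(
                2.0 * np.sqrt(2.0 * np.pi * ttp) * tol < 1.0,
                2.0 + np.sqrt(
                    np.maximum(-2.0 * ttp * np.log(2.0 * tol * np.sqrt(2.0 * np.pi * ttp)), 0.0)
                ),
                2.0,
            )
            ks = np.maximum(ks, np.sqrt(ttp) + 1.0)
        use_small = ks < kl
        for idx in np.nonzero(use_small)[0]:
            K = int(np.ceil(ks[idx]))
            ks_range = np.arange(-((K - 1) // 2), ((K - 1) // 2) + (K - 1) % 2 + 1)
            terms = (w + 2 * ks_range) * np.exp(-((w + 2 * ks_range) ** 2) / (2 * ttp[idx]))
            f[idx] = terms.sum() / math.sqrt(2 * math.pi * ttp[idx] ** 3)
        for idx in np.nonzero(~use_small)[0]:
            K = int(np.ceil(kl[idx]))
            kk = np.arange(1, K + 1)
            f[idx] = math.pi * np.sum(
                kk * np.exp(-(kk**2) * math.pi**2 * ttp[idx] / 2.0) * np.sin(kk * math.pi * w)
            )
        tilt = np.exp(-v * z / s**2 - v**2 * t[pos] / (2 * s**2))
        out[pos] = np.maximum(f, 0.0) * tilt * s**2 / a**2
    return float(out[0]) if scalar else out


def decision_cdf(t, params: WienerParams, boundary: str = "lower", tol: float = SERIES_TOL):
    """Defective CDF of the bare decision time (no variability, no
    nondecision time) at ``boundary``."""
    upper = _check_boundary(boundary)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    ts = np.atleast_1d(t).astype(float)
    gh_x, gh_w = _gh_nodes(2)  # unused: eta = 0
    out = _kernels.defective_cdf_arr(
        ts, params.a, params.z, params.v, params.s,
        0.0, 0.0, 0.0, 0.0, upper, gh_x, gh_w, tol,
    )
    return float(out[0]) if scalar else out


def defective_cdf(
    t,
    params: WienerParams,
    var: TrialVariability,
    boundary: str = "upper",
    gh_order: int = 20,
    tol: float = SERIES_TOL,
):
    """Defective RT CDF at ``boundary`` with full across-trial variability.

    P(response at ``boundary``, RT <= t), where RT = decision time plus
    a uniform nondecision time.  As t -> inf this approaches the
    variability-averaged response probability; the upper and lower limits
    sum to 1.
    """
    upper = _check_boundary(boundary)
    var.validate_for(params)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    ts = np.atleast_1d(t).astype(float)
    gh_x, gh_w = _gh_nodes(gh_order)
    out = _kernels.defective_cdf_arr(
        ts, params.a, params.z, params.v, params.s,
        var.eta, var.s_z, var.t_er, var.s_t, upper, gh_x, gh_w, tol,
    )
    return float(out[0]) if scalar else out


def defective_cdf_quadrature(
    t,
    params: WienerParams,
    var: TrialVariability,
    boundary: str = "upper",
    gh_order: int = 20,
    gl_order: int = 10,
    tol: float = SERIES_TOL,
) -> np.ndarray:
    """All-quadrature reference for :func:`defective_cdf`.

    Gauss-Hermite over drift and Gauss-Legendre over starting point and
    nondecision time, applied to the point-parameter decision CDF.  Slower
    than :func:`defective_cdf` (which integrates the uniform variabilities
    in closed form) but entirely independent of that code path; kept for
    cross-validation.
    """
    upper = _check_boundary(boundary)
    var.validate_for(params)
    ts = np.atleast_1d(np.asarray(t, dtype=float))

    gh_x, gh_w = _gh_nodes(gh_order)
    gl_x, gl_w = np.polynomial.legendre.leggauss(gl_order)

    if var.eta > 0:
        vs = params.v + math.sqrt(2.0) * var.eta * gh_x
        wv = gh_w / math.sqrt(math.pi)
    else:
        vs, wv = np.array([params.v]), np.array([1.0])
    if var.s_z > 0:
        zs = params.z + 0.5 * var.s_z * gl_x
        wz = 0.5 * gl_w
    else:
        zs, wz = np.array([params.z]), np.array([1.0])
    if var.s_t > 0:
        ters = var.t_er + 0.5 * var.s_t * gl_x
        wt = 0.5 * gl_w
    else:
        ters, wt = np.array([var.t_er]), np.array([1.0])

    out = np.zeros_like(ts)
    for v_i, w_i in zip(vs, wv):
        for z_j, w_j in zip(zs, wz):
            p = WienerParams(a=params.a, z=z_j, v=v_i, s=params.s)
            for ter_k, w_k in zip(ters, wt):
                tau = ts - ter_k
                mask = tau > 0
                if np.any(mask):
                    out[mask] += (
                        w_i * w_j * w_k
                        * decision_cdf(tau[mask], p, boundary="upper" if upper else "lower", tol=tol)
                    )
    return out


def sample_first_passage(
    n: int,
    params: WienerParams,
    var: TrialVariability | None = None,
    dt: float = 1e-4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` first-passage trials by Euler-Maruyama.

    Uses Brownian-bridge crossing probabilities between steps, removing
    the leading discretization bias.  Returns ``(rt, upper)`` where
    ``rt`` includes the nondecision-time draw (zero if ``var`` is None)
    and ``upper`` flags absorption at the upper boundary.  Serves as the
    package's independent simulation oracle for the analytic series.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if var is None:
        var = TrialVariability()
    var.validate_for(params)
    rts, up = _kernels.euler_fpt(
        n, params.a, params.z, params.v, params.s,
        var.eta, var.s_z, var.t_er, var.s_t, dt, int(seed) % (2**31),
    )
    return rts, up.astype(bool)
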