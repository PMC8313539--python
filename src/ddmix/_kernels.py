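"""Numba kernels for Wiener first-passage quantities and the G2 objective.

All kernels work with the "lower boundary" form of the classical
eigenfunction (large-time) series for a Wiener process with drift ``v``,
noise SD ``s``, absorbing boundaries at 0 and ``a`` and starting point
``z``:

    G0(t) = P_lower - (pi s^2/a^2) * sum_k  k S_k / lam_k * exp(-lam_k t)

    S_k   = exp(-v z / s^2) * sin(k pi z / a)
    lam_k = (v^2/s^2 + k^2 pi^2 s^2 / a^2) / 2

Uniform across-trial variability in the starting point (range ``s_z``)
and in nondecision time (range ``s_t``) is integrated in closed form:
the z-average of exp(c z) sin(b z) and the time-average of exp(-lam t)
are both elementary.  Only the normal drift variability needs quadrature
(Gauss-Hermite, supplied by the caller).

Upper-boundary quantities follow from the reflection symmetry
(a, z, v) -> (a, a - z, -v).
"""

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
SQRTPI = math.sqrt(math.pi)
_EXP_CLAMP = 250.0  # keeps pathological optimizer proposals finite
_KMAX = 3000


@njit(cache=True)
def _safe_exp(x):
    if x > _EXP_CLAMP:
        return math.exp(_EXP_CLAMP)
    if x < -_EXP_CLAMP:
        return 0.0
    return math.exp(x)


@njit(cache=True)
def _expavg(beta, z1, z2):
    """Mean of exp(beta*z) over [z1, z2] (point value if z1 == z2)."""
    if z2 <= z1:
        return _safe_exp(beta * z1)
    x = beta * (z2 - z1)
    if abs(x) < 1e-12:
        return _safe_exp(beta * 0.5 * (z1 + z2))
    return _safe_exp(beta * z1) * math.expm1(x) / x


@njit(cache=True)
def _p_lower_avg(v, s2, z1, z2, a):
    """P(absorb at 0), averaged over a uniform starting point on [z1, z2]."""
    u = 2.0 * v / s2
    if abs(u) * a < 1e-9:
        return 1.0 - 0.5 * (z1 + z2) / a
    if u > 0.0:
        avg = _expavg(-u, z1, z2)
        ea = _safe_exp(-u * a)
        return (avg - ea) / (1.0 - ea)
    u2 = -u
    avg = _expavg(-u2, a - z2, a - z1)
    ea = _safe_exp(-u2 * a)
    return 1.0 - (avg - ea) / (1.0 - ea)


@njit(cache=True)
def _sinavg(c, b, z1, z2):
    """Mean of exp(c*z)*sin(b*z) over [z1, z2] (point value if z1 == z2)."""
    if z2 <= z1:
        return _safe_exp(c * z1) * math.sin(b * z1)
    den = c * c + b * b
    f2 = _safe_exp(c * z2) * (c * math.sin(b * z2) - b * math.cos(b * z2))
    f1 = _safe_exp(c * z1) * (c * math.sin(b * z1) - b * math.cos(b * z1))
    return (f2 - f1) / (den * (z2 - z1))


@njit(cache=True)
def _cdf_lower_avg_add(ts, out, w, a, z1, z2, v, s, ter_lo, ter_hi, tol):
    """Add w * [z- and t_er-averaged lower-boundary defective CDF](ts) to out.

    ``ts`` are RTs on the full scale (decision + nondecision time).
    """
    s2 = s * s
    pbar = _p_lower_avg(v, s2, z1, z2, a)
    c = -v / s2
    pref = math.pi * s2 / (a * a)
    st = ter_hi - ter_lo
    half_vv = 0.5 * v * v / s2
    pis2a2 = 0.5 * math.pi * math.pi * s2 / (a * a)
    for i in range(ts.shape[0]):
        t = ts[i]
        if t <= ter_lo:
            continue
        hi = t if t < ter_hi else ter_hi
        if st > 0.0:
            acc = pbar * (hi - ter_lo) / st
        else:
            acc = pbar
        small = 0
        k = 1
        while k <= _KMAX:
            lam = half_vv + pis2a2 * k * k
            coef = pref * k * _sinavg(c, k * math.pi / a, z1, z2) / lam
            if st > 0.0:
                term = coef * (_safe_exp(-lam * (t - hi)) - _safe_exp(-lam * (t - ter_lo))) / (lam * st)
            else:
                term = coef * _safe_exp(-lam * (t - ter_lo))
            acc -= term
            if abs(term) < tol:
                small += 1
                if small >= 3 and k >= 4:
                    break
            else:
                small = 0
            k += 1
        if acc < 0.0:
            acc = 0.0
        elif acc > 1.0:
            acc = 1.0
        out[i] += w * acc


@njit(cache=True)
def defective_cdf_arr(ts, a, zc, v, s, eta, sz, ter, st, upper, gh_x, gh_w, tol):
    """Defective CDF of (response at one boundary, RT <= t) with all
    across-trial variabilities, evaluated at each element of ``ts``."""
    out = np.zeros(ts.shape[0])
    z1 = zc - 0.5 * sz
    z2 = zc + 0.5 * sz
    ter_lo = ter - 0.5 * st
    ter_hi = ter + 0.5 * st
    if eta > 1e-12:
        for m in range(gh_x.shape[0]):
            vm = v + SQRT2 * eta * gh_x[m]
            wm = gh_w[m] / SQRTPI
            if upper:
                _cdf_lower_avg_add(ts, out, wm, a, a - z2, a - z1, -vm, s, ter_lo, ter_hi, tol)
            else:
                _cdf_lower_avg_add(ts, out, wm, a, z1, z2, vm, s, ter_lo, ter_hi, tol)
    else:
        if upper:
            _cdf_lower_avg_add(ts, out, 1.0, a, a - z2, a - z1, -v, s, ter_lo, ter_hi, tol)
        else:
            _cdf_lower_avg_add(ts, out, 1.0, a, z1, z2, v, s, ter_lo, ter_hi, tol)
    for i in range(out.shape[0]):
        if out[i] < 0.0:
            out[i] = 0.0
        elif out[i] > 1.0:
            out[i] = 1.0
    return out


@njit(cache=True)
def prob_upper_var(a, zc, v, s, eta, sz, gh_x, gh_w):
    """P(response at upper boundary), averaged over drift and start-point
    variability."""
    z1 = zc - 0.5 * sz
    z2 = zc + 0.5 * sz
    s2 = s * s
    if eta > 1e-12:
        acc = 0.0
        for m in range(gh_x.shape[0]):
            vm = v + SQRT2 * eta * gh_x[m]
            acc += gh_w[m] / SQRTPI * (1.0 - _p_lower_avg(vm, s2, z1, z2, a))
        return acc
    return 1.0 - _p_lower_avg(v, s2, z1, z2, a)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / SQRT2))


@njit(cache=True)
def _guess_cdf(t, mu, sg):
    """CDF of the zero-truncated Normal(mu, sg) guess-time distribution."""
    if t <= 0.0:
        return 0.0
    f0 = _norm_cdf(-mu / sg)
    return (_norm_cdf((t - mu) / sg) - f0) / (1.0 - f0)


@njit(cache=True)
def gsq_kernel(a5, ter5, po5, v5, eta, sz, st, mug, sg, s,
               speed_idx, contrast_idx, edges, nedges, pobs, ncell_trials,
               gh_x, gh_w, tol, pi_floor, out_cell, out_pi):
    """Total G2 = 2 sum_cells N sum_bins p ln(p/pi) for the 25-cell design.

    ``edges``: (ncell, 2, 9) observed quantile RTs (response 0 = correct /
    upper, 1 = error / lower); ``nedges``: number of edges actually used
    per response (0 means the sparse single-bin representation);
    ``pobs``: (ncell, 2, 10) observed bin proportions of all cell trials.
    Per-cell contributions and predicted bin probabilities are written to
    ``out_cell`` and ``out_pi``.
    """
    ncell = ncell_trials.shape[0]
    total = 0.0
    for ci in range(ncell):
        j = speed_idx[ci]
        i = contrast_idx[ci]
        a = a5[j]
        ter = ter5[j]
        po = po5[j]
        v = v5[i]
        zc = 0.5 * a
        if sz >= 0.999 * a or ter - 0.5 * st <= 0.0 or a <= 0.0 or sg <= 0.0:
            return 1e12
        p_up = prob_upper_var(a, zc, v, s, eta, sz, gh_x, gh_w)
        g2 = 0.0
        for r in range(2):
            p_diff = p_up if r == 0 else 1.0 - p_up
            p_resp = 0.5 * po + (1.0 - po) * p_diff
            ne = nedges[ci, r]
            if ne == 0:
                pi0 = p_resp if p_resp > pi_floor else pi_floor
                out_pi[ci, r, 0] = pi0
                p = pobs[ci, r, 0]
                if p > 0.0:
                    g2 += p * math.log(p / pi0)
            else:
                ts = edges[ci, r, :ne]
                fd = defective_cdf_arr(ts, a, zc, v, s, eta, sz, ter, st,
                                       r == 0, gh_x, gh_w, tol)
                prev = 0.0
                for b in range(ne + 1):
                    if b < ne:
                        fmix = 0.5 * po * _guess_cdf(ts[b], mug, sg) + (1.0 - po) * fd[b]
                    else:
                        fmix = p_resp
                    pib = fmix - prev
                    prev = fmix
                    if pib < pi_floor:
                        pib = pi_floor
                    out_pi[ci, r, b] = pib
                    p = pobs[ci, r, b]
                    if p > 0.0:
                        g2 += p * math.log(p / pib)
        g2 *= 2.0 * ncell_trials[ci]
        out_cell[ci] = g2
        total += g2
    return total


@njit(cache=True)
def euler_fpt(n, a, zc, v, s, eta, sz, ter, st, dt, seed):
    """Euler-Maruyama simulation of the diffusion process, ``n`` trials.

    Between-step boundary crossings are handled with the Brownian-bridge
    crossing probability, which removes the leading O(sqrt(dt)) bias of
    the naive scheme.  Returns (rt, upper) where rt includes the uniform
    nondecision time draw (pass ter = st = 0 for bare decision times).
    """
    np.random.seed(seed)
    rts = np.empty(n)
    hit_up = np.empty(n, np.uint8)
    sdt = s * math.sqrt(dt)
    inv = 2.0 / (s * s * dt)
    for i in range(n):
        vi = v + eta * np.random.randn() if eta > 0.0 else v
        x = zc + sz * (np.random.random() - 0.5) if sz > 0.0 else zc
        vdt = vi * dt
        t = 0.0
        up = 0
        while True:
            xn = x + vdt + sdt * np.random.randn()
            t += dt
            if xn >= a:
                up = 1
                break
            if xn <= 0.0:
                up = 0
                break
            # bridge crossing checks, skipped when the probability < ~1e-14
            eu = (a - x) * (a - xn) * inv
            if eu < 32.0 and np.random.random() < math.exp(-eu):
                up = 1
                break
            el = x * xn * inv
            if el < 32.0 and np.random.random() < math.exp(-el):
                up = 0
                break
            x = xn
        te = ter + st * (np.random.random() - 0.5) if st > 0.0 else ter
        rts[i] = t + te
        hit_up[i] = up
    return rts, hit_up
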