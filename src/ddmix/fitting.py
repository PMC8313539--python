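"""Quantile-based G2 estimation of the mixture-model design parameters.

Each design cell contributes up to 20 inter-quantile bins (10 per
response, delimited by the observed 0.1 ... 0.9 quantile RTs); the model
is scored by the multinomial likelihood-ratio statistic

    G2 = 2 sum_cells N sum_bins p_i ln(p_i / pi_i)

where p_i are observed and pi_i model-predicted bin proportions.  All 25
cells of one subject are fit simultaneously under the selective-influence
constraints (drift varies only with contrast; boundary separation,
nondecision time and guess probability only with speed stress), by
Nelder-Mead with random restarts.  Two fitting modifications mirror the
original procedure: guess probabilities estimated below 0.1 are fixed to
zero and the fit re-run, and boundary separation / nondecision time can
be tied across the two highest speed-stress conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _kernels
from .mixture import PI_FLOOR
from .params import DesignParams, N_CONTRAST, N_SPEED

__all__ = [
    "FitConfig",
    "FitResult",
    "QuantileSummary",
    "SparseSampleError",
    "compute_quantiles",
    "gsquare",
    "summarize_trials",
    "heuristic_start",
    "fit_subject",
    "goodness_of_fit",
    "GoodnessOfFit",
]

DEFAULT_PROBS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

#: Minimum per-response trial count for the full quantile representation;
#: below it the response is summarised by a single bin (its probability).
SPARSE_THRESHOLD = 11

#: Headline degrees of freedom of the design: (2 x 10 bins - 1) x 25 cells.
DATA_DF = 475
#: Parameters of the model as conventionally counted (5 a + 5 T_er + 5 v
#: + 5 p_o + eta + s_z + s_t + mu_g + s_g).
N_PARAMS_REPORTED = 25


class SparseSampleError(ValueError):
    """Sample too small for the requested quantile representation."""


def compute_quantiles(rts, probs=DEFAULT_PROBS) -> np.ndarray:
    """Quantile RTs by linear interpolation (type-7 convention).

    Raises :class:`SparseSampleError` when the sample is smaller than
    ``len(probs) + 1`` observations, signalling that the caller should
    fall back to the single-bin representation.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < len(probs) + 1:
        raise SparseSampleError(
            f"need >= {len(probs) + 1} observations for {len(probs)} quantiles, "
            f"got {rts.size}"
        )
    return np.quantile(rts, probs)


def gsquare(p, pi, n_trials: float, pi_floor: float = PI_FLOOR) -> float:
    """G2 = 2 N sum p_i ln(p_i / pi_i); bins with p_i = 0 contribute 0.

    Predicted proportions are floored at ``pi_floor`` before the
    logarithm; a floor actually binding on a bin with observed mass
    signals a badly mispredicted region and raises a warning.
    """
    p = np.asarray(p, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    if abs(p.sum() - 1.0) > 1e-6 or abs(pi.sum() - 1.0) > 1e-4:
        raise ValueError("observed and predicted proportions must each sum to 1")
    if np.any((pi < pi_floor) & (p > 0)):
        warnings.warn(
            "predicted probability underflow in a bin with observed mass; "
            "G2 uses the clipping floor",
            RuntimeWarning,
            stacklevel=2,
        )
    pic = np.maximum(pi, pi_floor)
    mask = p > 0
    return float(2.0 * n_trials * np.sum(p[mask] * np.log(p[mask] / pic[mask])))


@dataclass
class QuantileSummary:
    """Observed quantile representation of one subject's 25 cells.

    Arrays are ordered speed-major: cell index = (speed-1)*5 + (contrast-1).
    ``nedges`` is 9 for the full representation, 0 for the sparse
    single-bin fallback; ``pobs`` holds observed bin proportions of all
    trials in the cell (rows: response 0 = correct, 1 = error).
    """

    speed_idx: np.ndarray     # (25,) 0-based speed condition
    contrast_idx: np.ndarray  # (25,) 0-based contrast condition
    edges: np.ndarray         # (25, 2, 9)
    nedges: np.ndarray        # (25, 2)
    pobs: np.ndarray          # (25, 2, 10)
    n_trials: np.ndarray      # (25,)
    probs: tuple[float, ...] = DEFAULT_PROBS

    @property
    def data_df(self) -> int:
        """Degrees of freedom actually present in the summary:
        (number of bins - 1) per cell, summed."""
        bins = np.where(self.nedges > 0, self.nedges + 1, 1).sum(axis=1)
        return int(np.sum(bins - 1))


def summarize_trials(
    trials: pd.DataFrame,
    probs=DEFAULT_PROBS,
    sparse_threshold: int = SPARSE_THRESHOLD,
) -> QuantileSummary:
    """Build the quantile summary of one subject's trial data."""
    nq = len(probs)
    ncell = N_SPEED * N_CONTRAST
    speed_idx = np.empty(ncell, dtype=np.int64)
    contrast_idx = np.empty(ncell, dtype=np.int64)
    edges = np.zeros((ncell, 2, nq))
    nedges = np.zeros((ncell, 2), dtype=np.int64)
    pobs = np.zeros((ncell, 2, nq + 1))
    n_trials = np.zeros(ncell)
    grouped = trials.groupby(["speed_cond", "contrast_cond"])
    for j in range(N_SPEED):
        for i in range(N_CONTRAST):
            ci = j * N_CONTRAST + i
            speed_idx[ci], contrast_idx[ci] = j, i
            try:
                cell = grouped.get_group((j + 1, i + 1))
            except KeyError:
                raise ValueError(
                    f"design cell (speed={j + 1}, contrast={i + 1}) has no trials"
                ) from None
            n = len(cell)
            n_trials[ci] = n
            for r, is_correct in ((0, 1), (1, 0)):
                rts = cell.loc[cell["correct"] == is_correct, "rt_s"].to_numpy()
                if rts.size >= sparse_threshold:
                    edges[ci, r] = compute_quantiles(rts, probs)
                    nedges[ci, r] = nq
                    pobs[ci, r, :] = (1.0 / (nq + 1)) * rts.size / n
                else:
                    pobs[ci, r, 0] = rts.size / n
    return QuantileSummary(
        speed_idx=speed_idx,
        contrast_idx=contrast_idx,
        edges=edges,
        nedges=nedges,
        pobs=pobs,
        n_trials=n_trials,
        probs=tuple(probs),
    )


# ---------------------------------------------------------------------------
# parameter-space mapping


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1.0 - p))


_BOUNDS = {
    "a": (0.02, 0.35),
    "t_er": (0.08, 1.2),
    "v": (-1.0, 3.0),
    "eta": (1e-4, 1.2),
    "mu_g": (0.05, 0.8),
    "s_g": (0.004, 0.4),
}


def _to_unit(x, lo, hi):
    return _logit((np.asarray(x, dtype=float) - lo) / (hi - lo))


def _from_unit(x, lo, hi):
    return lo + (hi - lo) * _sigmoid(np.asarray(x, dtype=float))


class _ParamSpace:
    """Maps between an unconstrained optimizer vector and DesignParams.

    Positive/bounded parameters use logistic transforms; the start-point
    range is expressed as a fraction of the smallest boundary separation
    and the nondecision range as a fraction of twice the smallest
    nondecision time, so every unconstrained vector yields a valid design.
    """

    def __init__(self, tie_fast_conditions: bool, fixed_zero_po: np.ndarray, s: float):
        self.tie = tie_fast_conditions
        self.fixed_zero_po = np.asarray(fixed_zero_po, dtype=bool)
        self.s = s
        self.n_a = N_SPEED - 1 if self.tie else N_SPEED
        self.n_po = int((~self.fixed_zero_po).sum())
        self.n_free = 2 * self.n_a + self.n_po + N_CONTRAST + 5

    def pack(self, d: DesignParams) -> np.ndarray:
        a = np.asarray(d.a)
        ter = np.asarray(d.t_er)
        if self.tie:
            a = np.concatenate([[a[:2].mean()], a[2:]])
            ter = np.concatenate([[ter[:2].mean()], ter[2:]])
        po_free = np.asarray(d.p_o)[~self.fixed_zero_po]
        theta = np.concatenate(
            [
                _to_unit(a, *_BOUNDS["a"]),
                _to_unit(ter, *_BOUNDS["t_er"]),
                _logit(po_free),
                _to_unit(np.asarray(d.v), *_BOUNDS["v"]),
                [_to_unit(d.eta, *_BOUNDS["eta"])],
                [_logit(d.s_z / (0.95 * min(d.a)))],
                [_logit(d.s_t / (1.9 * min(d.t_er)))],
                [_to_unit(d.mu_g, *_BOUNDS["mu_g"])],
                [_to_unit(d.s_g, *_BOUNDS["s_g"])],
            ]
        )
        return theta

    def unpack(self, theta: np.ndarray) -> DesignParams:
        k = 0
        a = _from_unit(theta[k : k + self.n_a], *_BOUNDS["a"])
        k += self.n_a
        ter = _from_unit(theta[k : k + self.n_a], *_BOUNDS["t_er"])
        k += self.n_a
        if self.tie:
            a = np.concatenate([[a[0]], a])
            ter = np.concatenate([[ter[0]], ter])
        po = np.zeros(N_SPEED)
        po[~self.fixed_zero_po] = _sigmoid(theta[k : k + self.n_po])
        k += self.n_po
        v = _from_unit(theta[k : k + N_CONTRAST], *_BOUNDS["v"])
        k += N_CONTRAST
        eta = float(_from_unit(theta[k], *_BOUNDS["eta"]))
        s_z = float(_sigmoid(theta[k + 1]) * 0.95 * a.min())
        s_t = float(_sigmoid(theta[k + 2]) * 1.9 * ter.min())
        mu_g = float(_from_unit(theta[k + 3], *_BOUNDS["mu_g"]))
        s_g = float(_from_unit(theta[k + 4], *_BOUNDS["s_g"]))
        return DesignParams(
            a=tuple(a), t_er=tuple(ter), p_o=tuple(po), v=tuple(v),
            eta=eta, s_z=s_z, s_t=s_t, mu_g=mu_g, s_g=s_g, s=self.s,
        )


# ---------------------------------------------------------------------------
# configuration and results


@dataclass
class FitConfig:
    """Settings of the G2 fit."""

    restarts: int = 3                 # random restarts beyond the heuristic start
    tie_fast_conditions: bool = True  # tie a, T_er across speed conditions 1-2
    p_o_floor: float = 0.1            # estimated p_o below this is fixed to 0
    quantile_probs: tuple = DEFAULT_PROBS
    sparse_threshold: int = SPARSE_THRESHOLD
    seed: int = 0                     # seeds the restart perturbations
    restart_scale: float = 0.1        # relative perturbation of the start values
    maxfev_primary: int = 12000       # NM budget of the first run
    maxfev_restart: int = 5000        # NM budget of each restart / refit
    gh_order: int = 20
    # CDF series truncation for the objective; looser than the ddm_core
    # default (1e-9) because fitting accuracy is limited by sampling noise
    # (G2 changes by far less than 0.01 between the two settings)
    series_tol: float = 3e-7
    s: float = 0.1                    # diffusion scaling constant

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown FitConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "quantile_probs" in d:
            d["quantile_probs"] = tuple(d["quantile_probs"])
        return cls(**d)


@dataclass
class FitResult:
    """Outcome of fitting one subject."""

    design: DesignParams
    gsquare: float
    df: int                       # headline df: 475 - 25
    df_free: int                  # 475 - actual free parameter count
    data_df: int                  # df present in the summary (sparse cells shrink it)
    n_free: int
    n_params_reported: int
    per_cell_gsquare: np.ndarray
    predicted_pi: np.ndarray
    summary: QuantileSummary
    po_zeroed: list[int]          # 1-based speed conditions with p_o fixed at 0
    tied_fast_conditions: bool
    converged: bool
    trace: list[dict] = field(default_factory=list)
    n_fev: int = 0


@dataclass
class GoodnessOfFit:
    gsquare: float
    df: int
    critical_value: float
    ratio: float
    grade: str


def goodness_of_fit(result: FitResult, alpha: float = 0.95) -> GoodnessOfFit:
    """Chi-square assessment of a fit.

    The G2 statistic is asymptotically chi-square; with the full design
    the headline df is 475 - 25 = 450 (0.95 critical value 500.5).  With
    this many trials per subject, values up to about twice the critical
    value still represent good fits, hence the qualitative grade.
    """
    crit = float(stats.chi2.ppf(alpha, result.df))
    ratio = result.gsquare / crit
    grade = "good" if result.gsquare < 2.0 * crit else "poor"
    return GoodnessOfFit(
        gsquare=result.gsquare, df=result.df, critical_value=crit,
        ratio=ratio, grade=grade,
    )


# ---------------------------------------------------------------------------
# start heuristics


def heuristic_start(trials: pd.DataFrame, config: FitConfig) -> DesignParams:
    """Data-driven starting values.

    Guess probabilities start at the sub-300-ms response fraction per
    speed condition; nondecision times at the 0.05 quantile of the
    (guess-purged) RTs; boundary separation from the median decision time
    via the zero-drift mean first-passage time a^2 / (4 s^2); drift rates
    from accuracy in the slower conditions via the no-variability closed
    form acc = 1 / (1 + exp(-v a / s^2)).
    """
    s = config.s
    po0, ter0, a0 = [], [], []
    for j in range(1, N_SPEED + 1):
        rts = trials.loc[trials["speed_cond"] == j, "rt_s"].to_numpy()
        frac_fast = float(np.mean(rts < 0.3))
        po0.append(min(max(frac_fast, 0.005), 0.98))
        dec = rts[rts > 0.35] if frac_fast > 0.05 else rts
        if dec.size < 10:
            dec = rts
        ter_j = max(float(np.quantile(dec, 0.05)) - 0.02, 0.12)
        ter0.append(min(ter_j, 1.0))
        mdt = max(float(np.median(dec)) - ter_j, 0.02)
        a0.append(min(max(2.0 * s * math.sqrt(mdt), 0.03), 0.3))
    abar = float(np.mean(a0[2:]))
    v0 = []
    slow = trials[trials["speed_cond"] >= 3]
    for i in range(1, N_CONTRAST + 1):
        sub = slow[slow["contrast_cond"] == i]
        acc = float(sub["correct"].mean()) if len(sub) else 0.7
        acc = min(max(acc, 0.52), 0.99)
        v0.append(min(max(s**2 * math.log(acc / (1 - acc)) / abar, 0.02), 1.5))
    fast = trials.loc[(trials["speed_cond"] == 1) & (trials["rt_s"] < 0.3), "rt_s"]
    mu_g0 = float(fast.mean()) if len(fast) >= 5 else 0.25
    s_g0 = min(max(float(fast.std()), 0.01), 0.2) if len(fast) >= 5 else 0.05
    ter_min, a_min = min(ter0), min(a0)
    return DesignParams(
        a=tuple(a0), t_er=tuple(ter0), p_o=tuple(po0), v=tuple(v0),
        eta=0.15, s_z=0.3 * a_min, s_t=0.3 * ter_min,
        mu_g=min(max(mu_g0, 0.08), 0.6), s_g=s_g0, s=s,
    )


# ---------------------------------------------------------------------------
# the fit itself


def _evaluate(design: DesignParams, summary: QuantileSummary, config: FitConfig):
    """G2 of ``design`` against ``summary`` (total, per-cell, predicted pi)."""
    gh_x, gh_w = np.polynomial.hermite.hermgauss(config.gh_order)
    out_cell = np.zeros(summary.n_trials.shape[0])
    out_pi = np.zeros_like(summary.pobs)
    total = _kernels.gsq_kernel(
        np.asarray(design.a), np.asarray(design.t_er), np.asarray(design.p_o),
        np.asarray(design.v), design.eta, design.s_z, design.s_t,
        design.mu_g, design.s_g, design.s,
        summary.speed_idx, summary.contrast_idx, summary.edges, summary.nedges,
        summary.pobs, summary.n_trials, gh_x, gh_w, config.series_tol, PI_FLOOR,
        out_cell, out_pi,
    )
    return float(total), out_cell, out_pi


def _minimize(space, theta0, summary, config, maxfev):
    gh_x, gh_w = np.polynomial.hermite.hermgauss(config.gh_order)
    out_cell = np.zeros(summary.n_trials.shape[0])
    out_pi = np.zeros_like(summary.pobs)

    def objective(theta):
        d = space.unpack(theta)
        return _kernels.gsq_kernel(
            np.asarray(d.a), np.asarray(d.t_er), np.asarray(d.p_o),
            np.asarray(d.v), d.eta, d.s_z, d.s_t, d.mu_g, d.s_g, d.s,
            summary.speed_idx, summary.contrast_idx, summary.edges,
            summary.nedges, summary.pobs, summary.n_trials,
            gh_x, gh_w, config.series_tol, PI_FLOOR, out_cell, out_pi,
        )

    res = optimize.minimize(
        objective, theta0, method="Nelder-Mead",
        options={
            "maxfev": maxfev, "adaptive": True,
            "xatol": 1e-4, "fatol": 1e-3,
        },
    )
    return res


def _perturb_design(d: DesignParams, rng: np.random.Generator, scale: float) -> DesignParams:
    mult = lambda x: float(x) * float(1.0 + scale * rng.standard_normal())
    a = tuple(max(mult(x), 0.021) for x in d.a)
    ter = tuple(max(mult(x), 0.09) for x in d.t_er)
    return d.replace(
        a=a, t_er=ter,
        p_o=tuple(min(max(mult(max(x, 0.01)), 1e-4), 0.99) for x in d.p_o),
        v=tuple(mult(x) for x in d.v),
        eta=max(mult(d.eta), 1e-3),
        s_z=min(max(mult(d.s_z), 1e-4), 0.9 * min(a)),
        s_t=min(max(mult(d.s_t), 1e-3), 1.8 * min(ter)),
        mu_g=mult(d.mu_g), s_g=max(mult(d.s_g), 0.005),
    )


def fit_subject(trials: pd.DataFrame, config: FitConfig | None = None) -> FitResult:
    """Fit the 25-condition mixture model to one subject's trials.

    Runs Nelder-Mead from a heuristic start plus ``config.restarts``
    perturbed restarts, keeps the best optimum, then applies the
    guess-probability rule: any fitted p_o below ``config.p_o_floor`` is
    fixed at zero and the fit re-run (repeated until the zero set is
    stable).  Missing design cells raise; non-convergence is flagged on
    the result, not raised.
    """
    if config is None:
        config = FitConfig()
    summary = summarize_trials(
        trials, probs=config.quantile_probs, sparse_threshold=config.sparse_threshold
    )
    rng = np.random.default_rng(config.seed)
    start = heuristic_start(trials, config)

    fixed_zero = np.zeros(N_SPEED, dtype=bool)
    space = _ParamSpace(config.tie_fast_conditions, fixed_zero, config.s)

    trace: list[dict] = []
    best = None
    n_fev = 0
    starts = [start] + [
        _perturb_design(start, rng, config.restart_scale) for _ in range(config.restarts)
    ]
    for k, st in enumerate(starts):
        maxfev = config.maxfev_primary if k == 0 else config.maxfev_restart
        res = _minimize(space, space.pack(st), summary, config, maxfev)
        n_fev += res.nfev
        trace.append(
            {"stage": f"start_{k}", "gsquare": float(res.fun), "nfev": int(res.nfev),
             "converged": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res

    # guess-probability zeroing rule, iterated to a stable zero set
    po_zeroed: list[int] = []
    for _ in range(N_SPEED):
        fitted = space.unpack(best.x)
        low = (np.asarray(fitted.p_o) < config.p_o_floor) & ~fixed_zero
        if not low.any():
            break
        fixed_zero = fixed_zero | low
        po_zeroed = [int(j + 1) for j in np.nonzero(fixed_zero)[0]]
        zeroed = fitted.replace(
            p_o=tuple(0.0 if fixed_zero[j] else fitted.p_o[j] for j in range(N_SPEED))
        )
        space = _ParamSpace(config.tie_fast_conditions, fixed_zero, config.s)
        res = _minimize(space, space.pack(zeroed), summary, config, config.maxfev_restart)
        n_fev += res.nfev
        trace.append(
            {"stage": f"po_zero_refit_{po_zeroed}", "gsquare": float(res.fun),
             "nfev": int(res.nfev), "converged": bool(res.success)}
        )
        # a refit constrained to the stable zero set cannot be worse than
        # the unconstrained optimum evaluated with those p_o rounded down;
        # keep the refit result regardless so the rule is actually applied
        best = res

    final = space.unpack(best.x)
    total, per_cell, pi = _evaluate(final, summary, config)
    n_free = space.n_free
    return FitResult(
        design=final,
        gsquare=total,
        df=DATA_DF - N_PARAMS_REPORTED,
        df_free=DATA_DF - n_free,
        data_df=summary.data_df,
        n_free=n_free,
        n_params_reported=N_PARAMS_REPORTED,
        per_cell_gsquare=per_cell,
        predicted_pi=pi,
        summary=summary,
        po_zeroed=po_zeroed,
        tied_fast_conditions=config.tie_fast_conditions,
        converged=all(t["converged"] for t in trace[-1:]),
        trace=trace,
        n_fev=n_fev,
    )
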