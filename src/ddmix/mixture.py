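"""The diffusion / fast-guess mixture distribution.

A trial is a fast guess with probability ``p_o`` and a diffusion decision
with probability ``1 - p_o``.  Guesses respond "correct" with probability
exactly 0.5 and have zero-truncated Normal(mu_g, s_g) latencies; diffusion
trials map the upper boundary to the correct response.  The defective
mixture CDF for a response R at time t is therefore

    F_R(t) = p_o * 0.5 * F_guess(t) + (1 - p_o) * F_diff,R(t)

and overall accuracy is p_o/2 + (1 - p_o) * P_diff(correct).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from . import ddm_core
from .params import ConditionParams, GuessParams

__all__ = [
    "guess_cdf",
    "guess_density",
    "mixture_defective_cdf",
    "mixture_accuracy",
    "mixture_rt_density",
    "predicted_bin_probs",
]

_RESPONSES = ("correct", "error")

#: Floor applied to predicted bin probabilities so that logarithms in the
#: G2 statistic stay finite.
PI_FLOOR = 1e-10


def _check_response(response: str) -> str:
    if response not in _RESPONSES:
        raise ValueError(f"response must be one of {_RESPONSES}, got {response!r}")
    return "upper" if response == "correct" else "lower"


def guess_cdf(t, guess: GuessParams):
    """CDF of the zero-truncated normal guess-time distribution."""
    t = np.asarray(t, dtype=float)
    lo = norm.cdf(-guess.mu_g / guess.s_g)
    out = (norm.cdf((t - guess.mu_g) / guess.s_g) - lo) / (1.0 - lo)
    return np.clip(np.where(t <= 0, 0.0, out), 0.0, 1.0)


def guess_density(t, guess: GuessParams):
    """Density of the zero-truncated normal guess-time distribution."""
    t = np.asarray(t, dtype=float)
    lo = norm.cdf(-guess.mu_g / guess.s_g)
    out = norm.pdf((t - guess.mu_g) / guess.s_g) / (guess.s_g * (1.0 - lo))
    return np.where(t <= 0, 0.0, out)


def mixture_defective_cdf(
    t, cond: ConditionParams, response: str = "correct", gh_order: int = 20
):
    """P(response, RT <= t) under the full mixture model."""
    boundary = _check_response(response)
    p_o = cond.guess.p_o
    f_g = guess_cdf(t, cond.guess)
    if p_o >= 1.0:
        return 0.5 * f_g
    f_d = ddm_core.defective_cdf(t, cond.wiener, cond.var, boundary, gh_order=gh_order)
    return p_o * 0.5 * f_g + (1.0 - p_o) * f_d


def mixture_accuracy(cond: ConditionParams, gh_order: int = 20) -> float:
    """Marginal probability of a correct response: p_o/2 + (1-p_o) P_diff."""
    p_o = cond.guess.p_o
    if p_o >= 1.0:
        return 0.5
    p_diff = ddm_core.response_prob_with_variability(
        cond.wiener, cond.var, "upper", gh_order=gh_order
    )
    return p_o * 0.5 + (1.0 - p_o) * p_diff


def mixture_rt_density(t, cond: ConditionParams, h: float = 2e-4, gh_order: int = 20):
    """Marginal RT density (both responses pooled) of the mixture.

    The diffusion part is obtained by central differences of the summed
    defective CDFs with step ``h``; the guess part is exact.  Adequate for
    locating density modes (the CDF is smooth).
    """
    t = np.asarray(t, dtype=float)
    p_o = cond.guess.p_o
    out = p_o * guess_density(t, cond.guess)
    if p_o < 1.0:
        f = np.zeros_like(t)
        for b in ("upper", "lower"):
            f += ddm_core.defective_cdf(t + h, cond.wiener, cond.var, b, gh_order=gh_order)
            f -= ddm_core.defective_cdf(t - h, cond.wiener, cond.var, b, gh_order=gh_order)
        out = out + (1.0 - p_o) * f / (2.0 * h)
    return out


def predicted_bin_probs(
    edges_correct,
    edges_error,
    cond: ConditionParams,
    gh_order: int = 20,
    pi_floor: float = PI_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted inter-quantile bin probabilities for one design cell.

    ``edges_correct`` / ``edges_error`` are the observed quantile RTs used
    as bin edges for that response (typically the 0.1 ... 0.9 quantiles;
    ``None`` or empty means the response is represented by a single bin
    holding its whole response probability).  Returns the two arrays of
    bin probabilities; with k edges a response has k + 1 bins.  All
    probabilities are floored at ``pi_floor`` and the un-floored values
    sum to 1 across both responses.
    """
    out = []
    for response, edges in (("correct", edges_correct), ("error", edges_error)):
        boundary = _check_response(response)
        p_o = cond.guess.p_o
        if p_o >= 1.0:
            p_resp = 0.5
        else:
            p_diff = ddm_core.response_prob_with_variability(
                cond.wiener, cond.var, boundary, gh_order=gh_order
            )
            p_resp = p_o * 0.5 + (1.0 - p_o) * p_diff
        if edges is None or len(edges) == 0:
            out.append(np.array([max(p_resp, pi_floor)]))
            continue
        edges = np.asarray(edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError(f"{response} quantile edges must be strictly increasing")
        f = mixture_defective_cdf(edges, cond, response, gh_order=gh_order)
        probs = np.diff(np.concatenate([[0.0], f, [p_resp]]))
        out.append(np.maximum(probs, pi_floor))
    return out[0], out[1]
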