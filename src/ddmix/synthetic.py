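"""Synthetic trial-level data with the structure of the speed-accuracy
x contrast experiment.

The generator emulates the experiment the model was built for: ~20
subjects, a balanced 5 (speed stress) x 5 (contrast) design with ~200
trials per cell (~5000 per subject), heavy fast-guess contamination under
speed stress (p_o = 0.735 in the fastest condition, 0.201 in the next,
none in the slower three), bimodal RT distributions where guesses and
decisions coexist, and chance accuracy below 300 ms.

Each trial record carries a latent ``origin`` flag (``"guess"`` or
``"diffusion"``) that real data would not have; it is used only to
validate the generator itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _kernels
from .params import (
    DesignParams,
    GuessParams,
    N_CONTRAST,
    N_SPEED,
    ParameterError,
    TrialVariability,
    WienerParams,
    canonical_design,
)

__all__ = [
    "sample_guess_trials",
    "sample_diffusion_trials",
    "simulate_dataset",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["subject", "speed_cond", "contrast_cond", "correct", "rt_s", "origin"]

#: Euler step (s) of the diffusion trial sampler.
DEFAULT_DT = 1e-4


def sample_guess_trials(
    n: int, guess: GuessParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` fast-guess trials: (rt, correct).

    Latencies are Normal(mu_g, s_g) truncated at zero (negatives redrawn);
    correctness is a fair coin.
    """
    rt = rng.normal(guess.mu_g, guess.s_g, size=n)
    while True:
        bad = rt <= 0
        if not bad.any():
            break
        rt[bad] = rng.normal(guess.mu_g, guess.s_g, size=int(bad.sum()))
    correct = rng.random(n) < 0.5
    return rt, correct


def sample_diffusion_trials(
    n: int,
    wiener: WienerParams,
    var: TrialVariability,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` diffusion trials: (rt, correct).

    RT is the Euler-simulated first-passage time (Brownian-bridge
    corrected) plus a uniform nondecision time; the upper boundary is the
    correct response.
    """
    var.validate_for(wiener)
    seed = int(rng.integers(2**31))
    rt, up = _kernels.euler_fpt(
        n, wiener.a, wiener.z, wiener.v, wiener.s,
        var.eta, var.s_z, var.t_er, var.s_t, dt, seed,
    )
    return rt, up.astype(bool)


def _perturbed(design: DesignParams, rng: np.random.Generator, sd: float) -> DesignParams:
    """Multiplicative log-normal perturbation of one subject's parameters.

    Guess probabilities are perturbed on the logit scale (zeros stay
    zero); the starting-point and nondecision ranges are re-clipped to
    keep every cell valid.
    """
    f = lambda x: float(x) * float(rng.lognormal(0.0, sd))
    a = tuple(f(x) for x in design.a)
    t_er = tuple(f(x) for x in design.t_er)
    v = tuple(f(x) for x in design.v)
    p_o = tuple(
        0.0 if x == 0.0 else float(1.0 / (1.0 + np.exp(-(np.log(x / (1 - x)) + rng.normal(0.0, sd)))))
        for x in design.p_o
    )
    s_z = min(f(design.s_z), 0.95 * min(a))
    t_er_min = min(t_er)
    s_t = min(f(design.s_t), 1.9 * t_er_min)
    return design.replace(
        a=a, t_er=t_er, v=v, p_o=p_o,
        eta=f(design.eta), s_z=s_z, s_t=s_t,
        mu_g=f(design.mu_g), s_g=f(design.s_g),
    )


def simulate_dataset(
    design: DesignParams | None = None,
    n_subjects: int = 20,
    n_trials_per_cell: int = 200,
    seed: int = 0,
    between_subject_sd: float = 0.1,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Simulate a balanced trial-level dataset from the mixture model.

    Parameters
    ----------
    design
        Generating parameters; defaults to :func:`canonical_design`.
    n_subjects, n_trials_per_cell
        Defaults give the scale of the original experiment: 20 subjects
        with 25 x 200 = 5000 trials each.
    seed
        Seeds one generator per subject (subject-major), so any subject's
        data are reproducible independently of the others.
    between_subject_sd
        SD of the multiplicative log-normal perturbation applied to each
        subject's parameters (0 disables heterogeneity; subject 1 of a
        single-subject call with sd 0 is generated from ``design``
        exactly).

    Returns
    -------
    DataFrame with columns subject, speed_cond, contrast_cond, correct,
    rt_s and the latent origin flag.
    """
    if design is None:
        design = canonical_design()
    if n_subjects < 1 or n_trials_per_cell < 1:
        raise ParameterError("n_subjects and n_trials_per_cell must be >= 1")
    frames = []
    root = np.random.SeedSequence(int(seed))
    for si, ss in enumerate(root.spawn(n_subjects), start=1):
        rng = np.random.default_rng(ss)
        d = _perturbed(design, rng, between_subject_sd) if between_subject_sd > 0 else design
        for speed in range(1, N_SPEED + 1):
            for contrast in range(1, N_CONTRAST + 1):
                cond = d.condition(speed, contrast)
                n_guess = int(rng.binomial(n_trials_per_cell, cond.guess.p_o))
                n_diff = n_trials_per_cell - n_guess
                rt = np.empty(n_trials_per_cell)
                correct = np.empty(n_trials_per_cell, dtype=bool)
                origin = np.empty(n_trials_per_cell, dtype=object)
                if n_guess:
                    rt[:n_guess], correct[:n_guess] = sample_guess_trials(
                        n_guess, cond.guess, rng
                    )
                    origin[:n_guess] = "guess"
                if n_diff:
                    rt[n_guess:], correct[n_guess:] = sample_diffusion_trials(
                        n_diff, cond.wiener, cond.var, rng, dt=dt
                    )
                    origin[n_guess:] = "diffusion"
                order = rng.permutation(n_trials_per_cell)
                frames.append(
                    pd.DataFrame(
                        {
                            "subject": si,
                            "speed_cond": speed,
                            "contrast_cond": contrast,
                            "correct": correct[order].astype(int),
                            "rt_s": rt[order],
                            "origin": origin[order],
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
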