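"""Parameter containers for the diffusion / fast-guess mixture model.

The model describes two-choice response times as a probabilistic mixture of

* a Wiener diffusion decision process between absorbing boundaries 0 and
  ``a``, starting at ``z``, with drift ``v`` and within-trial noise ``s``,
  plus across-trial variability in drift (normal, SD ``eta``), starting
  point (uniform, range ``s_z``) and nondecision time (uniform, mean
  ``t_er``, range ``s_t``); and
* a "fast guess" process that responds at chance (50% correct) with a
  normally distributed latency, mean ``mu_g`` and SD ``s_g``, truncated
  at zero.

A trial is a guess with probability ``p_o`` and a diffusion decision with
probability ``1 - p_o``.

The experimental design crosses five speed-accuracy instruction levels
(1 = extreme speed stress ... 5 = extreme accuracy stress) with five
stimulus contrast levels (1 = lowest contrast ... 5 = highest).  Selective
influence is built into :class:`DesignParams`: boundary separation,
nondecision time and the guess probability vary only with speed stress,
drift rate varies only with contrast, and all remaining parameters are
shared across the 25 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "WienerParams",
    "TrialVariability",
    "GuessParams",
    "ConditionParams",
    "DesignParams",
    "canonical_design",
    "DIFFUSION_NOISE_SD",
    "N_SPEED",
    "N_CONTRAST",
]

#: Conventional within-trial diffusion noise SD (evidence units / sqrt(s)).
#: The scaling parameter of the diffusion model is not identifiable from
#: data; all published magnitudes used here assume s = 0.1.
DIFFUSION_NOISE_SD: float = 0.1

N_SPEED: int = 5
N_CONTRAST: int = 5


class ParameterError(ValueError):
    """A parameter value violates its domain constraints."""


@dataclass(frozen=True)
class WienerParams:
    """Wiener diffusion process between absorbing boundaries 0 and ``a``.

    Parameters
    ----------
    a
        Boundary separation (evidence units), ``a > 0``.
    z
        Starting point, ``0 < z < a``.
    v
        Mean drift rate (evidence units / s).  Positive drift pushes the
        process toward the upper boundary ``a`` (the "correct" response).
    s
        Within-trial noise SD (evidence units / sqrt(s)).
    """

    a: float
    z: float
    v: float
    s: float = DIFFUSION_NOISE_SD

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ParameterError(f"boundary separation a={self.a} must be > 0")
        if not (0 < self.z < self.a):
            raise ParameterError(f"starting point z={self.z} must lie in (0, {self.a})")
        if not (self.s > 0):
            raise ParameterError(f"noise SD s={self.s} must be > 0")


@dataclass(frozen=True)
class TrialVariability:
    """Across-trial variability of the diffusion process.

    Drift varies normally with SD ``eta``; the starting point varies
    uniformly with range ``s_z`` (centred on ``z``); nondecision time is
    uniform with mean ``t_er`` and range ``s_t``.
    """

    eta: float = 0.0
    s_z: float = 0.0
    t_er: float = 0.0
    s_t: float = 0.0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ParameterError(f"eta={self.eta} must be >= 0")
        if self.s_z < 0:
            raise ParameterError(f"s_z={self.s_z} must be >= 0")
        if self.s_t < 0:
            raise ParameterError(f"s_t={self.s_t} must be >= 0")
        if self.t_er < self.s_t / 2:
            raise ParameterError(
                f"t_er={self.t_er} must be >= s_t/2={self.s_t / 2} "
                "(nondecision time cannot be negative)"
            )

    def validate_for(self, wiener: WienerParams) -> None:
        """Check constraints that couple variability to the process geometry."""
        bound = 2.0 * min(wiener.z, wiener.a - wiener.z)
        if self.s_z >= bound and self.s_z > 0:
            raise ParameterError(
                f"s_z={self.s_z} must be < 2*min(z, a-z)={bound}; "
                "the process could otherwise start outside the boundaries"
            )


@dataclass(frozen=True)
class GuessParams:
    """Fast-guess component: chance accuracy, normal latency.

    ``p_o`` is the probability that a trial is a fast guess; guesses are
    correct with probability exactly 0.5 regardless of condition.  The
    latency distribution Normal(``mu_g``, ``s_g``) is truncated at zero
    and renormalised (negligible mass for realistic parameters).
    """

    p_o: float
    mu_g: float
    s_g: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_o <= 1.0):
            raise ParameterError(f"p_o={self.p_o} must lie in [0, 1]")
        if not (self.mu_g > 0):
            raise ParameterError(f"mu_g={self.mu_g} must be > 0")
        if not (self.s_g > 0):
            raise ParameterError(f"s_g={self.s_g} must be > 0")


@dataclass(frozen=True)
class ConditionParams:
    """Complete generative specification of one design cell."""

    wiener: WienerParams
    var: TrialVariability
    guess: GuessParams

    def __post_init__(self) -> None:
        self.var.validate_for(self.wiener)


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the full 5 (speed) x 5 (contrast) design.

    Boundary separation ``a``, nondecision time ``t_er`` and guess
    probability ``p_o`` are indexed by speed condition; drift ``v`` by
    contrast condition; everything else is shared.  The starting point is
    unbiased, ``z = a/2``.
    """

    a: tuple[float, ...]
    t_er: tuple[float, ...]
    p_o: tuple[float, ...]
    v: tuple[float, ...]
    eta: float
    s_z: float
    s_t: float
    mu_g: float
    s_g: float
    s: float = DIFFUSION_NOISE_SD

    def __post_init__(self) -> None:
        for name, vals, n in (
            ("a", self.a, N_SPEED),
            ("t_er", self.t_er, N_SPEED),
            ("p_o", self.p_o, N_SPEED),
            ("v", self.v, N_CONTRAST),
        ):
            if len(vals) != n:
                raise ParameterError(f"{name} must have {n} entries, got {len(vals)}")
        # Build every cell once; ConditionParams enforces the invariants.
        for j in range(1, N_SPEED + 1):
            for i in range(1, N_CONTRAST + 1):
                self.condition(j, i)

    def condition(self, speed_cond: int, contrast_cond: int) -> ConditionParams:
        """Return the generative parameters of cell (speed, contrast)."""
        if not (1 <= speed_cond <= N_SPEED):
            raise ParameterError(f"speed_cond={speed_cond} must be in 1..{N_SPEED}")
        if not (1 <= contrast_cond <= N_CONTRAST):
            raise ParameterError(
                f"contrast_cond={contrast_cond} must be in 1..{N_CONTRAST}"
            )
        a = self.a[speed_cond - 1]
        return ConditionParams(
            wiener=WienerParams(a=a, z=a / 2.0, v=self.v[contrast_cond - 1], s=self.s),
            var=TrialVariability(
                eta=self.eta,
                s_z=self.s_z,
                t_er=self.t_er[speed_cond - 1],
                s_t=self.s_t,
            ),
            guess=GuessParams(
                p_o=self.p_o[speed_cond - 1], mu_g=self.mu_g, s_g=self.s_g
            ),
        )

    def replace(self, **kwargs) -> "DesignParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "a": list(self.a),
            "t_er": list(self.t_er),
            "p_o": list(self.p_o),
            "v": list(self.v),
            "eta": self.eta,
            "s_z": self.s_z,
            "s_t": self.s_t,
            "mu_g": self.mu_g,
            "s_g": self.s_g,
            "s": self.s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignParams":
        return cls(
            a=tuple(d["a"]),
            t_er=tuple(d["t_er"]),
            p_o=tuple(d["p_o"]),
            v=tuple(d["v"]),
            eta=float(d["eta"]),
            s_z=float(d["s_z"]),
            s_t=float(d["s_t"]),
            mu_g=float(d["mu_g"]),
            s_g=float(d["s_g"]),
            s=float(d.get("s", DIFFUSION_NOISE_SD)),
        )


def canonical_design() -> DesignParams:
    """Published mean parameter estimates for the 5x5 speed x contrast design.

    These are the across-subject mean parameters from fits of the mixture
    model to a 20-subject orientation-discrimination experiment with five
    speed-accuracy and five contrast levels.  They are the package's
    default generative setting: heavy fast guessing (p_o = 0.735) under
    extreme speed stress, decaying to none in the accuracy-stressed
    conditions.
    """
    return DesignParams(
        a=(0.063, 0.063, 0.072, 0.083, 0.106),
        t_er=(0.356, 0.356, 0.382, 0.393, 0.414),
        p_o=(0.735, 0.201, 0.0, 0.0, 0.0),
        v=(0.108, 0.175, 0.283, 0.426, 0.546),
        eta=0.184,
        s_z=0.037,
        s_t=0.129,
        mu_g=0.262,
        s_g=0.051,
    )
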