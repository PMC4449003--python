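"""Random-walk gambles with an absorbing starvation boundary.

A foraging option is modelled as a discrete random walk on the non-negative
integers. The walker starts at energy ``x0`` and takes ``n`` steps ("days").
On each day it moves right by ``g - 1`` (successful foraging: gain ``g``
minus the sure cost of one point) with probability ``p``, or left by 1 (the
sure cost alone) with probability ``1 - p``. Zero is an absorbing boundary:
a walk that reaches zero stops there, which is framed as starvation. The
probability mass absorbed at zero is ``p_starve``.

Enumerating every step sequence with absorption yields the exact endpoint
outcome distribution of the option, from which expected value, variance,
skewness and ``p_starve`` are computed. The same distribution describes the
equivalent single-step "casino" lottery, so both task frames share one
representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "WalkSpec",
    "OutcomeDistribution",
    "GambleStats",
    "GamblePairSpec",
    "GambleSetConfig",
    "enumerate_walk",
    "compute_stats",
    "generate_gamble_set",
]

#: tolerance for probability normalisation; at n <= 3 only rounding error remains
NORMALIZATION_TOL = 1e-12


@dataclass(frozen=True)
class WalkSpec:
    """One foraging option as an absorbed random walk.

    Parameters
    ----------
    x0 : int
        Initial energy (points), at least 1.
    n : int
        Number of days / steps, at least 1.
    g : int
        Gain on a successful day (points), at least 2 so that the net
        right-step ``g - 1`` is positive.
    p : float
        Per-day success probability, strictly inside (0, 1).
    """

    x0: int
    n: int
    g: int
    p: float

    def __post_init__(self) -> None:
        if not (isinstance(self.x0, (int, np.integer)) and self.x0 >= 1):
            raise ValueError(f"x0 must be an integer >= 1, got {self.x0!r}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be an integer >= 1, got {self.n!r}")
        if not (isinstance(self.g, (int, np.integer)) and self.g >= 2):
            raise ValueError(f"g must be an integer >= 2, got {self.g!r}")
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie strictly in (0, 1), got {self.p!r}")


@dataclass(frozen=True)
class OutcomeDistribution:
    """Exact endpoint distribution of an absorbed walk.

    ``support`` is strictly increasing and non-negative; ``probs`` matches it
    elementwise and sums to one. The mass at zero, if any, is ``p_starve``.
    """

    support: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) != len(self.probs) or not self.support:
            raise ValueError("support and probs must be nonempty and equal length")
        if any(x < 0 for x in self.support):
            raise ValueError("support values must be non-negative")
        if any(b <= a for a, b in zip(self.support, self.support[1:])):
            raise ValueError("support must be strictly increasing")
        if any(q < 0 for q in self.probs):
            raise ValueError("probabilities must be non-negative")
        if abs(sum(self.probs) - 1.0) > NORMALIZATION_TOL:
            raise ValueError(
                f"probabilities sum to {sum(self.probs)!r}, not 1 within "
                f"{NORMALIZATION_TOL}"
            )

    @property
    def p_starve(self) -> float:
        """Probability of hitting the absorbing boundary: the mass at zero."""
        return self.probs[0] if self.support[0] == 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "support": list(self.support),
            "probs": list(self.probs),
            "p_starve": self.p_starve,
        }


@dataclass(frozen=True)
class GambleStats:
    """Summary statistics of an outcome distribution.

    ``skw`` is the standardized third central moment (unitless); it is set
    to 0 by convention when the variance is 0.
    """

    ev: float
    var: float
    skw: float
    p_starve: float

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ValueError("variance cannot be negative")
        if not (0.0 <= self.p_starve <= 1.0):
            raise ValueError("p_starve must lie in [0, 1]")


@dataclass(frozen=True)
class GamblePairSpec:
    """A binary choice between two options sharing one energy bar and horizon.

    Both options are walks with the same initial state ``x0`` and the same
    number of days ``n``; they differ in gain and success probability.
    """

    x0: int
    n: int
    gA: int
    pA: float
    gB: int
    pB: float
    pair_id: int = 0

    @property
    def option_a(self) -> WalkSpec:
        return WalkSpec(self.x0, self.n, self.gA, self.pA)

    @property
    def option_b(self) -> WalkSpec:
        return WalkSpec(self.x0, self.n, self.gB, self.pB)


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------

def _enumerate(x0: int, n: int, g: int, p: float) -> dict[int, float]:
    """Expand all step sequences, terminating any branch that hits zero."""
    endpoint_mass: dict[int, float] = {}
    q = 1.0 - p
    step_right = g - 1

    def descend(x: int, steps_left: int, weight: float) -> None:
        if x == 0 or steps_left == 0:
            endpoint_mass[x] = endpoint_mass.get(x, 0.0) + weight
            return
        descend(x + step_right, steps_left - 1, weight * p)
        descend(x - 1, steps_left - 1, weight * q)

    descend(x0, n, 1.0)
    return endpoint_mass


@lru_cache(maxsize=None)
def _enumerate_cached(x0: int, n: int, g: int, p: float) -> OutcomeDistribution:
    mass = _enumerate(x0, n, g, p)
    support = tuple(sorted(mass))
    return OutcomeDistribution(support, tuple(mass[x] for x in support))


def enumerate_walk(spec: WalkSpec) -> OutcomeDistribution:
    """Exact endpoint distribution of an absorbed random walk.

    Follows every possible path along the branching tree of daily outcomes,
    multiplying probabilities along a path and summing paths that end at the
    same endpoint; paths stop early when they hit the absorbing boundary at
    zero.

    Examples
    --------
    >>> d = enumerate_walk(WalkSpec(x0=2, n=3, g=3, p=0.4))
    >>> round(d.p_starve, 12)   # (1-p)^2: only the left-left path starves
    0.36
    """
    return _enumerate_cached(spec.x0, spec.n, spec.g, float(spec.p))


def compute_stats(dist: OutcomeDistribution) -> GambleStats:
    """Expected value, variance, standardized skewness and ``p_starve``.

    ev = Σ x_j p_j; var = Σ p_j (x_j − ev)²;
    skw = Σ p_j (x_j − ev)³ / var^{3/2}, 0 by convention for var = 0.
    """
    x = np.asarray(dist.support, dtype=float)
    w = np.asarray(dist.probs, dtype=float)
    ev = float(w @ x)
    dev = x - ev
    var = float(w @ dev**2)
    if var > 0.0:
        skw = float(w @ dev**3) / var**1.5
    else:
        skw = 0.0
    return GambleStats(ev=ev, var=var, skw=skw, p_starve=dist.p_starve)


# ---------------------------------------------------------------------------
# Structured gamble-set generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GambleSetConfig:
    """Settings for the structured gamble-set generator.

    Defaults mirror the task design: 120 pairs for each of the four
    (initial state, days) combinations, gains on {2..6}, success
    probabilities uniform on [0.008, 0.9] rounded to three decimals, and
    every option carrying strictly positive starvation probability.
    """

    combos: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (2, 2), (2, 3))
    pairs_per_combo: int = 120
    gains: tuple[int, ...] = (2, 3, 4, 5, 6)
    p_low: float = 0.008
    p_high: float = 0.9
    p_decimals: int = 3

    def __post_init__(self) -> None:
        if not self.combos or self.pairs_per_combo < 1:
            raise ValueError("need at least one (x0, n) combination and one pair")
        if not self.gains or min(self.gains) < 2:
            raise ValueError("gains must be a nonempty set of integers >= 2")
        if not (0.0 < self.p_low < self.p_high < 1.0):
            raise ValueError("need 0 < p_low < p_high < 1")

    @property
    def n_pairs(self) -> int:
        return len(self.combos) * self.pairs_per_combo


def _draw_option(rng: np.random.Generator, config: GambleSetConfig) -> tuple[int, float]:
    g = int(rng.choice(config.gains))
    p = round(float(rng.uniform(config.p_low, config.p_high)), config.p_decimals)
    p = min(max(p, config.p_low), config.p_high)
    return g, p


def generate_gamble_set(
    config: GambleSetConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[GamblePairSpec]:
    """Generate a structured set of binary gamble pairs.

    Options of a pair share (x0, n); pairs are resampled until the two
    options differ and both have starvation probability strictly inside
    (0, 1). Deterministic for a fixed seed.
    """
    config = config or GambleSetConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pairs: list[GamblePairSpec] = []
    pair_id = 0
    for x0, n in config.combos:
        for _ in range(config.pairs_per_combo):
            while True:
                gA, pA = _draw_option(rng, config)
                gB, pB = _draw_option(rng, config)
                if (gA, pA) == (gB, pB):
                    continue
                psA = enumerate_walk(WalkSpec(x0, n, gA, pA)).p_starve
                psB = enumerate_walk(WalkSpec(x0, n, gB, pB)).p_starve
                if 0.0 < psA < 1.0 and 0.0 < psB < 1.0:
                    break
            pairs.append(GamblePairSpec(x0, n, gA, pA, gB, pB, pair_id=pair_id))
            pair_id += 1
    return pairs
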