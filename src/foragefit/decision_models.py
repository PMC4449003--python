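"""Choice models for binary gambles: moments-based, rank-dependent utility,
and homeostatic (starvation-probability) value models, plus the softmax rule.

Twelve models are registered. Family 1 (Models 1-4) values an option by a
linear combination of distribution moments (EV, variance, skewness). Family 2
(Models 5-6) is rank-dependent utility with a power utility and Prelec
probability weighting (one- and two-parameter variants). Family 3
(Models 7-9) adds a linear weight on the starvation probability p_starve to
the moment combinations. Models 10-12 are adaptations of Model 7 with
frame-specific or horizon-specific p_starve weights, and a p_starve-only
variant.

All models map the two option values V1, V2 into a choice probability through
the logistic rule P = 1 / (1 + exp(-(V1 - V2) / beta)) with decision noise
beta > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .gamble_engine import GambleStats, OutcomeDistribution

__all__ = [
    "ModelSpec",
    "TrialFeatures",
    "TrialArrays",
    "MODELS",
    "model_by_name",
    "power_utility",
    "prelec_weight",
    "rdu_value",
    "choice_prob",
    "option_value",
    "model_values",
]

FAMILY_MOMENTS = "moments"
FAMILY_RDU = "rank_dependent"
FAMILY_HOMEOSTATIC = "homeostatic"
FAMILY_SUPPLEMENTARY = "supplementary"

#: default family partition used in family-level model selection (Models 1-9)
DEFAULT_FAMILIES = {
    FAMILY_MOMENTS: (1, 2, 3, 4),
    FAMILY_RDU: (5, 6),
    FAMILY_HOMEOSTATIC: (7, 8, 9),
}


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry for one choice model.

    ``positive`` flags which parameters are constrained positive (optimised
    on the log scale during fitting); the rest are unconstrained. The softmax
    noise ``beta`` is always first and always positive.
    """

    model_id: int
    name: str
    family: str
    param_names: tuple[str, ...]
    positive: tuple[bool, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)


MODELS: dict[int, ModelSpec] = {
    1: ModelSpec(1, "EV", FAMILY_MOMENTS, ("beta",), (True,)),
    2: ModelSpec(2, "EV+Var", FAMILY_MOMENTS, ("beta", "rho"), (True, False)),
    3: ModelSpec(3, "EV+Skw", FAMILY_MOMENTS, ("beta", "lam"), (True, False)),
    4: ModelSpec(4, "EV+Var+Skw", FAMILY_MOMENTS,
                 ("beta", "rho", "lam"), (True, False, False)),
    5: ModelSpec(5, "Prelec-I", FAMILY_RDU,
                 ("beta", "mu", "alpha"), (True, True, True)),
    6: ModelSpec(6, "Prelec-II", FAMILY_RDU,
                 ("beta", "mu", "alpha", "beta_w"), (True, True, True, True)),
    7: ModelSpec(7, "EV+pstarve", FAMILY_HOMEOSTATIC,
                 ("beta", "xi"), (True, False)),
    8: ModelSpec(8, "EV+Var+pstarve", FAMILY_HOMEOSTATIC,
                 ("beta", "rho", "xi"), (True, False, False)),
    9: ModelSpec(9, "EV+Var+Skw+pstarve", FAMILY_HOMEOSTATIC,
                 ("beta", "rho", "lam", "xi"), (True, False, False, False)),
    10: ModelSpec(10, "EV+frame-pstarve", FAMILY_SUPPLEMENTARY,
                  ("beta", "xi_foraging", "xi_casino"), (True, False, False)),
    11: ModelSpec(11, "pstarve-only", FAMILY_SUPPLEMENTARY, ("beta",), (True,)),
    12: ModelSpec(12, "EV+day-pstarve", FAMILY_SUPPLEMENTARY,
                  ("beta", "xi_d1", "xi_d2", "xi_d3"),
                  (True, False, False, False)),
}

_BY_NAME = {m.name: m for m in MODELS.values()}


def model_by_name(name: str) -> ModelSpec:
    """Look up a model by registry name (e.g. ``"EV+pstarve"``)."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown model name {name!r}; known: {sorted(_BY_NAME)}")


@dataclass(frozen=True)
class TrialFeatures:
    """Per-trial inputs to the value models, for both options of the pair.

    ``frame`` is 1 in the foraging frame and 0 in the casino frame; exactly
    one day indicator d1..d3 is set, matching the pair's horizon.
    """

    stats_a: GambleStats
    stats_b: GambleStats
    dist_a: OutcomeDistribution
    dist_b: OutcomeDistribution
    frame: int
    days: int

    def __post_init__(self) -> None:
        if self.frame not in (0, 1):
            raise ValueError("frame indicator must be 0 (casino) or 1 (foraging)")
        if self.days not in (1, 2, 3):
            raise ValueError("days must be 1, 2 or 3")


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def power_utility(x, mu: float):
    """Power utility u(x) = x**mu over non-negative outcomes; u(0) = 0."""
    if mu <= 0:
        raise ValueError("power-utility exponent mu must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("outcomes must be non-negative")
    out = np.power(x, mu)
    return float(out) if out.ndim == 0 else out


def prelec_weight(p, alpha: float, beta_w: float = 1.0):
    """Prelec probability weighting w(p) = exp(-beta_w * (-log p)**alpha).

    ``beta_w = 1`` gives the one-parameter (Prelec-I) form. Handles p = 0 by
    the convention w(0) = 0; w(1) = 1 exactly.
    """
    if alpha <= 0:
        raise ValueError("Prelec alpha must be positive")
    if beta_w <= 0:
        raise ValueError("Prelec beta_w must be positive")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        neglog = -np.log(p)
    out = np.where(p > 0.0, np.exp(-beta_w * np.power(neglog, alpha)), 0.0)
    return float(out) if out.ndim == 0 else out


def _rdu_from_ranked(
    support_desc: np.ndarray,
    probs_desc: np.ndarray,
    mu: float,
    alpha: float,
    beta_w: float,
):
    """RDU value from support/probs already ranked best-first (last axis)."""
    cum = np.clip(np.cumsum(probs_desc, axis=-1), 0.0, 1.0)
    w = prelec_weight(cum, alpha, beta_w)
    pi = np.diff(w, axis=-1, prepend=0.0)
    return np.sum(pi * np.power(support_desc, mu), axis=-1)


def rdu_value(
    dist: OutcomeDistribution,
    mu: float,
    alpha: float,
    beta_w: float = 1.0,
) -> float:
    """Rank-dependent utility value V = Σ_j π_j u(x_j).

    Outcomes are ranked best-first; the decision weight of the best outcome
    is w(p_best) and subsequent weights are successive differences of the
    weighting function applied to cumulative ranked probabilities, so the
    weights sum to w(1) = 1. With mu = alpha = beta_w = 1 this reduces
    exactly to the expected value.
    """
    order = np.argsort(dist.support)[::-1]
    sup = np.asarray(dist.support, dtype=float)[order]
    prb = np.asarray(dist.probs, dtype=float)[order]
    return float(_rdu_from_ranked(sup, prb, mu, alpha, beta_w))


def choice_prob(v1, v2, beta: float):
    """Logistic (softmax) probability of choosing option 1.

    P = 1 / (1 + exp(-(v1 - v2) / beta)); beta > 0 is the decision noise.
    """
    if beta <= 0:
        raise ValueError("softmax beta must be positive")
    out = expit((np.asarray(v1, dtype=float) - np.asarray(v2, dtype=float)) / beta)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Scalar model evaluation
# ---------------------------------------------------------------------------

def _linear_terms(model_id: int, params: dict, s: GambleStats, feat: TrialFeatures) -> float:
    v = s.ev
    if model_id in (2, 4, 8, 9):
        v += params["rho"] * s.var
    if model_id in (3, 4, 9):
        v += params["lam"] * s.skw
    if model_id in (7, 8, 9):
        v += params["xi"] * s.p_starve
    if model_id == 10:
        xi = params["xi_foraging"] if feat.frame == 1 else params["xi_casino"]
        v += xi * s.p_starve
    if model_id == 12:
        xi = params[f"xi_d{feat.days}"]
        v += xi * s.p_starve
    return v


def option_value(model: ModelSpec | int, params, feat: TrialFeatures, option: str) -> float:
    """Value V of one option under a registered model.

    ``params`` maps parameter names to values (the softmax ``beta`` is
    ignored here; it enters only through :func:`choice_prob`). ``option`` is
    ``"A"`` or ``"B"``.
    """
    spec = MODELS[model] if isinstance(model, int) else model
    if spec.model_id not in MODELS:
        raise KeyError(f"unknown model id {spec.model_id}")
    if option not in ("A", "B"):
        raise ValueError("option must be 'A' or 'B'")
    params = dict(params)
    missing = [n for n in spec.param_names if n != "beta" and n not in params]
    if missing:
        raise ValueError(f"model {spec.model_id} missing parameters {missing}")
    s = feat.stats_a if option == "A" else feat.stats_b
    d = feat.dist_a if option == "A" else feat.dist_b
    mid = spec.model_id
    if mid == 5:
        return rdu_value(d, params["mu"], params["alpha"], 1.0)
    if mid == 6:
        return rdu_value(d, params["mu"], params["alpha"], params["beta_w"])
    if mid == 11:
        return s.p_starve
    return _linear_terms(mid, params, s, feat)


# ---------------------------------------------------------------------------
# Vectorised evaluation over a block of trials
# ---------------------------------------------------------------------------

class TrialArrays:
    """Feature arrays for a block of trials, shaped for fast likelihoods.

    Moment features are (n_trials, 2) with option A in column 0; outcome
    supports/probabilities are (n_trials, 2, J) padded with zero-probability
    outcomes of value 0 and pre-ranked best-first, so rank-dependent values
    vectorise without per-trial sorting.
    """

    __slots__ = ("ev", "var", "skw", "pst", "sup", "prb", "frame", "days", "n")

    def __init__(self, features: list[TrialFeatures]):
        n = len(features)
        if n == 0:
            raise ValueError("no trials")
        self.n = n
        self.ev = np.empty((n, 2))
        self.var = np.empty((n, 2))
        self.skw = np.empty((n, 2))
        self.pst = np.empty((n, 2))
        self.frame = np.empty(n)
        self.days = np.empty(n, dtype=int)
        jmax = max(
            max(len(f.dist_a.support), len(f.dist_b.support)) for f in features
        )
        self.sup = np.zeros((n, 2, jmax))
        self.prb = np.zeros((n, 2, jmax))
        for i, f in enumerate(features):
            for col, (s, d) in enumerate(
                ((f.stats_a, f.dist_a), (f.stats_b, f.dist_b))
            ):
                self.ev[i, col] = s.ev
                self.var[i, col] = s.var
                self.skw[i, col] = s.skw
                self.pst[i, col] = s.p_starve
                order = np.argsort(d.support)[::-1]
                j = len(d.support)
                self.sup[i, col, :j] = np.asarray(d.support, dtype=float)[order]
                self.prb[i, col, :j] = np.asarray(d.probs, dtype=float)[order]
            self.frame[i] = f.frame
            self.days[i] = f.days

    def day_indicator(self, day: int) -> np.ndarray:
        return (self.days == day).astype(float)


def model_values(model: ModelSpec | int, params: dict, ta: TrialArrays) -> np.ndarray:
    """Option values V as an (n_trials, 2) array under one model."""
    spec = MODELS[model] if isinstance(model, int) else model
    mid = spec.model_id
    if mid == 5:
        return _rdu_from_ranked(ta.sup, ta.prb, params["mu"], params["alpha"], 1.0)
    if mid == 6:
        return _rdu_from_ranked(
            ta.sup, ta.prb, params["mu"], params["alpha"], params["beta_w"]
        )
    if mid == 11:
        return ta.pst
    v = ta.ev.copy()
    if mid in (2, 4, 8, 9):
        v += params["rho"] * ta.var
    if mid in (3, 4, 9):
        v += params["lam"] * ta.skw
    if mid in (7, 8, 9):
        v += params["xi"] * ta.pst
    elif mid == 10:
        xi = params["xi_foraging"] * ta.frame + params["xi_casino"] * (1.0 - ta.frame)
        v += xi[:, None] * ta.pst
    elif mid == 12:
        xi = sum(
            params[f"xi_d{d}"] * ta.day_indicator(d) for d in (1, 2, 3)
        )
        v += xi[:, None] * ta.pst
    elif mid not in (1, 2, 3, 4, 8, 9):
        raise KeyError(f"unknown model id {mid}")
    return v
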