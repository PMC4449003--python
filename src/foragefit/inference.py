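"""Per-participant maximum-likelihood fitting and information criteria.

Each participant's trials are fitted independently by minimising the
negative log-likelihood of their observed choices under a registered choice
model, using the Nelder-Mead simplex. Positivity-constrained parameters
(softmax noise, utility and weighting exponents) are optimised on the log
scale. Fitting starts from positive seed values; if the optimiser reports
non-convergence, a second attempt starts from negative seeds for the
unconstrained parameters and the better converged result is kept.

Information criteria use the half-scale convention
BIC = -ln L + 0.5 k ln n and AIC = -ln L + k, where n counts the
participant's non-missed trials; with this scaling -BIC is directly a
Laplace-style approximation to the log model evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .decision_models import MODELS, ModelSpec, TrialArrays, TrialFeatures, model_values
from .gamble_engine import GamblePairSpec, compute_stats, enumerate_walk

__all__ = [
    "TrialRecord",
    "FitResult",
    "FitOptions",
    "build_trial_arrays",
    "fit_inputs_from_frame",
    "fits_to_frame",
    "negative_log_likelihood",
    "fit_participant",
    "fit_cohort",
    "information_criteria",
    "evidence_table",
]

#: choice probabilities are clipped to this interval before taking logs
PROB_CLIP = 1e-10

FRAME_FORAGING = "foraging"
FRAME_CASINO = "casino"


@dataclass(frozen=True, eq=False)
class TrialRecord:
    """One binary-choice trial of one participant."""

    participant_id: str
    frame: str
    block: int
    trial_index: int
    pair: GamblePairSpec
    choice: str  # "A", "B" or "missed"
    rt_ms: float

    def __eq__(self, other) -> bool:
        # dataclass-style equality, except NaN reaction times compare equal
        if not isinstance(other, TrialRecord):
            return NotImplemented
        rt_equal = (
            self.rt_ms == other.rt_ms
            or (np.isnan(self.rt_ms) and np.isnan(other.rt_ms))
        )
        return rt_equal and (
            (self.participant_id, self.frame, self.block, self.trial_index,
             self.pair, self.choice)
            == (other.participant_id, other.frame, other.block,
                other.trial_index, other.pair, other.choice)
        )

    def __post_init__(self) -> None:
        if self.frame not in (FRAME_FORAGING, FRAME_CASINO):
            raise ValueError(f"frame must be foraging/casino, got {self.frame!r}")
        if self.block not in (1, 2):
            raise ValueError("block must be 1 or 2")
        if self.choice not in ("A", "B", "missed"):
            raise ValueError(f"choice must be A/B/missed, got {self.choice!r}")
        if self.choice != "missed" and not (self.rt_ms > 0 or np.isnan(self.rt_ms)):
            raise ValueError("rt_ms must be positive on non-missed trials")


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one model to one participant."""

    participant_id: str
    model_id: int
    params: dict[str, float]
    negll: float
    n_trials: int
    bic: float
    aic: float
    converged: bool
    seed_branch: Literal["positive", "negative"]


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings; the defaults are the package's reference values."""

    xatol: float = 1e-6
    fatol: float = 1e-6
    maxfev_per_param: int = 2000
    seed_value: float = 0.5


@lru_cache(maxsize=None)
def _cached_features(
    x0: int, n: int, gA: int, pA: float, gB: int, pB: float, frame_int: int
) -> TrialFeatures:
    """Feature bundle for one (pair, frame); cached because a session reuses
    the same pairs across frames and a cohort reuses them across agents."""
    pair = GamblePairSpec(x0, n, gA, pA, gB, pB)
    da = enumerate_walk(pair.option_a)
    db = enumerate_walk(pair.option_b)
    return TrialFeatures(
        stats_a=compute_stats(da),
        stats_b=compute_stats(db),
        dist_a=da,
        dist_b=db,
        frame=frame_int,
        days=n,
    )


def _features_from_record(rec: TrialRecord) -> TrialFeatures:
    pair = rec.pair
    return _cached_features(
        pair.x0, pair.n, pair.gA, pair.pA, pair.gB, pair.pB,
        1 if rec.frame == FRAME_FORAGING else 0,
    )


def build_trial_arrays(trials: Sequence[TrialRecord]) -> tuple[TrialArrays, np.ndarray]:
    """Pack non-missed trials into feature arrays plus a 0/1 choice vector.

    Returns ``(arrays, choices)`` where ``choices[i]`` is 1 when option A was
    chosen. Missed trials are dropped; raises if none remain.
    """
    kept = [t for t in trials if t.choice != "missed"]
    if not kept:
        raise ValueError("all trials are missed; nothing to fit")
    feats = [_features_from_record(t) for t in kept]
    choices = np.array([1.0 if t.choice == "A" else 0.0 for t in kept])
    return TrialArrays(feats), choices


def fit_inputs_from_frame(
    df: pd.DataFrame,
) -> dict[str, tuple[TrialArrays, np.ndarray]]:
    """Per-participant ``(TrialArrays, choices)`` from a dataset frame.

    The fast path for cohort fitting: features are cached per (pair, frame)
    and TrialRecord objects are never materialised. Missed trials are
    dropped per participant.
    """
    out: dict[str, tuple[TrialArrays, np.ndarray]] = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        kept = sub[sub["choice"] != "missed"]
        if kept.empty:
            raise ValueError(f"participant {pid!r} has no non-missed trials")
        feats = [
            _cached_features(
                int(r.x0), int(r.n), int(r.gA), float(r.pA),
                int(r.gB), float(r.pB),
                1 if r.frame == FRAME_FORAGING else 0,
            )
            for r in kept.itertuples(index=False)
        ]
        choices = (kept["choice"].to_numpy() == "A").astype(float)
        out[str(pid)] = (TrialArrays(feats), choices)
    return out


def negative_log_likelihood(
    model: ModelSpec | int,
    params: dict[str, float],
    ta: TrialArrays,
    choices: np.ndarray,
) -> float:
    """-Σ ln P(observed choice) under the softmax rule, in nats.

    Choice probabilities are clipped away from {0, 1} by ``PROB_CLIP`` so the
    likelihood stays finite for near-deterministic parameter settings.
    """
    spec = MODELS[model] if isinstance(model, int) else model
    v = model_values(spec, params, ta)
    dv = (v[:, 0] - v[:, 1]) / params["beta"]
    # log P(A) = -log1p(exp(-dv)); stable via logaddexp
    log_pa = -np.logaddexp(0.0, -dv)
    log_pb = -np.logaddexp(0.0, dv)
    floor = np.log(PROB_CLIP)
    log_pa = np.clip(log_pa, floor, 0.0)
    log_pb = np.clip(log_pb, floor, 0.0)
    return float(-(choices @ log_pa + (1.0 - choices) @ log_pb))


def information_criteria(negll: float, k: int, n: int) -> tuple[float, float]:
    """Half-scale information criteria: (BIC, AIC).

    BIC = negll + 0.5 k ln n; AIC = negll + k. Note this is half the
    conventional 2(-ln L) + k ln n scaling; -BIC then approximates the log
    model evidence directly.
    """
    if k < 0 or n < 1:
        raise ValueError("need k >= 0 and n >= 1")
    return negll + 0.5 * k * np.log(n), negll + k


def _to_natural(theta: np.ndarray, positive: tuple[bool, ...]) -> np.ndarray:
    out = np.array(theta, dtype=float)
    mask = np.asarray(positive)
    out[mask] = np.exp(out[mask])
    return out


def _seed_vector(spec: ModelSpec, branch: str, seed_value: float) -> np.ndarray:
    # positive branch: every natural-scale parameter starts at +seed_value;
    # negative branch: unconstrained parameters start at -seed_value instead
    # (positivity-constrained ones cannot be negative and keep +seed_value).
    theta = np.empty(spec.k)
    for i, pos in enumerate(spec.positive):
        if pos:
            theta[i] = np.log(seed_value)
        else:
            theta[i] = seed_value if branch == "positive" else -seed_value
    return theta


def _run_branch(
    spec: ModelSpec,
    ta: TrialArrays,
    choices: np.ndarray,
    branch: str,
    options: FitOptions,
):
    def objective(theta: np.ndarray) -> float:
        natural = _to_natural(theta, spec.positive)
        params = dict(zip(spec.param_names, natural))
        val = negative_log_likelihood(spec, params, ta, choices)
        return val if np.isfinite(val) else 1e12

    x0 = _seed_vector(spec, branch, options.seed_value)
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": options.xatol,
            "fatol": options.fatol,
            "maxfev": options.maxfev_per_param * spec.k,
            "maxiter": options.maxfev_per_param * spec.k,
        },
    )
    converged = bool(res.success) and np.isfinite(res.fun)
    return res, converged


def fit_participant(
    model: ModelSpec | int,
    trials: Sequence[TrialRecord] | tuple[TrialArrays, np.ndarray],
    options: FitOptions | None = None,
    participant_id: str | None = None,
) -> FitResult:
    """Fit one model to one participant's choices by Nelder-Mead MLE.

    ``trials`` is either a sequence of :class:`TrialRecord` or a pre-built
    ``(TrialArrays, choices)`` pair (the fast path when many models are
    fitted to the same trials). Fitting starts from the positive seed
    branch; on non-convergence the negative branch is tried and the better
    converged result kept. If neither branch converges the best found values
    are returned with ``converged=False``.
    """
    spec = MODELS[model] if isinstance(model, int) else model
    options = options or FitOptions()
    if isinstance(trials, tuple):
        ta, choices = trials
        pid = participant_id or ""
    else:
        ta, choices = build_trial_arrays(trials)
        pid = participant_id or trials[0].participant_id

    res_pos, conv_pos = _run_branch(spec, ta, choices, "positive", options)
    if conv_pos:
        res, converged, branch = res_pos, True, "positive"
    else:
        res_neg, conv_neg = _run_branch(spec, ta, choices, "negative", options)
        if conv_neg:
            res, converged, branch = res_neg, True, "negative"
        else:  # keep the better of the two failed attempts, flagged
            if res_neg.fun < res_pos.fun:
                res, branch = res_neg, "negative"
            else:
                res, branch = res_pos, "positive"
            converged = False

    natural = _to_natural(res.x, spec.positive)
    params = dict(zip(spec.param_names, (float(v) for v in natural)))
    negll = float(res.fun)
    n = ta.n
    bic, aic = information_criteria(negll, spec.k, n)
    return FitResult(
        participant_id=pid,
        model_id=spec.model_id,
        params=params,
        negll=negll,
        n_trials=n,
        bic=bic,
        aic=aic,
        converged=converged,
        seed_branch=branch,
    )


def fit_cohort(
    trials_by_participant: dict[str, Sequence[TrialRecord] | tuple[TrialArrays, np.ndarray]],
    model_ids: Iterable[int],
    options: FitOptions | None = None,
) -> list[FitResult]:
    """Fit a set of models to every participant; one FitResult per cell."""
    results = []
    for pid, trials in trials_by_participant.items():
        if not isinstance(trials, tuple):
            trials = build_trial_arrays(trials)
        for mid in model_ids:
            results.append(
                fit_participant(mid, trials, options=options, participant_id=pid)
            )
    return results


def fits_to_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    """Flatten fit results into a tidy DataFrame (one row per fit)."""
    rows = []
    for r in results:
        row = {
            "participant_id": r.participant_id,
            "model_id": r.model_id,
            "negll": r.negll,
            "n_trials": r.n_trials,
            "bic": r.bic,
            "aic": r.aic,
            "converged": r.converged,
            "seed_branch": r.seed_branch,
        }
        for name, val in r.params.items():
            row[f"param_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def evidence_table(
    results: Sequence[FitResult], criterion: Literal["bic", "aic"] = "bic"
) -> pd.DataFrame:
    """Participants x models table of the chosen information criterion."""
    df = fits_to_frame(results)
    table = df.pivot(index="participant_id", columns="model_id", values=criterion)
    if table.isna().any().any():
        raise ValueError("evidence table has missing participant x model cells")
    return table
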