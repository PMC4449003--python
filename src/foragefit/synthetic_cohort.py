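"""Synthetic datasets with the statistical structure the analysis assumes.

A cohort mirrors the study design: 22 agents each complete 480 gamble pairs
in two frames (960 trials), with both casino blocks preceding both foraging
blocks and each frame split into two blocks. Choices are simulated from a
registered decision model via the softmax rule; a small missed-trial rate
(missing completely at random) matches the reported average of 2 missed
trials per 960. Log reaction times follow a linear mixed-effects generator
driven by the absolute between-option differences in expected value and
starvation probability, with participant-level random intercepts and slopes.

Ground-truth generating parameters are recorded alongside every dataset so
recovery of parameters and of the generating model can be verified end to
end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_models import MODELS, TrialArrays, model_values
from .gamble_engine import GamblePairSpec, GambleSetConfig, generate_gamble_set
from .inference import FRAME_CASINO, FRAME_FORAGING, TrialRecord, _cached_features

__all__ = [
    "AgentSpec",
    "RtGeneratorSpec",
    "DEFAULT_RT_SPEC",
    "simulate_agent",
    "simulate_cohort",
    "simulate_rts",
    "records_to_frame",
    "frame_to_records",
]

#: reported average missed trials per session of 960
DEFAULT_MISSED_RATE = 2.0 / 960.0

DATASET_COLUMNS = [
    "participant_id", "frame", "block", "trial_index", "pair_id",
    "x0", "n", "gA", "pA", "gB", "pB", "choice", "rt_ms",
]


@dataclass(frozen=True)
class AgentSpec:
    """Generating model, parameters and seed for one simulated participant."""

    model_id: int
    params: dict[str, float]
    participant_id: str
    seed: int

    def __post_init__(self) -> None:
        spec = MODELS[self.model_id]
        missing = set(spec.param_names) - set(self.params)
        if missing:
            raise ValueError(
                f"agent for model {self.model_id} missing parameters {sorted(missing)}"
            )
        if self.params["beta"] <= 0:
            raise ValueError("softmax beta must be positive")


@dataclass(frozen=True)
class RtGeneratorSpec:
    """Log-normal RT generator mirroring the mixed-effects analysis model.

    log RT (ms) = g0 + g1*|dEV| + g2*|dPst| + g3*|dEV|*|dPst|
                  + participant random effects on each term + Gaussian noise.
    """

    gamma: tuple[float, float, float, float]
    re_sd: tuple[float, float, float, float]
    resid_sd: float

    def __post_init__(self) -> None:
        if self.resid_sd <= 0:
            raise ValueError("residual SD must be positive")
        if any(s < 0 for s in self.re_sd):
            raise ValueError("random-effect SDs must be non-negative")


#: defaults chosen to emulate a plausible human session: ~1350 ms baseline,
#: faster choices for easier discriminations, slight slowing for the
#: interaction; synthetic values, not estimates from any dataset.
DEFAULT_RT_SPEC = RtGeneratorSpec(
    gamma=(7.2, -0.05, -0.3, 0.15),
    re_sd=(0.25, 0.02, 0.10, 0.05),
    resid_sd=0.35,
)


def _ordered_session(
    pairs: list[GamblePairSpec],
) -> list[tuple[str, int, GamblePairSpec]]:
    """Casino blocks 1-2 then foraging blocks 1-2; pairs split in half."""
    half = (len(pairs) + 1) // 2
    blocks = [(pairs[:half], 1), (pairs[half:], 2)]
    session = []
    for frame in (FRAME_CASINO, FRAME_FORAGING):
        for block_pairs, block in blocks:
            session.extend((frame, block, p) for p in block_pairs)
    return session


def _session_arrays(pairs: list[GamblePairSpec]) -> tuple[list, TrialArrays]:
    session = _ordered_session(pairs)
    feats = [
        _cached_features(
            p.x0, p.n, p.gA, p.pA, p.gB, p.pB,
            1 if frame == FRAME_FORAGING else 0,
        )
        for frame, _block, p in session
    ]
    return session, TrialArrays(feats)


def simulate_agent(
    agent: AgentSpec,
    pairs: list[GamblePairSpec],
    missed_rate: float = DEFAULT_MISSED_RATE,
    _session_cache: tuple[list, TrialArrays] | None = None,
) -> list[TrialRecord]:
    """Forward-simulate one agent's session.

    Each trial's choice is Bernoulli with the agent's softmax probability of
    option A; a fraction ``missed_rate`` of trials is marked missed
    (missing completely at random). Reaction times are left NaN until
    :func:`simulate_rts` fills them. Deterministic given the agent's seed.
    """
    if not pairs:
        raise ValueError("need at least one gamble pair")
    session, ta = _session_cache or _session_arrays(pairs)
    rng = np.random.default_rng(agent.seed)
    v = model_values(agent.model_id, agent.params, ta)
    # P(choose A) via the logistic rule, vectorised over the session
    dv = (v[:, 0] - v[:, 1]) / agent.params["beta"]
    with np.errstate(over="ignore"):  # exp overflow -> P(A) underflows to 0
        p_a = 1.0 / (1.0 + np.exp(-dv))
    chose_a = rng.random(ta.n) < p_a
    missed = rng.random(ta.n) < missed_rate

    records = []
    for i, (frame, block, pair) in enumerate(session):
        choice = "missed" if missed[i] else ("A" if chose_a[i] else "B")
        records.append(
            TrialRecord(
                participant_id=agent.participant_id,
                frame=frame,
                block=block,
                trial_index=i,
                pair=pair,
                choice=choice,
                rt_ms=float("nan"),
            )
        )
    return records


def _draw_params(
    model_id: int,
    param_distribution: dict[str, float | tuple[float, float]],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Fixed values pass through; (mean, sd) tuples draw from a normal,
    truncated to stay positive for positivity-constrained parameters."""
    spec = MODELS[model_id]
    out: dict[str, float] = {}
    for name, pos in zip(spec.param_names, spec.positive):
        setting = param_distribution[name]
        if isinstance(setting, tuple):
            mean, sd = setting
            val = float(rng.normal(mean, sd))
            if pos:
                val = max(val, 0.05)
        else:
            val = float(setting)
        if pos and val <= 0:
            raise ValueError(f"parameter {name} must be positive, got {val}")
        out[name] = val
    return out


def simulate_cohort(
    n_agents: int = 22,
    model_id: int = 7,
    param_distribution: dict[str, float | tuple[float, float]] | None = None,
    gamble_config: GambleSetConfig | None = None,
    seed: int = 0,
    missed_rate: float = DEFAULT_MISSED_RATE,
    pairs: list[GamblePairSpec] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full cohort dataset plus its ground truth.

    Defaults mirror the study shape: 22 agents x (480 pairs x 2 frames),
    casino blocks first, generated by the winning homeostatic model with
    starvation aversion (xi < 0) and moderate decision noise. Returns
    ``(dataset, ground_truth)`` where the dataset follows the canonical CSV
    schema and the ground truth records every agent's generating parameters.
    """
    if n_agents < 1:
        raise ValueError("need at least one agent")
    if param_distribution is None:
        param_distribution = {
            7: {"beta": 0.5, "xi": -3.0},
            10: {"beta": 0.5, "xi_foraging": -3.0, "xi_casino": -1.5},
        }.get(model_id)
        if param_distribution is None:
            raise ValueError(
                f"no default parameters for model {model_id}; pass param_distribution"
            )
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = generate_gamble_set(gamble_config, seed=rng)
    session_cache = _session_arrays(pairs)

    truth: dict = {"model_id": model_id, "seed": seed, "agents": {}}
    all_records: list[TrialRecord] = []
    for i in range(n_agents):
        pid = f"sub{i + 1:02d}"
        params = _draw_params(model_id, param_distribution, rng)
        agent = AgentSpec(
            model_id=model_id,
            params=params,
            participant_id=pid,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth["agents"][pid] = {"params": params, "seed": agent.seed}
        all_records.extend(
            simulate_agent(agent, pairs, missed_rate, _session_cache=session_cache)
        )
    return records_to_frame(all_records), truth


# ---------------------------------------------------------------------------
# Reaction times
# ---------------------------------------------------------------------------

def _pair_stat_columns(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """|dEV| and |dPst| per row, from the pair definition columns."""
    cache: dict[tuple, tuple[float, float]] = {}
    dev = np.empty(len(df))
    dps = np.empty(len(df))
    cols = df[["x0", "n", "gA", "pA", "gB", "pB"]].to_numpy()
    for i, (x0, n, gA, pA, gB, pB) in enumerate(cols):
        key = (int(x0), int(n), int(gA), float(pA), int(gB), float(pB))
        if key not in cache:
            feats = _cached_features(*key, 0)
            cache[key] = (
                abs(feats.stats_a.ev - feats.stats_b.ev),
                abs(feats.stats_a.p_starve - feats.stats_b.p_starve),
            )
        dev[i], dps[i] = cache[key]
    return dev, dps


def simulate_rts(
    dataset: pd.DataFrame,
    spec: RtGeneratorSpec = DEFAULT_RT_SPEC,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill the ``rt_ms`` column with mixed-effects log-normal RTs.

    Missed trials keep NaN. Returns a copy; the input is not modified.
    """
    rng = np.random.default_rng(seed)
    df = dataset.copy()
    dev, dps = _pair_stat_columns(df)
    design = np.column_stack([np.ones(len(df)), dev, dps, dev * dps])
    gamma = np.asarray(spec.gamma)
    re_sd = np.asarray(spec.re_sd)

    log_rt = np.empty(len(df))
    for pid, idx in df.groupby("participant_id", sort=True).groups.items():
        loc = df.index.get_indexer(idx)
        b = rng.normal(0.0, re_sd)
        eta = design[loc] @ (gamma + b)
        log_rt[loc] = eta + rng.normal(0.0, spec.resid_sd, size=loc.size)
    rt = np.exp(log_rt)
    rt[df["choice"].to_numpy() == "missed"] = np.nan
    df["rt_ms"] = rt
    return df


# ---------------------------------------------------------------------------
# Record <-> frame conversion
# ---------------------------------------------------------------------------

def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten TrialRecords into the canonical dataset schema."""
    rows = [
        {
            "participant_id": r.participant_id,
            "frame": r.frame,
            "block": r.block,
            "trial_index": r.trial_index,
            "pair_id": r.pair.pair_id,
            "x0": r.pair.x0,
            "n": r.pair.n,
            "gA": r.pair.gA,
            "pA": r.pair.pA,
            "gB": r.pair.gB,
            "pB": r.pair.pB,
            "choice": r.choice,
            "rt_ms": r.rt_ms,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild TrialRecords from a dataset frame (inverse of records_to_frame)."""
    records = []
    for row in df.itertuples(index=False):
        pair = GamblePairSpec(
            x0=int(row.x0), n=int(row.n),
            gA=int(row.gA), pA=float(row.pA),
            gB=int(row.gB), pB=float(row.pB),
            pair_id=int(row.pair_id),
        )
        records.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                frame=str(row.frame),
                block=int(row.block),
                trial_index=int(row.trial_index),
                pair=pair,
                choice=str(row.choice),
                rt_ms=float(row.rt_ms),
            )
        )
    return records
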