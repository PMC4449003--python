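"""Group-level model comparison.

Fixed-effects analysis sums per-participant information-criterion
differences against a reference model (log-group Bayes factors; with the
half-scale BIC convention used here, smaller values mean more evidence).

Random-effects analysis treats the model identity as a random effect across
participants: population model frequencies follow a Dirichlet distribution
whose posterior is obtained by the standard variational scheme (iterating
participant-wise posterior model assignments against Dirichlet counts).
Exceedance probabilities -- the posterior probability that a model (or a
family of models) is the most frequent in the population -- are estimated by
Monte-Carlo arg-max counting over Dirichlet posterior draws.

Family-level inference equalises the prior mass across families by giving
each model a prior count of (1 / family size), then aggregates sampled
frequencies within families.

Exact sign tests on per-participant parameter estimates use the two-sided
binomial tail under P(positive) = 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import binomtest

__all__ = [
    "BmsResult",
    "log_group_bayes_factors",
    "bms_random_effects",
    "family_bms",
    "sign_test",
]

DEFAULT_N_SAMPLES = 1_000_000
_VB_TOL = 1e-6
_VB_MAX_ITER = 10_000
_CHUNK = 200_000


@dataclass(frozen=True)
class BmsResult:
    """Posterior of the random-effects model-frequency analysis."""

    model_ids: tuple[int, ...]
    alpha: np.ndarray                      # Dirichlet posterior counts
    model_posterior_mean: np.ndarray       # expected model frequencies
    exceedance: np.ndarray                 # per-model exceedance probabilities
    n_samples: int
    seed: int
    families: tuple[str, ...] | None = None
    family_exceedance: np.ndarray | None = None

    def exceedance_by_model(self) -> dict[int, float]:
        return dict(zip(self.model_ids, map(float, self.exceedance)))

    def exceedance_by_family(self) -> dict[str, float]:
        if self.families is None:
            raise ValueError("no family partition in this result")
        return dict(zip(self.families, map(float, self.family_exceedance)))


def _as_matrix(table: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), tuple(table.columns)
    arr = np.asarray(table, dtype=float)
    return arr, tuple(range(1, arr.shape[1] + 1))


def log_group_bayes_factors(
    ic_table: pd.DataFrame, reference_model: int
) -> pd.Series:
    """Per-model group sums of IC differences versus a reference model.

    For each model m the value is Σ_participants (IC_m − IC_ref); the
    reference maps to exactly 0 and smaller values indicate more evidence
    for the model relative to the reference.
    """
    if reference_model not in ic_table.columns:
        raise ValueError(f"reference model {reference_model} not in table")
    diff = ic_table.sub(ic_table[reference_model], axis=0)
    return diff.sum(axis=0)


def _variational_dirichlet(
    log_evidence: np.ndarray, alpha0: np.ndarray
) -> np.ndarray:
    """Posterior Dirichlet counts for population model frequencies."""
    if not np.all(np.isfinite(log_evidence)):
        raise ValueError("log evidences must be finite")
    if np.any(alpha0 <= 0):
        raise ValueError("prior alpha must be positive")
    alpha = alpha0.astype(float).copy()
    for _ in range(_VB_MAX_ITER):
        log_u = log_evidence + digamma(alpha) - digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < _VB_TOL:
            return alpha_new
        alpha = alpha_new
    raise RuntimeError(
        f"variational Dirichlet updates did not converge in {_VB_MAX_ITER} "
        f"iterations; last alpha = {alpha}"
    )


def _sample_argmax_freq(
    alpha: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    group_index: np.ndarray | None = None,
    n_groups: int | None = None,
) -> np.ndarray:
    """Fraction of Dirichlet draws in which each component (or group sum)
    attains the arg-max. Uses unnormalised Gamma draws; arg-max is invariant
    to the normalisation."""
    k_out = n_groups if group_index is not None else alpha.size
    counts = np.zeros(k_out, dtype=np.int64)
    remaining = n_samples
    while remaining > 0:
        m = min(_CHUNK, remaining)
        draws = rng.standard_gamma(alpha, size=(m, alpha.size))
        if group_index is not None:
            grouped = np.zeros((m, k_out))
            np.add.at(grouped.T, group_index, draws.T)
            winners = grouped.argmax(axis=1)
        else:
            winners = draws.argmax(axis=1)
        counts += np.bincount(winners, minlength=k_out)
        remaining -= m
    return counts / n_samples


def bms_random_effects(
    log_evidence: pd.DataFrame | np.ndarray,
    prior_alpha: float | np.ndarray = 1.0,
    seed: int = 0,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> BmsResult:
    """Random-effects Bayesian model selection over a participants x models
    table of log evidences (here: -BIC or -AIC on the half scale).

    Returns the Dirichlet posterior over population model frequencies and
    Monte-Carlo exceedance probabilities.
    """
    lev, model_ids = _as_matrix(log_evidence)
    k = lev.shape[1]
    alpha0 = np.broadcast_to(np.asarray(prior_alpha, dtype=float), (k,)).copy()
    alpha = _variational_dirichlet(lev, alpha0)
    rng = np.random.default_rng(seed)
    exceedance = _sample_argmax_freq(alpha, n_samples, rng)
    return BmsResult(
        model_ids=model_ids,
        alpha=alpha,
        model_posterior_mean=alpha / alpha.sum(),
        exceedance=exceedance,
        n_samples=n_samples,
        seed=seed,
    )


def family_bms(
    log_evidence: pd.DataFrame,
    partition: dict[str, tuple[int, ...]],
    seed: int = 0,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> BmsResult:
    """Family-level random-effects model selection.

    ``partition`` maps family names to tuples of model ids and must cover
    every column of ``log_evidence``. Each family receives equal total prior
    mass (1), split equally among its members, so families of different
    sizes compete on an even footing. The family exceedance probability is
    the posterior probability that the family's summed model frequency
    exceeds every other family's.
    """
    for fam, members in partition.items():
        if len(members) == 0:
            raise ValueError(f"family {fam!r} is empty")
    model_ids = tuple(log_evidence.columns)
    covered = {m for members in partition.values() for m in members}
    if covered != set(model_ids):
        raise ValueError(
            f"partition covers {sorted(covered)} but table has {sorted(model_ids)}"
        )
    families = tuple(partition)
    group_index = np.empty(len(model_ids), dtype=int)
    alpha0 = np.empty(len(model_ids))
    for gi, fam in enumerate(families):
        for m in partition[fam]:
            j = model_ids.index(m)
            group_index[j] = gi
            alpha0[j] = 1.0 / len(partition[fam])

    lev, _ = _as_matrix(log_evidence)
    alpha = _variational_dirichlet(lev, alpha0)
    rng = np.random.default_rng(seed)
    exceedance = _sample_argmax_freq(alpha, n_samples, rng)
    fam_exceedance = _sample_argmax_freq(
        alpha, n_samples, rng, group_index=group_index, n_groups=len(families)
    )
    return BmsResult(
        model_ids=model_ids,
        alpha=alpha,
        model_posterior_mean=alpha / alpha.sum(),
        exceedance=exceedance,
        n_samples=n_samples,
        seed=seed,
        families=families,
        family_exceedance=fam_exceedance,
    )


def sign_test(values, null_median: float = 0.0) -> float:
    """Exact two-sided sign test against a null median.

    Values equal to the null median are dropped (the standard exact-method
    convention). Returns the two-sided binomial tail probability of the
    observed count of values above the null under P = 1/2.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[arr != null_median]
    if arr.size == 0:
        raise ValueError("all values equal the null median; sign test undefined")
    n_pos = int(np.sum(arr > null_median))
    return float(binomtest(n_pos, arr.size, 0.5, alternative="two-sided").pvalue)
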