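"""Linear mixed-effects analysis of log reaction times.

Reaction times index choice difficulty: decisions between options that
differ more in expected value and in starvation probability should be
faster. The model regresses log-transformed RTs on the absolute
between-option differences |dEV| and |dPst| and their interaction, with a
participant-level random intercept and random slopes for every fixed
effect:

    log(RT) ~ dEV + dPst + dEV:dPst + (1 + dEV + dPst + dEV:dPst | participant)

Models are fitted by maximum likelihood (not REML) through statsmodels'
MixedLM so that fixed-effect structures can be compared by likelihood-ratio
tests: each fixed effect's significance comes from comparing the full model
to the model without that term, keeping the random-effects structure fixed.
If the full random-effects covariance is singular or the fit fails, the
random structure falls back to an intercept-only specification with a
logged warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

import statsmodels.formula.api as smf

from .synthetic_cohort import _pair_stat_columns

__all__ = ["RtModelResult", "fit_rt_model", "prepare_rt_frame"]

logger = logging.getLogger(__name__)

_FIXED_TERMS = ("dev", "dps", "dev:dps")
_FULL_RE = "~dev + dps + dev_x_dps"


@dataclass(frozen=True)
class RtModelResult:
    """Fixed effects, t-values and likelihood-ratio tests for log RTs."""

    estimates: dict[str, float]
    t_values: dict[str, float]
    loglik_full: float
    loglik_reduced: dict[str, float]
    lrt_stat: dict[str, float]
    lrt_p: dict[str, float]
    re_structure: str  # "full" or "intercept"


def prepare_rt_frame(dataset: pd.DataFrame) -> pd.DataFrame:
    """Non-missed trials with log RTs and difficulty predictors.

    Predictors are the per-trial absolute differences between the two
    options in EV and p_starve (uncentred), plus their product.
    """
    kept = dataset[dataset["choice"] != "missed"].copy()
    rts = kept["rt_ms"].to_numpy(dtype=float)
    if np.any(~np.isfinite(rts)) or np.any(rts <= 0):
        raise ValueError(
            "rt_ms must be positive and finite on all non-missed trials; "
            "RTs must be supplied on the millisecond scale, the log "
            "transform is applied here"
        )
    dev, dps = _pair_stat_columns(kept)
    kept["dev"] = dev
    kept["dps"] = dps
    kept["dev_x_dps"] = dev * dps
    kept["log_rt"] = np.log(rts)
    return kept


def _fit_ml(data: pd.DataFrame, fixed: str, re_formula: str):
    model = smf.mixedlm(
        fixed, data, groups=data["participant_id"], re_formula=re_formula
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=False, maxiter=500)


def _formula(drop: str | None) -> str:
    terms = [t for t in _FIXED_TERMS if t != drop]
    return "log_rt ~ " + " + ".join(terms)


def fit_rt_model(dataset: pd.DataFrame, re_structure: str = "full") -> RtModelResult:
    """Fit the log-RT mixed model and test each fixed effect by LRT.

    Parameters
    ----------
    dataset : DataFrame
        Canonical dataset schema; rt_ms in milliseconds on non-missed trials.
    re_structure : {"full", "intercept"}
        Random-effects specification; "full" includes random slopes for all
        fixed effects and falls back to "intercept" on singular fits.
    """
    data = prepare_rt_frame(dataset)
    if re_structure not in ("full", "intercept"):
        raise ValueError("re_structure must be 'full' or 'intercept'")
    re_formula = _FULL_RE if re_structure == "full" else "~1"

    def fit_all(re_form: str):
        full = _fit_ml(data, _formula(None), re_form)
        reduced = {t: _fit_ml(data, _formula(t), re_form) for t in _FIXED_TERMS}
        return full, reduced

    used = re_structure
    try:
        full, reduced = fit_all(re_formula)
        singular = not np.all(np.isfinite(full.bse_fe)) or not np.isfinite(full.llf)
    except (np.linalg.LinAlgError, ValueError):
        singular = True
    if re_structure == "full" and singular:
        logger.warning(
            "full random-effects covariance singular or fit failed; "
            "falling back to random intercept only"
        )
        used = "intercept"
        full, reduced = fit_all("~1")

    estimates, t_values = {}, {}
    for term in _FIXED_TERMS:
        key = term.replace(":", ":")
        estimates[term] = float(full.fe_params[key])
        t_values[term] = float(full.fe_params[key] / full.bse_fe[key])

    loglik_full = float(full.llf)
    loglik_reduced, lrt_stat, lrt_p = {}, {}, {}
    for term, res in reduced.items():
        ll = float(res.llf)
        # ML log-likelihood of the nested model can exceed the full model's
        # only through optimiser noise; clamp the statistic at zero.
        stat = max(0.0, 2.0 * (loglik_full - ll))
        loglik_reduced[term] = ll
        lrt_stat[term] = stat
        lrt_p[term] = float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return RtModelResult(
        estimates=estimates,
        t_values=t_values,
        loglik_full=loglik_full,
        loglik_reduced=loglik_reduced,
        lrt_stat=lrt_stat,
        lrt_p=lrt_p,
        re_structure=used,
    )
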