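"""Condition-level inference on block-summary outcome tables.

Implements the repeated-measures machinery used to compare the five task
conditions on physiological/behavioural outcomes: a linear mixed-effects
model (REML) with a random intercept per participant and condition plus
design nuisance factors (group, time, group x time) as fixed effects;
estimated marginal means (EMMs) per condition; all pairwise condition
contrasts with Tukey familywise adjustment via the studentized-range
distribution; and the pooled within-participant correlation between
breathing frequency and RVT (both outcomes centered on participant means,
CI by Fisher z).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .exceptions import InvalidArgumentError, InvalidStateError

NUISANCE_FACTORS = ("group", "time")


@dataclass
class ConditionModel:
    """Fitted mixed model plus the bookkeeping needed for EMMs."""

    result: object
    outcome: str
    data: pd.DataFrame
    condition_levels: tuple
    df_contrast: float

    @property
    def converged(self) -> bool:
        return bool(getattr(self.result, "converged", True))


@dataclass(frozen=True)
class EMMResult:
    emmeans: pd.DataFrame  # condition, mean, se, df, ci_low, ci_high
    contrasts: pd.DataFrame  # a, b, estimate, se, df, t, p_unadjusted, p_tukey


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    ci_low: float
    ci_high: float
    p: float
    n_obs: int
    method: str


def fit_condition_model(table: pd.DataFrame, outcome: str) -> ConditionModel:
    """REML mixed model: outcome ~ condition + nuisance, random intercept per participant.

    Condition enters without an intercept and the nuisance factors (group,
    time, and their interaction, when present with >= 2 levels) enter
    sum-coded, so on balanced data the condition coefficients are directly
    the estimated marginal means.
    """
    if outcome not in table.columns:
        raise InvalidArgumentError(f"outcome column '{outcome}' not in table")
    if table["participant"].nunique() < 2:
        raise InvalidArgumentError("need >= 2 participants")
    if table["condition"].nunique() < 2:
        raise InvalidArgumentError("need >= 2 conditions")
    if table[outcome].std() == 0:
        raise InvalidArgumentError(f"outcome '{outcome}' is constant")

    terms = ["0", "C(condition)"]
    for f in NUISANCE_FACTORS:
        if f in table.columns:
            if table[f].nunique() < 2:
                warnings.warn(f"nuisance factor '{f}' has one level; dropped", stacklevel=2)
            else:
                terms.append(f"C({f}, Sum)")
    if all(f"C({f}, Sum)" in terms for f in NUISANCE_FACTORS):
        terms.append("C(group, Sum):C(time, Sum)")
    formula = f"{outcome} ~ " + " + ".join(terms)

    model = smf.mixedlm(formula, table, groups=table["participant"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise InvalidArgumentError(
            "singular fixed-effects design; check condition/group/time coding"
        )
    df_contrast = len(table) - rank - table["participant"].nunique() + 1
    levels = tuple(sorted(table["condition"].unique()))
    return ConditionModel(result, outcome, table, levels, float(df_contrast))


def _condition_param_indices(model: ConditionModel) -> dict:
    names = list(model.result.fe_params.index)
    out = {}
    for lev in model.condition_levels:
        key = f"C(condition)[{lev}]"
        if key not in names:
            raise InvalidStateError(f"condition level '{lev}' missing from fitted model")
        out[lev] = names.index(key)
    return out


def condition_f_test(model: ConditionModel) -> tuple[float, float]:
    """Wald test of equal condition means: returns (F statistic, p value).

    The chi-square Wald statistic is converted to an F on (k−1, df_contrast)
    degrees of freedom; with hundreds of residual df the two scales agree.
    """
    idx = _condition_param_indices(model)
    k = len(idx)
    n_fe = len(model.result.fe_params)
    L = np.zeros((k - 1, n_fe))
    base = idx[model.condition_levels[0]]
    for i, lev in enumerate(model.condition_levels[1:]):
        L[i, base] = 1.0
        L[i, idx[lev]] = -1.0
    cov = model.result.cov_params().to_numpy()[:n_fe, :n_fe]
    beta = model.result.fe_params.to_numpy()
    diff = L @ beta
    stat = float(diff @ np.linalg.solve(L @ cov @ L.T, diff))
    f_stat = stat / (k - 1)
    p = float(stats.f.sf(f_stat, k - 1, model.df_contrast))
    return f_stat, p


def emm_and_tukey(model: ConditionModel, alpha: float = 0.05) -> EMMResult:
    """Estimated marginal means per condition and Tukey-adjusted pairwise contrasts.

    With sum-coded nuisance factors the condition coefficients are the EMMs
    averaged over nuisance levels; contrast p-values use the studentized
    range distribution with k conditions and the model's contrast df.
    """
    if model.result is None:
        raise InvalidStateError("model is not fitted")
    idx = _condition_param_indices(model)
    beta = model.result.fe_params.to_numpy()
    n_fe = len(beta)
    cov = model.result.cov_params().to_numpy()[:n_fe, :n_fe]
    df = model.df_contrast
    tcrit = stats.t.ppf(1 - alpha / 2, df)

    em_rows = []
    for lev in model.condition_levels:
        m, se = beta[idx[lev]], np.sqrt(cov[idx[lev], idx[lev]])
        em_rows.append(
            dict(condition=lev, mean=m, se=se, df=df, ci_low=m - tcrit * se, ci_high=m + tcrit * se)
        )
    k = len(model.condition_levels)
    ct_rows = []
    for a, b in itertools.combinations(model.condition_levels, 2):
        est = beta[idx[a]] - beta[idx[b]]
        var = cov[idx[a], idx[a]] + cov[idx[b], idx[b]] - 2 * cov[idx[a], idx[b]]
        se = np.sqrt(var)
        t = est / se
        p_un = 2 * stats.t.sf(abs(t), df)
        p_tk = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df))
        ct_rows.append(
            dict(a=a, b=b, estimate=est, se=se, df=df, t=t,
                 p_unadjusted=p_un, p_tukey=min(1.0, p_tk),
                 ci_low=est - tcrit * se, ci_high=est + tcrit * se)
        )
    return EMMResult(emmeans=pd.DataFrame(em_rows), contrasts=pd.DataFrame(ct_rows))


def within_participant_correlation(
    table: pd.DataFrame,
    x: str = "frequency_hz",
    y: str = "rvt_au",
    method: str = "pooled",
) -> CorrelationResult:
    """Within-participant correlation of two block-level outcomes.

    Both variables are centered on participant means and pooled; Pearson r
    is computed on the centered values.  ``method='pooled'`` uses
    df = N_obs − 2 (naive pooled convention); ``method='rmcorr'`` uses the
    repeated-measures convention df = N_obs − n_participants − 1.  The CI
    is by Fisher z either way.  Participants with zero within-variance in
    either variable are excluded with a warning.
    """
    if method not in ("pooled", "rmcorr"):
        raise InvalidArgumentError(f"unknown method '{method}'")
    good = []
    for p, g in table.groupby("participant"):
        if len(g) < 3:
            raise InvalidArgumentError(f"participant {p} has fewer than 3 blocks")
        if g[x].std() == 0 or g[y].std() == 0:
            warnings.warn(f"participant {p} has zero within-variance; excluded", stacklevel=2)
            continue
        good.append(g)
    if not good:
        raise InvalidArgumentError("no participants with within-variance")
    data = pd.concat(good)
    cx = data[x] - data.groupby(data["participant"])[x].transform("mean")
    cy = data[y] - data.groupby(data["participant"])[y].transform("mean")
    n = len(data)
    r = float(np.corrcoef(cx, cy)[0, 1])
    df = n - 2 if method == "pooled" else n - data["participant"].nunique() - 1
    t = r * np.sqrt(df / max(1e-12, 1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zse = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.975)
    return CorrelationResult(
        r=r,
        df=int(df),
        ci_low=float(np.tanh(z - zcrit * zse)),
        ci_high=float(np.tanh(z + zcrit * zse)),
        p=float(p),
        n_obs=n,
        method=method,
    )
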