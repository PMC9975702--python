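"""Post-hoc statistics on mode loadings.

Covers the clinical follow-up analyses: OLS models of loadings on age,
age² and sex; diagnosis-category contrasts against a "no diagnosis"
reference with Tukey (studentized-range) multiplicity adjustment of
estimated-marginal-mean differences; a linear trend of loadings on the
number of comorbid diagnoses; and robustness reruns (sex-residualised
refit, partial-correlation variants, leave-one-diagnosis-out projection)
summarised as concordance correlations with the original variable
loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import studentized_range

from .blocks import ConfoundTable, DataBlock
from .decompose import (DecompositionConfig, ModeSet,
                        compute_variable_loadings, run_full_decomposition)
from .preprocess import residualise

__all__ = [
    "CovariateModelResult",
    "TrendResult",
    "fit_covariate_model",
    "diagnosis_contrasts",
    "comorbidity_trend",
    "robustness_reruns",
]

DEFAULT_COVARIATES = ("age", "age2", "sex")


def _covariate_design(confounds: ConfoundTable, terms) -> tuple[np.ndarray, list[str]]:
    """Design columns for terms like age, age2 (centered age squared), sex."""
    cols, names = [], []
    frame = confounds.frame
    age_c = None
    if "age" in frame.columns:
        age = frame["age"].to_numpy(float)
        age_c = age - age.mean()
    for term in terms:
        if term == "age":
            cols.append(age_c)
            names.append("age")
        elif term == "age2":
            if age_c is None:
                raise KeyError("age2 requested but no age column")
            cols.append(age_c ** 2)    # centered age, decorrelates the two terms
            names.append("age2")
        elif term in confounds.categorical:
            levels = sorted(frame[term].unique())
            for lev in levels[1:]:
                cols.append((frame[term] == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
        elif term in confounds.continuous:
            cols.append(frame[term].to_numpy(float))
            names.append(term)
        else:
            raise KeyError(f"unknown model term {term!r}")
    return (np.column_stack(cols) if cols else np.empty((len(frame), 0))), names


@dataclass
class CovariateModelResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray
    df_resid: int


def fit_covariate_model(
    loadings: np.ndarray,
    confounds: ConfoundTable,
    terms=DEFAULT_COVARIATES,
) -> CovariateModelResult:
    """OLS of one mode's loadings on the named covariate terms."""
    y = np.asarray(loadings, float)
    X, names = _covariate_design(confounds, terms)
    X1 = np.column_stack([np.ones(len(y)), X])
    names = ["intercept"] + names
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError(f"rank-deficient design over terms {list(terms)}")
    fit = sm.OLS(y, X1).fit()
    return CovariateModelResult(
        pd.Series(fit.params, index=names), pd.Series(fit.bse, index=names),
        pd.Series(fit.pvalues, index=names), np.asarray(fit.fittedvalues),
        np.asarray(fit.resid), int(fit.df_resid))


def diagnosis_contrasts(
    loadings: np.ndarray,
    diagnosis: pd.Series | np.ndarray,
    confounds: ConfoundTable | None = None,
    reference: str = "no diagnosis",
    covariates=DEFAULT_COVARIATES,
    family: str = "all-pairwise",
) -> pd.DataFrame:
    """Each diagnostic category vs the reference, Tukey-adjusted.

    Fits ``loading ~ diagnosis + covariates``; because the model is
    additive, the difference in estimated marginal means (covariates held
    at sample means) between a category and the reference equals that
    category's dummy coefficient. The adjusted p uses the studentized-range
    distribution at q = |t|·√2 with ``k`` groups — all observed groups for
    ``family="all-pairwise"``, contrasts+1 for ``family="vs-reference"`` —
    and the residual df. With two groups and no covariates this reduces
    exactly to the pooled two-sample t-test.
    """
    diag = pd.Series(np.asarray(diagnosis, dtype=object)).astype(str)
    y = np.asarray(loadings, float)
    groups = sorted(diag.unique())
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least two diagnosis categories")
    counts = diag.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"categories with < 2 participants: {list(small.index)}")

    others = [g for g in groups if g != reference]
    dummies = np.column_stack([(diag == g).to_numpy(float) for g in others])
    if confounds is not None and covariates:
        Xcov, _ = _covariate_design(confounds, covariates)
    else:
        Xcov = np.empty((len(y), 0))
    X = np.column_stack([np.ones(len(y)), dummies, Xcov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient contrast design")
    fit = sm.OLS(y, X).fit()
    df = int(fit.df_resid)
    if family == "all-pairwise":
        k_groups = len(groups)
    elif family == "vs-reference":
        k_groups = len(others) + 1
    else:
        raise ValueError(f"unknown family {family!r}")

    rows = []
    tcrit = stats.t.ppf(0.975, df)
    for i, g in enumerate(others):
        beta = fit.params[1 + i]
        se = fit.bse[1 + i]
        t = beta / se
        if k_groups == 2:
            p_adj = 2 * stats.t.sf(abs(t), df)
        else:
            p_adj = float(studentized_range.sf(abs(t) * np.sqrt(2), k_groups, df))
        rows.append((g, beta, se, df, beta - tcrit * se, beta + tcrit * se,
                     t, min(1.0, p_adj)))
    return pd.DataFrame(rows, columns=["comparison", "beta", "se", "df",
                                       "ci_low", "ci_high", "t", "p_adj"])


@dataclass
class TrendResult:
    slope: float
    se: float
    p: float
    n: int


def comorbidity_trend(
    loadings: np.ndarray,
    n_diagnoses: np.ndarray,
    confounds: ConfoundTable | None = None,
    include_zero: bool = True,
    covariates=DEFAULT_COVARIATES,
) -> TrendResult:
    """Linear trend of mode loadings on the number of diagnoses."""
    y = np.asarray(loadings, float)
    counts = np.asarray(n_diagnoses, float)
    if (counts < 0).any():
        raise ValueError("n_diagnoses must be non-negative")
    keep = np.ones(len(y), bool) if include_zero else counts > 0
    if np.ptp(counts[keep]) == 0:
        raise ValueError("all retained participants share one diagnosis count")
    if confounds is not None and covariates:
        Xcov, _ = _covariate_design(confounds, covariates)
    else:
        Xcov = np.empty((len(y), 0))
    X = np.column_stack([np.ones(keep.sum()), counts[keep], Xcov[keep]])
    fit = sm.OLS(y[keep], X).fit()
    return TrendResult(float(fit.params[1]), float(fit.bse[1]),
                       float(fit.pvalues[1]), int(keep.sum()))


def _mode_concordance(original: ModeSet, new_loadings: pd.DataFrame) -> np.ndarray:
    """Pearson r between original and rerun variable-loading vectors per mode."""
    out = np.empty(original.n_modes)
    base = original.variable_loadings
    for k in range(original.n_modes):
        a = base[base["mode"] == k + 1].set_index(["block", "variable"])["loading"]
        b = new_loadings[new_loadings["mode"] == k + 1].set_index(
            ["block", "variable"])["loading"]
        b = b.loc[a.index]
        valid = a.notna() & b.notna()
        out[k] = stats.pearsonr(a[valid], b[valid]).statistic
    return out


def robustness_reruns(
    imaging: DataBlock,
    behaviour: DataBlock,
    confounds: ConfoundTable,
    modes: ModeSet,
    scheme: str,
    config: DecompositionConfig | None = None,
    leave_out_category: str | None = None,
    diagnosis: pd.Series | None = None,
) -> np.ndarray:
    """Stability of the variable-loading pattern under a robustness scheme.

    Schemes: ``sex-residualised`` refits the whole pipeline on
    sex-residualised behaviour and matches modes across fits;
    ``age-partial`` / ``income-partial`` / ``medication-partial`` recompute
    variable loadings as partial correlations controlling that covariate;
    ``leave-out-category`` drops one diagnosis group, projects the
    remainder through the original weights, and recomputes loadings.
    Returns the per-mode concordance r with the original variable loadings.
    """
    partial_map = {"age-partial": "age", "income-partial": "household_income",
                   "medication-partial": "medication"}
    if scheme == "sex-residualised":
        behav_res = residualise(behaviour, confounds, ["sex"])
        cfg = config or DecompositionConfig(**{k: v for k, v in modes.config.items()
                                               if k in DecompositionConfig().__dict__})
        rerun = run_full_decomposition(imaging, behav_res, cfg)
        from .reliability import match_modes
        perm, _ = match_modes(modes, rerun)
        vl = rerun.variable_loadings.copy()
        remap = {int(p) + 1: k + 1 for k, p in enumerate(perm)}
        vl["mode"] = vl["mode"].map(remap)
        return _mode_concordance(modes, vl)
    if scheme in partial_map:
        vl = compute_variable_loadings(modes, imaging, behaviour,
                                       covariates_to_partial=[partial_map[scheme]],
                                       confounds=confounds)
        return _mode_concordance(modes, vl)
    if scheme == "leave-out-category":
        if diagnosis is None:
            raise ValueError("leave-out-category needs the diagnosis series")
        diag = pd.Series(np.asarray(diagnosis, dtype=object)).astype(str)
        keep = np.where((diag != leave_out_category).to_numpy())[0]
        img_sub = imaging.take_rows(keep)
        beh_sub = behaviour.take_rows(keep)
        sub = ModeSet(
            modes.unmixing,
            (img_sub.values - modes.brain_mean) @ modes.brain_projection,
            (beh_sub.values - modes.behav_mean) @ modes.behav_projection,
            modes.mode_corrs, modes.brain_projection, modes.behav_projection,
            modes.brain_mean, modes.behav_mean, modes.brain_variables,
            modes.behav_variables, img_sub.participant_ids)
        vl = compute_variable_loadings(sub, img_sub, beh_sub)
        return _mode_concordance(modes, vl)
    raise ValueError(f"unknown scheme {scheme!r}")
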