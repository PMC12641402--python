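"""Longitudinal inference on dysconnectivity indices.

The central model is a linear mixed model for repeated measures,

    DCI_ijk = b0 + b1*Session_j + b2*Age_i + b3*Sex_i + b4*CPZ_i
              + b5*Trainings_i + b6*Group_i + b7*Hemisphere_k + g_i + e_ijk,

with a random intercept g_i per participant, fitted by REML. One such model
is fitted per DCI outcome (whole brain, eight networks, four anatomical
seed scopes — thirteen in total); the session p-values are corrected across
outcomes by Benjamini-Hochberg FDR, and significant outcomes receive a post
hoc baseline-vs-follow-up contrast expressed as Cohen's d (standardised by
the model-based total SD, sqrt(intercept variance + residual variance)).

Region-resolved analyses: a per-region repeated-measures session-effect map
(for parcellation and transcriptomic annotation) and per-region ordinary
least squares of clinical change scores on DCC change, thresholded
descriptively at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

CLINICAL_SCORES = ("GAF", "PANSS", "cognition")

#: fixed-effect covariates of the longitudinal model, beyond session
LMM_COVARIATES = ("age", "sex", "cpz", "trainings", "group", "hemisphere")


@dataclass
class LMMResult:
    outcome: str
    n_obs: int
    n_subjects: int
    params: pd.Series
    bse: pd.Series
    session_coef: float
    session_se: float
    session_p: float
    re_var: float
    resid_var: float
    df_resid: int
    converged: bool
    singular: bool
    qvalue: float | None = None


@dataclass
class PosthocResult:
    outcome: str
    contrast: str
    cohen_d: float
    ci95: tuple[float, float]
    p_tukey: float
    standardiser: str = "sqrt(random-intercept variance + residual variance)"


def _encode_design(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns: session/sex/group/hemisphere as 0-1 dummies."""
    df = table.copy()
    df["session_followup"] = (df["session"] == "followup").astype(float)
    if "sex" in df:
        df["sex_male"] = (df["sex"].astype(str) == "M").astype(float)
    if "group" in df:
        df["group_fsbt"] = (df["group"].astype(str) == "FSBT").astype(float)
    if "hemisphere" in df:
        df["hemisphere_right"] = (df["hemisphere"].astype(str) == "R").astype(float)
    return df


def _fixed_columns(df: pd.DataFrame, covariates) -> list[str]:
    rename = {"sex": "sex_male", "group": "group_fsbt", "hemisphere": "hemisphere_right"}
    cols = ["session_followup"]
    for c in covariates:
        col = rename.get(c, c)
        if col in df and df[col].nunique() > 1:
            cols.append(col)
    return cols


def _fit_mixedlm(model: MixedLM):
    """REML fit with optimizer fallback (boundary variance fits can make a
    single optimizer's linear algebra blow up)."""
    last: Exception | None = None
    for method in ("bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return model.fit(reml=True, method=method)
        except np.linalg.LinAlgError as exc:  # try the next optimizer
            last = exc
    raise last  # pragma: no cover


def fit_dci_lmm(
    table: pd.DataFrame,
    outcome: str = "dci",
    covariates=LMM_COVARIATES,
) -> LMMResult:
    """REML random-intercept fit of a DCI outcome on session and covariates.

    ``table`` is tidy with one row per (subject, session[, hemisphere]) and
    columns ``subject, session, <outcome>`` plus the covariates. Constant
    covariate columns are dropped from the design. A response with (near)
    zero variance yields the degenerate zero fit with a singular flag, as
    does a boundary fit of the random-intercept variance.
    """
    subjects = table["subject"].unique()
    if len(subjects) < 8:
        raise ValueError("need at least 8 subjects")
    if set(table["session"].unique()) != {"baseline", "followup"}:
        raise ValueError("both sessions must be present")
    df = _encode_design(table).reset_index(drop=True)
    y = df[outcome].to_numpy(dtype=float)
    cols = _fixed_columns(df, covariates)
    label = table.attrs.get("scope", outcome)

    # continuous covariates are z-scored for numerical stability; this leaves
    # the session estimate, its SE and p unchanged (their own coefficients
    # are then per covariate SD)
    for c in cols:
        if c != "session_followup":
            v = df[c].to_numpy(dtype=float)
            if not set(np.unique(v)) <= {0.0, 1.0}:
                df[c] = (v - v.mean()) / v.std()

    if np.var(y) < 1e-14:
        zeros = pd.Series(0.0, index=["const"] + cols)
        return LMMResult(
            outcome=label, n_obs=len(df), n_subjects=len(subjects),
            params=zeros, bse=zeros.copy(),
            session_coef=0.0, session_se=0.0, session_p=1.0,
            re_var=0.0, resid_var=0.0,
            df_resid=len(df) - len(cols) - 1, converged=True, singular=True,
        )

    exog = sm.add_constant(df[cols].to_numpy(), has_constant="add")
    names = ["const"] + cols
    model = MixedLM(y, exog, groups=df["subject"].to_numpy())
    fit = _fit_mixedlm(model)
    params = pd.Series(fit.fe_params, index=names)
    bse = pd.Series(np.asarray(fit.bse_fe), index=names)
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    pvals = pd.Series(np.asarray(fit.pvalues)[: len(names)], index=names)
    return LMMResult(
        outcome=label, n_obs=len(df), n_subjects=len(subjects),
        params=params, bse=bse,
        session_coef=float(params["session_followup"]),
        session_se=float(bse["session_followup"]),
        session_p=float(pvals["session_followup"]),
        re_var=re_var, resid_var=float(fit.scale),
        df_resid=len(df) - len(names),
        converged=bool(fit.converged), singular=re_var < 1e-10,
    )


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def posthoc_session(table: pd.DataFrame, fit: LMMResult) -> PosthocResult:
    """Baseline-vs-follow-up contrast as Cohen's d with its 95% CI.

    With exactly two session levels the Tukey family collapses to the single
    session contrast; d is the session coefficient divided by the model-based
    total SD, sqrt(random-intercept variance + residual variance). The CI is
    a delta-method interval that carries both the contrast's sampling error
    and the uncertainty of the standardiser (variance term d^2 / (2(n-1)),
    n = subjects, the classical Cohen's-d variance contribution; a plain
    rescaling of the contrast's t interval ignores it and undercovers).
    A negative d means the DCI was lower at follow-up.
    """
    total_var = fit.re_var + fit.resid_var
    if total_var <= 0:
        raise ValueError("total variance is zero; Cohen's d undefined")
    sd = float(np.sqrt(total_var))
    d = fit.session_coef / sd
    tcrit = sps.t.ppf(0.975, fit.df_resid)
    se_d = float(np.sqrt((fit.session_se / sd) ** 2
                         + d * d / (2 * (fit.n_subjects - 1))))
    lo = d - tcrit * se_d
    hi = d + tcrit * se_d
    tstat = fit.session_coef / fit.session_se if fit.session_se > 0 else np.inf
    p = float(2.0 * sps.t.sf(abs(tstat), fit.df_resid))
    return PosthocResult(
        outcome=fit.outcome, contrast="baseline vs followup",
        cohen_d=float(d), ci95=(float(lo), float(hi)), p_tukey=p,
    )


def dci_battery(
    dci_df: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, LMMResult], dict[str, PosthocResult]]:
    """Fit the thirteen-outcome longitudinal battery with FDR and post hocs.

    ``dci_df`` is the tidy (subject, session, hemisphere, scope, dci) table;
    one mixed model is fitted per scope, session p-values are BH-corrected
    across scopes, and scopes significant at q < ``alpha`` receive the post
    hoc session contrast.
    """
    scopes = list(dict.fromkeys(dci_df["scope"]))
    fits: dict[str, LMMResult] = {}
    for scope in scopes:
        sub = dci_df[dci_df["scope"] == scope].merge(covariates, on="subject")
        sub.attrs["scope"] = scope
        fits[scope] = fit_dci_lmm(sub)
    qvals = fdr_bh([fits[s].session_p for s in scopes])
    posthocs: dict[str, PosthocResult] = {}
    rows = []
    for scope, q in zip(scopes, qvals):
        fit = fits[scope]
        fit.qvalue = float(q)
        row = {
            "scope": scope, "session_coef": fit.session_coef,
            "session_p": fit.session_p, "q": fit.qvalue,
            "cohen_d": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "p_tukey": np.nan,
        }
        if q < alpha and fit.re_var + fit.resid_var > 0:
            sub = dci_df[dci_df["scope"] == scope].merge(covariates, on="subject")
            ph = posthoc_session(sub, fit)
            posthocs[scope] = ph
            row.update(cohen_d=ph.cohen_d, ci_lo=ph.ci95[0], ci_hi=ph.ci95[1],
                       p_tukey=ph.p_tukey)
        rows.append(row)
    return pd.DataFrame(rows), fits, posthocs


def session_effect_map(
    dcc_df: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_names=("age", "sex", "cpz", "trainings", "group"),
) -> pd.DataFrame:
    """Per-region repeated-measures session effect on the DCC.

    ``dcc_df`` is wide: columns ``subject, session`` plus one column per
    region. Each region gets a random-intercept model of DCC on session and
    the between-subject covariates; the returned statistic is the *negated*
    session t-value, so positive values mean dysconnectivity decreased from
    baseline to follow-up (aligned with the change-map sign convention).
    """
    regions = [c for c in dcc_df.columns if c not in ("subject", "session")]
    merged = dcc_df.merge(covariates, on="subject")
    df = _encode_design(merged)
    cols = _fixed_columns(df, covariate_names)
    for c in cols:  # z-score continuous covariates (numerical stability)
        if c != "session_followup":
            v = df[c].to_numpy(dtype=float)
            if not set(np.unique(v)) <= {0.0, 1.0}:
                df[c] = (v - v.mean()) / v.std()
    exog = sm.add_constant(df[cols].to_numpy(), has_constant="add")
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise ValueError(f"rank-deficient design; aliased columns among {cols}")
    groups = df["subject"].to_numpy()
    k = cols.index("session_followup") + 1  # +1 for the constant
    rows = []
    for region in regions:
        y = df[region].to_numpy(dtype=float)
        if np.var(y) < 1e-14:
            rows.append({"region": region, "statistic": 0.0, "p": 1.0})
            continue
        fit = _fit_mixedlm(MixedLM(y, exog, groups=groups))
        t = float(fit.fe_params[k] / np.asarray(fit.bse_fe)[k])
        p = float(np.asarray(fit.pvalues)[k])
        rows.append({"region": region, "statistic": -t, "p": p})
    return pd.DataFrame(rows)


def voxelwise_clinical_regression(
    change_maps: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes=CLINICAL_SCORES,
    alpha: float = 0.05,
    covariate_names=("age", "sex", "cpz"),
) -> dict[str, pd.DataFrame]:
    """Per-region OLS of clinical change on DCC change, with confounders.

    ``change_maps``: one row per subject (column ``subject`` plus one column
    per region) of standardised DCC change scores (positive = reduction).
    ``clinical``: per-subject change scores, positive = improvement. Each
    region is regressed separately, controlling for age, sex and CPZ dose;
    the beta map is thresholded descriptively at unadjusted p < ``alpha``.
    """
    regions = [c for c in change_maps.columns if c != "subject"]
    merged = change_maps.merge(clinical, on="subject").merge(covariates, on="subject")
    df = _encode_design(merged.assign(session="baseline"))
    rename = {"sex": "sex_male", "group": "group_fsbt"}
    conf = [rename.get(c, c) for c in covariate_names if rename.get(c, c) in df]
    conf = [c for c in conf if df[c].nunique() > 1]
    n = len(df)
    if n <= len(conf) + 2:
        raise ValueError("too few subjects for the covariate set")
    out: dict[str, pd.DataFrame] = {}
    confmat = df[conf].to_numpy(dtype=float) if conf else np.empty((n, 0))
    for outcome in outcomes:
        y = df[outcome].to_numpy(dtype=float)
        rows = []
        for region in regions:
            x = np.column_stack([np.ones(n), df[region].to_numpy(dtype=float), confmat])
            fit = sm.OLS(y, x).fit()
            beta, p = float(fit.params[1]), float(fit.pvalues[1])
            rows.append({
                "region": region, "beta": beta, "p": p,
                "beta_thresholded": beta if p < alpha else np.nan,
            })
        out[outcome] = pd.DataFrame(rows)
    return out
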