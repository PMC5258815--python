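"""Predictive modelling: grouped logistic models, ROC/AUC, elastic net, LMM.

The modelling strategy mirrors small-cohort biomarker practice: fit plain
logistic models for predefined groups of related predictors, compare their
ROC curves, then let an elastic-net-penalized logistic regression choose
the optimal combined model, tuning the mixing parameter and penalty
strength by repeated stratified random holdouts ("leave-group-out"
cross-validation) scored by holdout AUC.  eGFR trajectories are modelled
with a linear mixed-effects model: fixed effects for time, follow-up DSR
status and their interaction, plus a random intercept per patient; the
interaction p-value comes from an ML likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .errors import ConfigError

#: Coefficient magnitude (on standardized scale) treated as separation.
SEPARATION_CAP = 15.0


@dataclass(frozen=True)
class PredictorGroupSpec:
    """A named group of related predictor columns."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("group must have at least one member")


#: Predefined groups of related predictors over the columns of
#: :func:`patient_features`.
DEFAULT_PREDICTOR_GROUPS: tuple[PredictorGroupSpec, ...] = (
    PredictorGroupSpec("demographics", ("age_at_tx", "sex_male")),
    PredictorGroupSpec(
        "recipient_factors", ("prior_rejection", "dialysis_months_pre_tx")
    ),
    PredictorGroupSpec("hla_antibody", ("hla_ab_dsa", "log_dsa_t1")),
    PredictorGroupSpec(
        "biopsy_features",
        ("banff_g", "banff_ptc", "banff_cg", "banff_cv", "c4d_ptc", "ifta_pct"),
    ),
    PredictorGroupSpec("elispot", ("dsr_t1", "bdep_dsr_t1")),
)

#: Combined-model scenario for the for-cause-biopsy subgroup: HLA antibody
#: (incl. DSA MFI), C4d in peritubular capillaries, interstitial
#: fibrosis/tubular atrophy, proteinuria, and B-dependent DSR.
BFC_COMBINED_MODEL = PredictorGroupSpec(
    "bfc_combined",
    ("hla_ab_dsa", "log_dsa_t1", "c4d_ptc", "ifta_pct", "pcr_gt_50", "bdep_dsr_t1"),
)


def patient_features(cohort, calls) -> pd.DataFrame:
    """One row of model-ready covariates per patient.

    ELISPOT columns come from the baseline (t1) donor call; patients
    without an interpretable t1 call carry missing values there.
    """
    from .records import AntigenClass, HlaAbStatus, Sex, TimePoint

    rows = []
    for p in cohort.patients:
        call = calls.get((p.patient_id, TimePoint.T1, AntigenClass.DONOR))
        ok = call is not None and call.interpretable
        rows.append(
            {
                "patient_id": p.patient_id,
                "age_at_tx": p.age_at_tx,
                "sex_male": float(p.sex is Sex.M),
                "prior_rejection": float(p.prior_rejection),
                "dialysis_months_pre_tx": p.dialysis_months_pre_tx,
                "hla_ab_dsa": float(p.hla_ab_status is HlaAbStatus.DSA),
                "log_dsa_t1": np.log1p(p.dsa_mfi_t1)
                if p.dsa_mfi_t1 is not None
                else np.nan,
                "banff_g": p.banff_g,
                "banff_ptc": p.banff_ptc,
                "banff_cg": p.banff_cg,
                "banff_cv": p.banff_cv,
                "c4d_ptc": float(p.c4d_ptc),
                "ifta_pct": p.ifta_pct,
                "pcr_gt_50": float(p.pcr > 50) if p.pcr is not None else np.nan,
                "dsr_t1": float(call.dsr) if ok else np.nan,
                "bdep_dsr_t1": float(call.dsr and call.b_dependent) if ok else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


@dataclass
class LogisticFit:
    group: str
    params: pd.Series
    probabilities: pd.Series
    converged: bool
    separation_flagged: bool
    dropped: tuple[str, ...] = ()


def fit_logistic_group(
    features: pd.DataFrame,
    outcome: pd.Series,
    group: PredictorGroupSpec,
) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS) for one predictor group.

    Complete cases only; all-missing predictors are dropped with a warning;
    perfect separation is flagged and the offending coefficients capped at
    ±``SEPARATION_CAP`` so the fit remains usable for ranking.
    """
    y = outcome.astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")

    cols, dropped = [], []
    for m in group.members:
        if m not in features.columns or features[m].isna().all():
            dropped.append(m)
            warnings.warn(f"predictor {m} all-missing; dropped", stacklevel=2)
        else:
            cols.append(m)
    if not cols:
        raise ValueError(f"group {group.name}: no usable predictors")

    X = features[cols].astype(float)
    keep = X.notna().all(axis=1)
    X, yk = X[keep], y[keep]
    Xd = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(yk, Xd, family=sm.families.Binomial())
        res = model.fit(tol=1e-8, maxiter=200)
    params = res.params.copy()
    fitted = np.asarray(res.fittedvalues, dtype=float)
    flagged = bool(
        (params.abs() > SEPARATION_CAP).any()
        or np.all((fitted < 1e-4) | (fitted > 1 - 1e-4))
    )
    if flagged:
        warnings.warn(
            f"group {group.name}: perfect separation suspected; "
            "coefficients capped", stacklevel=2,
        )
        params = params.clip(-SEPARATION_CAP, SEPARATION_CAP)
    eta = Xd @ params
    probs = 1.0 / (1.0 + np.exp(-eta))
    probs = probs.clip(1e-12, 1 - 1e-12)
    return LogisticFit(
        group=group.name,
        params=params,
        probabilities=probs,
        converged=res.converged,
        separation_flagged=flagged,
        dropped=tuple(dropped),
    )


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the tie-adjusted concordance of (event, non-event) pairs.

    Rank formulation: AUC = (R₁ − n₁(n₁+1)/2) / (n₁ n₀), with midranks so
    tied score pairs count one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    best_operating_point: tuple[float, float]  # (sensitivity, specificity)
    ci95: tuple[float, float]


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """ROC curve, rank-formulation AUC, Youden-optimal point, bootstrap CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = auc_rank(scores, labels)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    youden = tpr - fpr
    best = int(np.argmax(youden))
    best_point = (float(tpr[best]), float(1.0 - fpr[best]))

    rng = np.random.default_rng(seed)
    boots = []
    n = len(labels)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if labels[idx].sum() in (0, n):
            continue
        boots.append(auc_rank(scores[idx], labels[idx]))
    lo, hi = (
        (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        if boots
        else (float("nan"), float("nan"))
    )
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
        best_operating_point=best_point, ci95=(lo, hi),
    )


@dataclass(frozen=True)
class ElasticNetSpec:
    """Grid and cross-validation settings for elastic-net model selection."""

    alpha_grid: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 11), 2))
    n_lambda: int = 50
    lambda_decades: float = 4.0
    holdout_fraction: float = 0.25
    n_repeats: int = 100
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if not self.alpha_grid or self.n_lambda < 1:
            raise ConfigError("alpha and lambda grids must be nonempty")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ConfigError("holdout_fraction must lie in (0, 1)")


@dataclass
class ElasticNetResult:
    selected: tuple[str, ...]
    alpha: float
    lam: float
    cv_auc: float
    coefficients: pd.Series
    refit_roc: RocResult
    cv_table: pd.DataFrame


def _lambda_grid(X: np.ndarray, y: np.ndarray, spec: ElasticNetSpec) -> np.ndarray:
    # glmnet-style: lambda_max is the smallest penalty zeroing all coefficients
    # under the lasso; alpha < 1 rescales it.
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / n
    lam_max = max(lam_max, 1e-4)
    alpha_floor = max(min(a for a in spec.alpha_grid if a > 0), 1e-3) \
        if any(a > 0 for a in spec.alpha_grid) else 1.0
    lam_max /= alpha_floor
    return np.geomspace(lam_max, lam_max * 10 ** (-spec.lambda_decades), spec.n_lambda)


def _stratified_holdouts(
    y: np.ndarray, spec: ElasticNetSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(spec.seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_pos = max(1, round(len(pos) * spec.holdout_fraction))
    n_neg = max(1, round(len(neg) * spec.holdout_fraction))
    splits = []
    for _ in range(spec.n_repeats):
        test = np.concatenate(
            [rng.choice(pos, n_pos, replace=False),
             rng.choice(neg, n_neg, replace=False)]
        )
        mask = np.zeros(len(y), dtype=bool)
        mask[test] = True
        splits.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
    return splits


def _fit_enet(X, y, alpha: float, lam: float) -> LogisticRegression:
    n = len(y)
    C = 1.0 / (lam * n)
    if alpha == 0.0:
        clf = LogisticRegression(penalty="l2", C=C, solver="lbfgs", max_iter=2000)
    elif alpha == 1.0:
        clf = LogisticRegression(
            penalty="l1", C=C, solver="liblinear", max_iter=2000, random_state=0
        )
    else:
        clf = LogisticRegression(
            penalty="elasticnet", l1_ratio=alpha, C=C, solver="saga",
            max_iter=5000, tol=1e-4, random_state=0,
        )
    clf.fit(X, y)
    return clf


def elastic_net_select(
    features: pd.DataFrame,
    outcome: Sequence[int],
    spec: ElasticNetSpec | None = None,
) -> ElasticNetResult:
    """Elastic-net model selection under repeated stratified holdout CV.

    For every (alpha, lambda) grid point the same seeded holdout splits are
    scored by holdout AUC.  Selection follows the one-standard-error rule:
    among grid points whose mean holdout AUC lies within one standard error
    of the best mean, the most parsimonious penalty wins (largest lambda,
    then largest alpha).  The winning penalty is refit on the full data and
    the predictors with nonzero coefficients are reported.  Deterministic
    for a given seed.
    """
    spec = spec or ElasticNetSpec()
    if features.shape[1] < 2:
        raise ValueError("need >=2 candidate predictors")
    y = np.asarray(outcome, dtype=int)
    X = features.to_numpy(dtype=float)
    if spec.standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    lambdas = _lambda_grid(X, y, spec)
    splits = _stratified_holdouts(y, spec)

    records = []
    for alpha in spec.alpha_grid:
        for lam in lambdas:
            aucs = []
            for train, test in splits:
                if y[train].sum() in (0, len(train)) or y[test].sum() in (0, len(test)):
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf = _fit_enet(X[train], y[train], alpha, lam)
                s = clf.decision_function(X[test])
                aucs.append(auc_rank(s, y[test]))
            records.append(
                {"alpha": alpha, "lambda": lam,
                 "mean_auc": float(np.mean(aucs)) if aucs else np.nan,
                 "se_auc": float(np.std(aucs, ddof=1) / np.sqrt(len(aucs)))
                 if len(aucs) > 1 else 0.0}
            )
    cv_table = pd.DataFrame(records)
    best_idx = cv_table["mean_auc"].idxmax()
    best_auc = float(cv_table.loc[best_idx, "mean_auc"])
    margin = float(cv_table.loc[best_idx, "se_auc"])
    winners = cv_table[cv_table["mean_auc"] >= best_auc - margin - 1e-12]
    winners = winners.sort_values(
        ["lambda", "alpha"], ascending=[False, False], kind="stable"
    )
    best = winners.iloc[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = _fit_enet(X, y, float(best["alpha"]), float(best["lambda"]))
    coefs = pd.Series(clf.coef_.ravel(), index=features.columns)
    selected = tuple(coefs.index[np.abs(coefs) > 1e-8])
    refit = roc_auc(clf.decision_function(X), y, seed=spec.seed)
    return ElasticNetResult(
        selected=selected,
        alpha=float(best["alpha"]),
        lam=float(best["lambda"]),
        cv_auc=float(best_auc),
        coefficients=coefs,
        refit_roc=refit,
        cv_table=cv_table,
    )


@dataclass
class LmmFit:
    """ML fit of eGFR ~ time × DSR-at-t2 with a random patient intercept."""

    intercept: float
    time_slope: float  # ml/min per 1.73 m^2 per year, reference group
    dsr_t2_effect: float
    interaction_slope: float  # additional yearly slope when DSR at t2
    random_intercept_var: float
    residual_var: float
    interaction_p: float
    converged: bool
    singular: bool
    loglik_full: float
    loglik_reduced: float


def fit_lmm_egfr(
    data: pd.DataFrame,
    time_col: str = "time_years",
    egfr_col: str = "egfr",
    group_col: str = "patient_id",
    dsr_col: str = "dsr_t2",
) -> LmmFit:
    """Linear mixed model for eGFR trajectories by follow-up DSR status.

    Fixed effects: intercept, time (years), DSR-at-t2 indicator and the
    time × DSR interaction; random intercept per patient; ML estimation so
    that the interaction p-value is a valid likelihood-ratio test of the
    nested fixed-effects structure.
    """
    df = data[[group_col, time_col, egfr_col, dsr_col]].dropna().copy()
    df[dsr_col] = df[dsr_col].astype(float)
    counts = df.groupby(group_col)[time_col].nunique()
    if (counts >= 2).mean() < 0.8:
        raise ValueError("need >=2 time points for >=80% of patients")

    df["interaction"] = df[time_col] * df[dsr_col]
    X_full = sm.add_constant(df[[time_col, dsr_col, "interaction"]])
    X_red = sm.add_constant(df[[time_col, dsr_col]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(df[egfr_col], X_full, groups=df[group_col]).fit(reml=False)
        red = sm.MixedLM(df[egfr_col], X_red, groups=df[group_col]).fit(reml=False)
    lr = 2.0 * (full.llf - red.llf)
    p = float(scipy.stats.chi2.sf(max(lr, 0.0), df=1))
    re_var = float(np.asarray(full.cov_re).ravel()[0])
    return LmmFit(
        intercept=float(full.params["const"]),
        time_slope=float(full.params[time_col]),
        dsr_t2_effect=float(full.params[dsr_col]),
        interaction_slope=float(full.params["interaction"]),
        random_intercept_var=re_var,
        residual_var=float(full.scale),
        interaction_p=p,
        converged=bool(full.converged),
        singular=re_var < 1e-8,
        loglik_full=float(full.llf),
        loglik_reduced=float(red.llf),
    )
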