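"""ASAP scoring, combined logistic classifiers and ROC evaluation.

The ASAP score is a published logistic risk score for hepatocellular
carcinoma combining Age, Sex, AFP and PIVKA-II:

    Z = -6.836 + 0.042*age + 0.989*sex + 1.841*log10(AFP) + 0.949*log10(PIVKA-II)

with sex coded 1 for male, 0 for female, AFP in ng/mL and PIVKA-II in
mAU/mL, both clipped to the assay detection limits first.  Combined
marker + score classifiers are binary logistic regressions (all-in
"enter" or backward elimination on Wald p-values); performance is
reported as AUC, sensitivity at a fixed specificity, and AIC.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import delong_test, rank_auc

log = logging.getLogger(__name__)

__all__ = [
    "AFP_LIMITS",
    "PIVKA_LIMITS",
    "ASAP_COEFFICIENTS",
    "clip_to_detection_limits",
    "asap_score",
    "FittedLogit",
    "fit_combined",
    "ClassifierResult",
    "evaluate",
    "compare_auc",
]

#: Assay detection limits: AFP 0.5-2000 ng/mL, PIVKA-II 5-75000 mAU/mL.
AFP_LIMITS = (0.5, 2000.0)
PIVKA_LIMITS = (5.0, 75000.0)

#: (intercept, age, sex, log10 AFP, log10 PIVKA-II)
ASAP_COEFFICIENTS = (-6.836, 0.042, 0.989, 1.841, 0.949)


def clip_to_detection_limits(afp, pivka):
    """Clamp biomarker values to the assay detection windows."""
    afp_c = np.clip(afp, *AFP_LIMITS)
    pivka_c = np.clip(pivka, *PIVKA_LIMITS)
    if np.isscalar(afp) or np.ndim(afp) == 0:
        return float(afp_c), float(pivka_c)
    return afp_c, pivka_c


def asap_score(age, sex, afp, pivka):
    """Evaluate the ASAP risk score Z (sex: 1 male, 0 female).

    The printed formula is evaluated exactly on the values given;
    callers normally pass detection-limit-clipped biomarkers (see
    :func:`clip_to_detection_limits`, applied by the cohort simulator).
    Non-positive raw inputs, for which the logarithm is undefined, are
    lifted to the assay floor.
    """
    afp = np.where(np.asarray(afp, dtype=float) > 0, afp, AFP_LIMITS[0])
    pivka = np.where(np.asarray(pivka, dtype=float) > 0, pivka, PIVKA_LIMITS[0])
    b0, b_age, b_sex, b_afp, b_pivka = ASAP_COEFFICIENTS
    z = (
        b0
        + b_age * np.asarray(age, dtype=float)
        + b_sex * np.asarray(sex, dtype=float)
        + b_afp * np.log10(afp)
        + b_pivka * np.log10(pivka)
    )
    if np.ndim(z) == 0:
        return float(z)
    return z


@dataclass
class FittedLogit:
    """A fitted binary logistic model over named feature columns."""

    features: list[str]
    params: pd.Series  # includes 'const'
    llf: float
    aic: float  # 2k - 2 lnL, k counts the intercept
    method: str
    separated: bool = False
    pvalues: pd.Series | None = None

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor (monotone in predicted probability)."""
        Xs = sm.add_constant(X[self.features], has_constant="add")
        return Xs.to_numpy(dtype=float) @ self.params.reindex(Xs.columns).to_numpy()


def _fit_logit_once(X: pd.DataFrame, y: np.ndarray) -> FittedLogit:
    Xs = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xs).fit(disp=0, maxiter=200)
        if not np.isfinite(res.params).all() or np.abs(res.params).max() > 1e3:
            raise sm.tools.sm_exceptions.PerfectSeparationError("diverged")
        return FittedLogit(
            features=list(X.columns),
            params=res.params,
            llf=float(res.llf),
            aic=float(2 * len(res.params) - 2 * res.llf),
            method="enter",
            pvalues=res.pvalues,
        )
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        # ridge-penalized fallback when classes are perfectly separable
        log.warning("perfect separation detected; fitting an L2-penalized model")
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(X.to_numpy(dtype=float), y)
        params = pd.Series(
            np.concatenate([[clf.intercept_[0]], clf.coef_[0]]),
            index=["const", *X.columns],
        )
        eta = sm.add_constant(X, has_constant="add").to_numpy() @ params.to_numpy()
        p = 1.0 / (1.0 + np.exp(-eta))
        eps = 1e-12
        llf = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        return FittedLogit(
            features=list(X.columns),
            params=params,
            llf=llf,
            aic=float(2 * len(params) - 2 * llf),
            method="enter",
            separated=True,
        )


def fit_combined(
    X: pd.DataFrame, labels, method: str = "enter", removal_p: float = 0.05
) -> FittedLogit:
    """Fit a combined binary logistic classifier.

    ``enter`` keeps every feature; ``backward`` iteratively removes the
    feature with the largest Wald p-value until all remaining p <=
    ``removal_p`` (possibly down to an intercept-only model).  Returns
    coefficients, log-likelihood and AIC = 2k - 2 lnL (k counts the
    intercept).
    """
    if X.isna().to_numpy().any():
        raise ValueError("missing feature values")
    y = np.asarray(labels, dtype=int)
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        log.warning("fewer than 10 samples in a class; estimates may be unstable")
    if method == "enter":
        return _fit_logit_once(X, y)
    if method != "backward":
        raise ValueError("method must be 'enter' or 'backward'")
    cols = list(X.columns)
    while cols:
        fit = _fit_logit_once(X[cols], y)
        if fit.pvalues is None:  # separated fallback has no Wald p-values
            fit.method = "backward"
            return fit
        pv = fit.pvalues.drop("const")
        if pv.max() <= removal_p:
            fit.method = "backward"
            return fit
        cols.remove(pv.idxmax())
    # every feature eliminated: intercept-only model
    fit = _fit_logit_once(X[[]], y)
    fit.method = "backward"
    return fit


@dataclass
class ClassifierResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    aic: float | None
    n_case: int
    n_control: int


def evaluate(
    scores,
    labels,
    fixed_specificity: float = 0.9,
    threshold: float | None = None,
    aic: float | None = None,
) -> ClassifierResult:
    """AUC plus sensitivity at a fixed-specificity operating point.

    AUC uses the rank (Mann-Whitney) formulation.  When ``threshold``
    is None the operating threshold is chosen on these labels: the
    smallest threshold whose specificity is >= ``fixed_specificity``
    (positive call = score strictly above the threshold).  Passing a
    ``threshold`` carries a training operating point over to a
    validation cohort unchanged, in which case the realized specificity
    may drift from the nominal one.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_case, n_control = int(y.sum()), int((1 - y).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("both classes must be present")
    auc = rank_auc(s, y)
    controls = s[y == 0]
    if threshold is None:
        candidates = np.unique(controls)
        chosen = None
        for t in candidates:  # ascending: smallest threshold first
            if np.mean(controls <= t) >= fixed_specificity:
                chosen = float(t)
                break
        threshold = chosen if chosen is not None else float(candidates[-1])
    sens = float(np.mean(s[y == 1] > threshold))
    spec = float(np.mean(controls <= threshold))
    return ClassifierResult(
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        threshold=float(threshold),
        aic=aic,
        n_case=n_case,
        n_control=n_control,
    )


def compare_auc(scores_a, scores_b, labels) -> dict[str, float]:
    """Paired DeLong test for the AUC difference of two models scored on
    the same samples.  Returns ``{'auc_a', 'auc_b', 'p'}``."""
    auc_a, auc_b, p = delong_test(scores_a, scores_b, labels)
    return {"auc_a": auc_a, "auc_b": auc_b, "p": p}
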