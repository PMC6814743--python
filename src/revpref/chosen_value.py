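"""Chosen-value analysis on a common-currency scale.

Both bundle rewards are expressed in ml of the numeraire reward A via the
currency weight k1, estimated psychophysically from anchor trials: if qA ml of
reward A alone is indifferent to qB ml of reward B alone, then k1 = qA/qB and
the value of a bundle is ``qA + k1*qB`` (optionally plus an interaction term
``k2*qA*qB`` reflecting indifference-curve nonlinearity).  The chosen value
(CV) is the value of the option taken, the unchosen value (UCV) that of the
option left behind; regressing a neuron's response on (CV, UCV) sorts it into
absolute-chosen / relative-chosen / unchosen / total value coding by the
significance pattern of the two coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .behavior import fit_psychometric
from .classify import RegressionResult, _ols, zscore
from .simulate import trial_bundles

__all__ = [
    "ValueCodingResult",
    "estimate_k1",
    "estimate_k1_from_block",
    "compute_values",
    "classify_value_coding",
    "absolute_vs_relative_probe",
    "regress_extended_value",
]


def estimate_k1(anchor_ip_qA: float, anchor_qB: float) -> float:
    """Currency weight from an anchor indifference: k1 = qA / qB.

    ``anchor_ip_qA`` is the reward-A-only quantity indifferent to the
    reward-B-only quantity ``anchor_qB``.  k1 < 1 means reward B is worth less
    per ml than the numeraire; k1 > 1 means it is worth more.
    """
    if anchor_qB <= 0 or anchor_ip_qA <= 0:
        raise ValueError("anchor quantities must be positive")
    return anchor_ip_qA / anchor_qB


def estimate_k1_from_block(anchor_block: pd.DataFrame, **fit_kwargs) -> float:
    """Estimate k1 from a simulated anchor block via the psychometric fit."""
    qB = anchor_block.attrs.get("anchor_qB", float(anchor_block["qB0"].iloc[0]))
    fit = fit_psychometric(anchor_block, **fit_kwargs)
    return estimate_k1(fit.ip, qB)


def compute_values(
    trials: pd.DataFrame,
    k1: float,
    k2: float = 0.0,
    form: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """Chosen and unchosen common-currency values per trial (ml of reward A).

    ``form='linear'`` uses ``qA + k1*qB``; ``form='interaction'`` adds
    ``k2*qA*qB``.  In three-option trials the unchosen value is that of the
    best unchosen option.
    """
    if form not in ("linear", "interaction"):
        raise ValueError("form must be 'linear' or 'interaction'")
    kk2 = k2 if form == "interaction" else 0.0

    def value(b):
        return b.qA + k1 * b.qB + kk2 * b.qA * b.qB

    cv = np.empty(len(trials))
    ucv = np.empty(len(trials))
    for i, (_, row) in enumerate(trials.iterrows()):
        opts = trial_bundles(row)
        ch = int(row["chosen"])
        cv[i] = value(opts[ch])
        ucv[i] = max(value(o) for j, o in enumerate(opts) if j != ch)
    return cv, ucv


@dataclass
class ValueCodingResult:
    """Value-coding category of one neuron-epoch response."""

    category: str  # absolute_chosen | relative_chosen | unchosen | total | none
    sign: int
    fit: RegressionResult


def classify_value_coding(
    z: np.ndarray,
    cv: np.ndarray,
    ucv: np.ndarray,
    alpha: float = 0.05,
    max_collinearity: float = 0.95,
) -> ValueCodingResult:
    """Sort a response into value-coding categories from the (CV, UCV) fit.

    absolute_chosen: only the CV coefficient significant; unchosen: only UCV;
    relative_chosen: both significant with opposite signs (coding CV - UCV);
    total: both significant with the same sign (coding CV + UCV); none
    otherwise.  Refuses classification when CV and UCV are nearly collinear.
    """
    if np.std(cv) == 0:
        raise ValueError("chosen value must vary across trials")
    if np.std(cv) > 0 and np.std(ucv) > 0:
        r = abs(np.corrcoef(cv, ucv)[0, 1])
        if r > max_collinearity:
            raise ValueError(
                f"CV and UCV are collinear (|r| = {r:.3f}); classification refused")
    # a constant UCV column is dropped by the fit, reducing exactly to the
    # CV-only regression
    fit = _ols(np.asarray(z, dtype=float),
               pd.DataFrame({"cv": cv, "ucv": ucv}), "value")
    s_cv = fit.pvalues["cv"] < alpha
    s_ucv = "ucv" in fit.pvalues and fit.pvalues["ucv"] < alpha
    b_cv = fit.params["cv"]
    b_ucv = fit.params.get("ucv", 0.0)
    if s_cv and not s_ucv:
        cat, sign = "absolute_chosen", np.sign(b_cv)
    elif s_ucv and not s_cv:
        cat, sign = "unchosen", np.sign(b_ucv)
    elif s_cv and s_ucv and np.sign(b_cv) != np.sign(b_ucv):
        cat, sign = "relative_chosen", np.sign(b_cv)
    elif s_cv and s_ucv:
        cat, sign = "total", np.sign(b_cv)
    else:
        cat, sign = "none", 0
    return ValueCodingResult(category=cat, sign=int(sign), fit=fit)


def absolute_vs_relative_probe(
    z: np.ndarray,
    context: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Context dependence of responses to the same chosen bundle.

    ``context`` labels trials by the alternative the same chosen bundle was
    pitted against.  Absolute chosen-value coding predicts no context effect
    (rank-sum / Kruskal-Wallis not significant); a significant effect points
    to relative coding.
    """
    labels = np.unique(context)
    if len(labels) < 2:
        raise ValueError("need at least two alternative-contexts")
    groups = [np.asarray(z)[context == c] for c in labels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(labels) == 2:
            _, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        else:
            _, p = stats.kruskal(*groups)
    if not np.isfinite(p):
        p = 1.0
    return {"p": float(p), "absolute": bool(p >= alpha)}


def regress_extended_value(
    trials: pd.DataFrame,
    neuron: str,
    epoch: str,
    k1: float,
    k2: float = 0.0,
    form: str = "linear",
) -> dict:
    """Extended value regression with history, side, and trial-number terms.

    Regresses the z-scored response on trial number, current and previous
    chosen/unchosen values, reference position, previous variable-bundle
    choice, and left choice (first trial dropped for the history terms).
    Also refits without the left-choice term and reports the largest relative
    change this induces in the remaining coefficients (a side-coding
    sensitivity check).
    """
    t = trials[trials["n_options"] == 2].reset_index(drop=True)
    cv, ucv = compute_values(t, k1, k2, form)
    z = zscore(t, neuron, epoch)
    X = pd.DataFrame(
        {
            "trial_number": t["trial"],
            "cv": cv,
            "ucv": ucv,
            "prev_cv": pd.Series(cv).shift(1),
            "prev_ucv": pd.Series(ucv).shift(1),
            "ref_left": t["ref_left"].astype(float),
            "prev_chose_variable": t["chose_variable"].astype(float).shift(1),
            "chose_left": t["chose_left"].astype(float),
        }
    ).iloc[1:]
    z = z[1:]
    fit = _ols(z, X, "value_extended")
    fit_no_cl = _ols(z, X.drop(columns=["chose_left"]), "value_extended_no_side")
    # relative change is only meaningful for coefficients distinguishable
    # from zero; near-zero terms would inflate the percentage arbitrarily
    common = [c for c in fit.params.index
              if c in fit_no_cl.params.index and c != "const"
              and fit.pvalues[c] < 0.05]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs((fit_no_cl.params[common] - fit.params[common])
                     / fit.params[common])
    rel = rel.replace([np.inf, -np.inf], np.nan).dropna()
    return {
        "fit": fit,
        "fit_without_side": fit_no_cl,
        "max_pct_change": float(rel.max() * 100) if len(rel) else np.nan,
    }
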