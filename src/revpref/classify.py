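"""Neuronal response screening and tuning classification.

Each neuron-epoch response (per-trial firing rates z-scored to the pretrial
control epoch) is classified against the indifference-curve (IC) structure of
behavior by a three-test procedure:

1. a double linear regression of the response on both bundle rewards — the
   screening step, requiring both coefficients significant with the same sign;
2. a Spearman rank correlation confirming monotone change across ICs;
3. a two-factor ANOVA (across-IC x within-IC) requiring significance across
   curves but not along them, and no interaction.

Responses failing the preference pattern are tested for single-reward coding
with reduced regressions and nested F-tests, or labelled mixed/unmodulated.
Companion regressions add the reward interaction term (the hyperbolic
analogue), quadratic controls, and an extended model with trial-history and
spatial covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .bundles import EPOCH_DURATIONS
from .simulate import TASK_EPOCHS, target_bundle

__all__ = [
    "EpochResponse",
    "RegressionResult",
    "ClassificationResult",
    "assign_ic_ranks",
    "epoch_response",
    "zscore",
    "task_related_wilcoxon",
    "task_related_sliding_anova",
    "regress_both",
    "regress_single",
    "spearman_across_ics",
    "anova_two_factor",
    "classify",
    "classify_population",
    "regress_interaction",
    "model_comparison",
    "regress_extended",
]

RESPONSE_LABELS = (
    "rp_positive",
    "rp_inverse",
    "single_A_pos",
    "single_A_neg",
    "single_B_pos",
    "single_B_neg",
    "mixed",
    "unmodulated",
)


@dataclass
class EpochResponse:
    """Per-trial normalized response of one neuron in one task epoch."""

    neuron: str
    epoch: str
    z: np.ndarray
    qA: np.ndarray
    qB: np.ndarray
    ic_rank: np.ndarray
    within_rank: np.ndarray
    trial_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class RegressionResult:
    """A fitted linear model on a neuron-epoch response."""

    model: str
    params: pd.Series
    pvalues: pd.Series
    adj_r2: float
    n: int
    df_resid: float
    ss_resid: float
    dropped: list[str] = field(default_factory=list)


@dataclass
class ClassificationResult:
    """Label and test evidence for one neuron-epoch response."""

    neuron: str
    epoch: str
    label: str
    evidence: dict


# ---------------------------------------------------------------------------
# response construction
# ---------------------------------------------------------------------------

def zscore(trials: pd.DataFrame, neuron: str, epoch: str) -> np.ndarray:
    """Epoch firing rates z-scored to the neuron's pretrial statistics.

    ``z = (count/duration - pretrial mean rate) / pretrial rate SD`` with the
    pretrial mean and SD taken over all trials of the neuron.
    """
    pre = trials[f"{neuron}_pretrial"].to_numpy(dtype=float) / EPOCH_DURATIONS["pretrial"]
    mu, sd = pre.mean(), pre.std(ddof=0)
    if sd == 0:
        raise ValueError(f"{neuron}: zero pretrial variance, cannot z-score")
    rate = trials[f"{neuron}_{epoch}"].to_numpy(dtype=float) / EPOCH_DURATIONS[epoch]
    return (rate - mu) / sd


def assign_ic_ranks(qA, qB, value_fn, levels=None, atol: float = 1e-6):
    """Assign each bundle to an indifference-curve rank and a position on it.

    ``value_fn(qA, qB)`` maps bundle coordinates to a preference level (a
    ground-truth utility or a fitted hyperbolic form).  Bundles are grouped by
    nearest level in ``levels`` (default: the distinct values present, merged
    within ``atol``); ``ic_rank`` is 1-based ascending in level and
    ``within_rank`` orders bundles on each curve by ascending reward-B
    quantity.
    """
    qA = np.asarray(qA, dtype=float)
    qB = np.asarray(qB, dtype=float)
    vals = np.asarray(value_fn(qA, qB), dtype=float)
    if levels is None:
        levels = []
        for v in np.sort(vals):
            if not levels or v - levels[-1] > atol:
                levels.append(v)
        levels = np.asarray(levels)
    else:
        levels = np.sort(np.asarray(levels, dtype=float))
    ic_rank = 1 + np.argmin(np.abs(vals[:, None] - levels[None, :]), axis=1)
    within = np.zeros(len(qA), dtype=int)
    for r in np.unique(ic_rank):
        m = ic_rank == r
        uniq = np.unique(qB[m])
        within[m] = 1 + np.searchsorted(uniq, qB[m])
    return ic_rank, within


def epoch_response(
    trials: pd.DataFrame,
    neuron: str,
    epoch: str,
    value_fn,
    levels=None,
) -> EpochResponse:
    """Build an :class:`EpochResponse` from a trial table."""
    z = zscore(trials, neuron, epoch)
    tb = np.array([target_bundle(row).as_tuple() for _, row in trials.iterrows()])
    qA, qB = tb[:, 0], tb[:, 1]
    ic_rank, within = assign_ic_ranks(qA, qB, value_fn, levels=levels)
    return EpochResponse(
        neuron=neuron, epoch=epoch, z=z, qA=qA, qB=qB,
        ic_rank=ic_rank, within_rank=within,
        trial_index=trials["trial"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# task-relatedness
# ---------------------------------------------------------------------------

def task_related_wilcoxon(
    trials: pd.DataFrame, neuron: str, alpha: float = 0.01
) -> dict[str, bool]:
    """Paired Wilcoxon test of each task epoch against the pretrial control.

    Returns a flag per task epoch; the neuron counts as task-related if at
    least one epoch is flagged.  All-tied samples cannot reject and are not
    flagged.
    """
    if len(trials) < 6:
        raise ValueError("need at least 6 trials for the signed-rank test")
    pre = trials[f"{neuron}_pretrial"].to_numpy(dtype=float) / EPOCH_DURATIONS["pretrial"]
    flags = {}
    for epoch in TASK_EPOCHS:
        rate = trials[f"{neuron}_{epoch}"].to_numpy(dtype=float) / EPOCH_DURATIONS[epoch]
        diff = rate - pre
        if np.all(diff == 0):
            flags[epoch] = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.wilcoxon(rate, pre, zero_method="wilcox", method="auto")
        flags[epoch] = bool(p < alpha)
    return flags


def task_related_sliding_anova(
    binned: dict[str, np.ndarray],
    alpha: float = 0.01,
    window_bins: int = 3,
    consecutive: int = 4,
) -> bool:
    """Sliding-window one-factor ANOVA of binned counts against pretrial.

    Counts are grouped into non-overlapping 150-ms windows (3 bins of 50 ms);
    a response is flagged only if at least four consecutive windows (600 ms)
    differ from the pretrial rate at ``alpha``, which rejects brief transients.
    """
    epoch_bins = np.asarray(binned["epoch"], dtype=float)
    pre_bins = np.asarray(binned["pretrial"], dtype=float)
    pre_rate = pre_bins.mean(axis=1)  # per-trial pretrial bin mean
    n_windows = epoch_bins.shape[1] // window_bins
    sig = []
    for wdx in range(n_windows):
        w = epoch_bins[:, wdx * window_bins:(wdx + 1) * window_bins].mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.f_oneway(w, pre_rate)
        sig.append(bool(np.isfinite(p) and p < alpha))
    run = best = 0
    for s in sig:
        run = run + 1 if s else 0
        best = max(best, run)
    return best >= consecutive


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _ols(z: np.ndarray, X: pd.DataFrame, model: str) -> RegressionResult:
    dropped = [c for c in X.columns if X[c].nunique() < 2]
    X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError(f"{model}: no informative regressors remain")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()])) < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max().idxmax()
        raise ValueError(f"{model}: rank-deficient design (collinear with {worst!r})")
    res = sm.OLS(z, sm.add_constant(X)).fit()
    return RegressionResult(
        model=model, params=res.params, pvalues=res.pvalues,
        adj_r2=float(res.rsquared_adj), n=int(res.nobs),
        df_resid=float(res.df_resid), ss_resid=float(res.ssr), dropped=dropped,
    )


def nested_f_test(reduced: RegressionResult, full: RegressionResult):
    """Variance-ratio test of a reduced model nested in a full model."""
    df_num = reduced.df_resid - full.df_resid
    if df_num <= 0 or full.ss_resid <= 0:
        return np.nan, np.nan
    f = ((reduced.ss_resid - full.ss_resid) / df_num) / (full.ss_resid / full.df_resid)
    p = stats.f.sf(f, df_num, full.df_resid)
    return float(f), float(p)


def _design_ok(resp: EpochResponse) -> None:
    pts = np.unique(np.column_stack([resp.qA, resp.qB]), axis=0)
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct bundles")
    for name, v in (("reward A", resp.qA), ("reward B", resp.qB)):
        if np.unique(v).size < 2:
            raise ValueError(f"design is degenerate in {name} (single quantity)")


def regress_both(resp: EpochResponse) -> RegressionResult:
    """Double linear regression of z on both bundle rewards (screening model)."""
    _design_ok(resp)
    X = pd.DataFrame({"qA": resp.qA, "qB": resp.qB})
    return _ols(resp.z, X, "both_rewards")


def screening_pass(fit: RegressionResult, alpha: float = 0.05) -> bool:
    """True if both reward coefficients are significant with the same sign."""
    bA, bB = fit.params["qA"], fit.params["qB"]
    pA, pB = fit.pvalues["qA"], fit.pvalues["qB"]
    return bool(pA < alpha and pB < alpha and np.sign(bA) == np.sign(bB))


def regress_single(resp: EpochResponse, alpha: float = 0.05) -> dict:
    """Reduced single-reward regressions with nested F-tests and verdict.

    A single-reward verdict requires (1) significance in the reduced model of
    one reward only, (2) the double regression significant for that reward
    only, and (3) a significant F-test for adding that reward to the other
    reward's reduced model.
    """
    _design_ok(resp)
    full = regress_both(resp)
    fit_a = _ols(resp.z, pd.DataFrame({"qA": resp.qA}), "reward_a_only")
    fit_b = _ols(resp.z, pd.DataFrame({"qB": resp.qB}), "reward_b_only")
    f_add_B, p_add_B = nested_f_test(fit_a, full)  # does B add to A-only?
    f_add_A, p_add_A = nested_f_test(fit_b, full)  # does A add to B-only?
    sigA5 = fit_a.pvalues["qA"] < alpha
    sigB6 = fit_b.pvalues["qB"] < alpha
    sigA4 = full.pvalues["qA"] < alpha
    sigB4 = full.pvalues["qB"] < alpha
    verdict = None
    if sigA5 and not sigB6 and sigA4 and not sigB4 and p_add_A < alpha:
        verdict = "single_A_pos" if fit_a.params["qA"] > 0 else "single_A_neg"
    elif sigB6 and not sigA5 and sigB4 and not sigA4 and p_add_B < alpha:
        verdict = "single_B_pos" if fit_b.params["qB"] > 0 else "single_B_neg"
    return {
        "full": full, "reward_a_only": fit_a, "reward_b_only": fit_b,
        "p_add_A": p_add_A, "p_add_B": p_add_B, "verdict": verdict,
    }


def spearman_across_ics(resp: EpochResponse):
    """Spearman rank correlation of the response with IC rank."""
    if np.unique(resp.ic_rank).size < 2:
        raise ValueError("need at least two IC ranks")
    if np.all(resp.z == resp.z[0]):
        return np.nan, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(resp.z, resp.ic_rank)
    if not np.isfinite(rho):
        return np.nan, 1.0
    return float(rho), float(p)


def anova_two_factor(resp: EpochResponse):
    """Two-way ANOVA (Type II) with factors across-IC and within-IC position.

    Returns (p_across, p_within, p_interaction).  The preference pattern is
    significance across curves with insignificance along them and in the
    interaction.
    """
    df = pd.DataFrame(
        {"z": resp.z, "ic": resp.ic_rank, "within": resp.within_rank}
    )
    if df["ic"].nunique() < 2:
        raise ValueError("the across-IC factor needs at least two levels")
    if df["within"].nunique() < 2:
        # singleton curves (e.g. grid designs): no trade-off testable along
        # curves, so the within factor is vacuously consistent
        fit = smf.ols("z ~ C(ic)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        return float(tab.loc["C(ic)", "PR(>F)"]), 1.0, 1.0
    counts = df.groupby(["ic", "within"]).size()
    thin = counts[counts < 2]
    if len(thin) == len(counts):
        raise ValueError("no cell has 2 or more trials")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols("z ~ C(ic) + C(within) + C(ic):C(within)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
    p_across = float(tab.loc["C(ic)", "PR(>F)"])
    p_within = float(tab.loc["C(within)", "PR(>F)"])
    p_inter = float(tab.loc["C(ic):C(within)", "PR(>F)"])
    if not np.isfinite(p_inter):
        p_inter = 1.0  # interaction inestimable on this design: treat as absent
    return p_across, p_within, p_inter


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(resp: EpochResponse, alpha: float = 0.05) -> ClassificationResult:
    """Label one neuron-epoch response by the three-test procedure.

    Revealed-preference labels require all three tests: same-sign significant
    double regression, significant Spearman correlation across ICs, and the
    ANOVA pattern (across significant, within and interaction not).  Otherwise
    the single-reward rule is applied; responses significant both across and
    along curves are ``mixed``; the rest are ``unmodulated``.
    """
    both = regress_both(resp)
    rho, p_rho = spearman_across_ics(resp)
    p_across, p_within, p_inter = anova_two_factor(resp)
    evidence = {
        "regression": both,
        "spearman_rho": rho,
        "spearman_p": p_rho,
        "anova_p_across": p_across,
        "anova_p_within": p_within,
        "anova_p_interaction": p_inter,
    }
    screen = screening_pass(both, alpha)
    anova_ok = p_across < alpha and p_within >= alpha and p_inter >= alpha
    if screen and p_rho < alpha and anova_ok:
        label = "rp_positive" if both.params["qA"] > 0 else "rp_inverse"
        return ClassificationResult(resp.neuron, resp.epoch, label, evidence)
    single = regress_single(resp, alpha)
    evidence["single"] = single
    if single["verdict"] is not None:
        return ClassificationResult(resp.neuron, resp.epoch, single["verdict"], evidence)
    if p_across < alpha and p_within < alpha:
        return ClassificationResult(resp.neuron, resp.epoch, "mixed", evidence)
    return ClassificationResult(resp.neuron, resp.epoch, "unmodulated", evidence)


def classify_population(
    trials: pd.DataFrame,
    neurons: list[str],
    value_fn,
    epochs=TASK_EPOCHS,
    levels=None,
    alpha: float = 0.05,
    screen_alpha: float = 0.01,
) -> pd.DataFrame:
    """Classify every neuron-epoch response in a session.

    Non-task-related neurons (paired Wilcoxon screen at ``screen_alpha``) are
    labelled unmodulated in every epoch.  A neuron's overall label is
    revealed-preference if any epoch response earns it.
    """
    rows = []
    for n in neurons:
        related = task_related_wilcoxon(trials, n, alpha=screen_alpha)
        for ep in epochs:
            if not any(related.values()):
                rows.append(dict(neuron=n, epoch=ep, label="unmodulated",
                                 task_related=False))
                continue
            resp = epoch_response(trials, n, ep, value_fn, levels=levels)
            c = classify(resp, alpha=alpha)
            rows.append(dict(neuron=n, epoch=ep, label=c.label, task_related=True))
    df = pd.DataFrame(rows)

    def neuron_label(g):
        labs = set(g["label"])
        for cand in ("rp_positive", "rp_inverse"):
            if cand in labs:
                return cand
        for cand in ("single_A_pos", "single_A_neg", "single_B_pos",
                     "single_B_neg", "mixed"):
            if cand in labs:
                return cand
        return "unmodulated"

    overall = df.groupby("neuron", sort=False).apply(neuron_label, include_groups=False)
    df["neuron_label"] = df["neuron"].map(overall)
    return df


# ---------------------------------------------------------------------------
# companion models
# ---------------------------------------------------------------------------

def regress_interaction(resp: EpochResponse) -> RegressionResult:
    """Regression with the reward interaction term (hyperbolic analogue)."""
    _design_ok(resp)
    X = pd.DataFrame({"qA": resp.qA, "qB": resp.qB, "qA_qB": resp.qA * resp.qB})
    return _ols(resp.z, X, "interaction")


def regress_quadratic(resp: EpochResponse) -> RegressionResult:
    X = pd.DataFrame({"qA": resp.qA, "qB": resp.qB,
                      "qA2": resp.qA**2, "qB2": resp.qB**2})
    return _ols(resp.z, X, "quadratic")


def regress_quadratic_interaction(resp: EpochResponse) -> RegressionResult:
    X = pd.DataFrame({"qA": resp.qA, "qB": resp.qB, "qA2": resp.qA**2,
                      "qB2": resp.qB**2, "qA_qB": resp.qA * resp.qB})
    return _ols(resp.z, X, "quadratic_interaction")


def model_comparison(resp: EpochResponse, alpha: float = 0.05) -> pd.DataFrame:
    """Compare the double regression against its nonlinear extensions.

    Each extension is tested against the two-reward base model with a nested
    F-test; adjusted R-squared values are reported alongside.
    """
    base = regress_both(resp)
    rows = [dict(model="both_rewards", adj_r2=base.adj_r2, f=np.nan,
                 p=np.nan, improves=False)]
    for fit in (regress_interaction(resp), regress_quadratic(resp),
                regress_quadratic_interaction(resp)):
        f, p = nested_f_test(base, fit)
        rows.append(dict(model=fit.model, adj_r2=fit.adj_r2, f=f, p=p,
                         improves=bool(np.isfinite(p) and p < alpha)))
    return pd.DataFrame(rows).set_index("model")


def regress_extended(trials: pd.DataFrame, neuron: str, epoch: str) -> RegressionResult:
    """Extended response model with reward, choice, history and side terms.

    Regresses the z-scored response on trial number, the four bundle reward
    quantities, current variable-bundle choice, previous variable-bundle
    choice, and left choice; the first trial is dropped for the history term.
    Degenerate regressors are dropped and recorded on the result.
    """
    t = trials[trials["n_options"] == 2].reset_index(drop=True)
    z = zscore(t, neuron, epoch)[1:]
    X = pd.DataFrame(
        {
            "trial_number": t["trial"],
            "ref_qA": t["qA0"],
            "ref_qB": t["qB0"],
            "var_qA": t["qA1"],
            "var_qB": t["qB1"],
            "chose_variable": t["chose_variable"].astype(float),
            "prev_chose_variable": t["chose_variable"].astype(float).shift(1),
            "chose_left": t["chose_left"].astype(float),
        }
    ).iloc[1:]
    return _ols(z, X, "extended")
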