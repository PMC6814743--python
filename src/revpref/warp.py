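"""Choice-set reduction tests of the weak axiom of revealed preference.

A utility maximizer that reveals bundle x preferred within {x, y, z} (chosen
with probability above 1/3) must keep x revealed preferred within the subset
{x, y} (chosen with probability above 1/2).  The behavioral test compares
empirical choice frequencies across the two set sizes; the neuronal test asks
whether the response rank order over bundles is preserved when the set
shrinks, and whether the response to the preferred bundle itself is invariant
to set size (absolute-value coding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .classify import zscore

__all__ = ["WarpVerdict", "behavioral_warp", "neuronal_warp", "choice_frequencies"]


@dataclass
class WarpVerdict:
    verdict: str  # compliant | violation | indeterminate
    best3: int | None
    best2: int | None
    freq3: np.ndarray | None = None
    freq2: np.ndarray | None = None


def choice_frequencies(trials: pd.DataFrame, n_options: int) -> np.ndarray:
    """Empirical choice frequency per option index for one set size."""
    t = trials[trials["n_options"] == n_options]
    if len(t) == 0:
        raise ValueError(f"no trials with {n_options} options")
    counts = np.bincount(t["chosen"].to_numpy(int), minlength=n_options)
    return counts / counts.sum()


def behavioral_warp(trials: pd.DataFrame) -> WarpVerdict:
    """Set-reduction consistency of revealed preference.

    Uses a mixed block of three-option trials over {x, y, z} and two-option
    trials over {x, y} (option indices 0, 1, 2 = x, y, z).  Compliant iff the
    option revealed preferred in the triple (frequency strictly above 1/3) is
    among {x, y} and is revealed preferred in the pair (frequency strictly
    above 1/2); empirical ties at either threshold are indeterminate.
    """
    f3 = choice_frequencies(trials, 3)
    f2 = choice_frequencies(trials, 2)
    best3 = int(np.argmax(f3))
    best2 = int(np.argmax(f2))
    if np.isclose(f3[best3], 1 / 3) or np.isclose(f2[best2], 0.5):
        return WarpVerdict("indeterminate", best3, best2, f3, f2)
    if f3[best3] <= 1 / 3 or f2[best2] <= 0.5:
        return WarpVerdict("indeterminate", best3, best2, f3, f2)
    if best3 >= 2:  # triple-best option absent from the pair: axiom untestable
        return WarpVerdict("indeterminate", best3, best2, f3, f2)
    verdict = "compliant" if best3 == best2 else "violation"
    return WarpVerdict(verdict, best3, best2, f3, f2)


def neuronal_warp(
    trials: pd.DataFrame,
    neuron: str,
    epoch: str = "stimulus",
    alpha_bundle: float = 0.002,
    alpha_spearman: float = 1e-4,
    alpha_set: float = 0.05,
) -> dict:
    """Rank preservation of a neuron's bundle responses across set sizes.

    Responses (z-scored rates) are grouped by chosen bundle and set size.  A
    two-factor ANOVA (bundle {x, y} x set size) plus a Spearman correlation
    over the triple assesses whether x keeps eliciting the strongest response;
    the set-size factor being non-significant additionally indicates
    set-size-invariant (absolute) value coding.
    """
    z = zscore(trials, neuron, epoch)
    df = pd.DataFrame(
        {
            "z": z,
            "bundle": trials["chosen"].to_numpy(int),
            "set_size": trials["n_options"].to_numpy(int),
        }
    )
    triple = df[df["set_size"] == 3]
    if triple["bundle"].nunique() < 2:
        raise ValueError("triple trials sample fewer than two bundles")
    # monotone ordering over the triple: x (index 0) should rank highest
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p_rho = stats.spearmanr(-triple["bundle"], triple["z"])
    if not np.isfinite(rho):
        rho, p_rho = np.nan, 1.0
    sub = df[df["bundle"] < 2]
    if sub.groupby(["bundle", "set_size"]).ngroups < 4:
        raise ValueError("need x and y responses in both set sizes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols("z ~ C(bundle) + C(set_size)", data=sub).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
    p_bundle = float(tab.loc["C(bundle)", "PR(>F)"])
    p_set = float(tab.loc["C(set_size)", "PR(>F)"])
    means3 = triple.groupby("bundle")["z"].mean()
    means2 = df[df["set_size"] == 2].groupby("bundle")["z"].mean()
    x_strongest = bool(
        means3.idxmax() == 0 and (0 in means2.index and means2.idxmax() == 0)
    )
    rank_preserved = bool(
        p_bundle < alpha_bundle and p_rho < alpha_spearman and x_strongest
    )
    return {
        "rank_preserved": rank_preserved,
        "set_size_invariant": bool(rank_preserved and p_set >= alpha_set),
        "p_bundle": p_bundle,
        "p_set": p_set,
        "spearman_rho": float(rho),
        "spearman_p": float(p_rho),
        "x_strongest": x_strongest,
    }
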