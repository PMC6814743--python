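"""Neuronal indifference curves: construction, behavioral comparison, validation.

A pooled regression of z-scored responses on both rewards and their product,

    z = b0 + b1*qA + b2*qB + b3*qA*qB ,

defines a family of iso-response curves.  Merging the response and offset into
a level constant k gives ``k = b1*qA + b2*qB + b3*qA*qB``, whose exact
inversion ``qA(qB) = (k - b2*qB) / (b1 + b3*qB)`` traces the neuronal
indifference curve at level k.  Curves at distinct levels are compared with
behavioral ICs through scale-free parameters (the coefficient ratio b2/b1 for
slope, b3/(b1*b2) for curvature) and validated with held-out bundles: each
out-of-sample response is matched to the nearest iso-level curve and its
vertical (reward-A) distance compared to the +/-95% band derived from the
regression's residual error, expressed in ml along the y-axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .behavior import BehavioralIC
from .classify import zscore
from .simulate import TASK_EPOCHS, target_bundle

__all__ = [
    "NeuronalIC",
    "PooledNeuronalFit",
    "response_table",
    "build_neuronal_ic",
    "ic_parameters",
    "compare_slopes",
    "out_of_sample_distance",
    "population_map",
]


@dataclass
class NeuronalIC:
    """One iso-response curve ``k = b1*qA + b2*qB + b3*qA*qB``."""

    beta1: float
    beta2: float
    beta3: float
    k: float

    def qA(self, qB):
        """Reward-A quantity on the curve; NaN where the curve is singular."""
        qB = np.asarray(qB, dtype=float)
        denom = self.beta1 + self.beta3 * qB
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (self.k - self.beta2 * qB) / denom
        return np.where(np.abs(denom) < 1e-12, np.nan, out)

    def level(self, qA, qB):
        """The iso-response form evaluated at a bundle position."""
        return self.beta1 * np.asarray(qA) + self.beta2 * np.asarray(qB) \
            + self.beta3 * np.asarray(qA) * np.asarray(qB)


def build_neuronal_ic(beta1: float, beta2: float, beta3: float, k: float) -> NeuronalIC:
    """Construct the iso-response curve for given coefficients and level."""
    if beta1 == 0 and beta3 == 0:
        raise ValueError("curve undefined: no reward-A dependence")
    return NeuronalIC(beta1=beta1, beta2=beta2, beta3=beta3, k=k)


def response_table(
    trials: pd.DataFrame,
    neurons,
    epochs=("stimulus",),
) -> pd.DataFrame:
    """Per-response mean z per tested bundle.

    One row per (neuron, epoch, bundle): columns neuron, epoch, qA, qB, z
    (mean z-scored rate over the trials showing that bundle) and n_trials.
    """
    tb = np.array([target_bundle(r).as_tuple() for _, r in trials.iterrows()])
    rows = []
    for n in neurons:
        for ep in epochs:
            z = zscore(trials, n, ep)
            df = pd.DataFrame({"qA": tb[:, 0], "qB": tb[:, 1], "z": z})
            g = df.groupby(["qA", "qB"], as_index=False).agg(
                z=("z", "mean"), n_trials=("z", "size"))
            g.insert(0, "epoch", ep)
            g.insert(0, "neuron", n)
            rows.append(g)
    return pd.concat(rows, ignore_index=True)


@dataclass
class PooledNeuronalFit:
    """Pooled interaction regression over all preference responses."""

    beta0: float
    beta1: float  # qA
    beta2: float  # qB
    beta3: float  # qA*qB
    err0: float   # residual RMSE in z (= level) units
    n: int
    k_values: np.ndarray          # fitted level of each training response
    boot: np.ndarray | None = None  # (n_boot, 4) coefficient samples

    @property
    def slope_ratio(self) -> float:
        """Relative coding strength of reward B vs reward A (b2/b1)."""
        if self.beta1 == 0:
            return np.nan
        return self.beta2 / self.beta1

    @property
    def curvature(self) -> float:
        return self.beta3

    @property
    def curvature_scaled(self) -> float:
        """Scale-free curvature b3/b1 (1/ml), comparable to c/b of behavior.

        Both ratios are invariant to the arbitrary overall scale of their
        coefficient vectors (response gain on the neuronal side, curve-level
        normalization on the behavioral side) and coincide when the response
        is a fixed affine function of the behavioral utility.
        """
        if self.beta1 == 0:
            return np.nan
        return self.beta3 / self.beta1

    def predict_z(self, qA, qB):
        return self.beta0 + self.beta1 * np.asarray(qA) \
            + self.beta2 * np.asarray(qB) \
            + self.beta3 * np.asarray(qA) * np.asarray(qB)

    def curve(self, k: float) -> NeuronalIC:
        return NeuronalIC(self.beta1, self.beta2, self.beta3, k)

    def level_grid(self, n_levels: int = 10) -> np.ndarray:
        """Decile grid of fitted response levels (iso-curve levels)."""
        qs = np.linspace(0.05, 0.95, n_levels)
        return np.quantile(self.k_values, qs)

    def band_width(self, qB) -> np.ndarray:
        """Half-width of the +/-95% band in ml along the y-axis.

        The residual error lives in level (z) units; dividing by dk/dqA =
        b1 + b3*qB converts it to reward-A quantity.
        """
        denom = np.abs(self.beta1 + self.beta3 * np.asarray(qB, dtype=float))
        with np.errstate(divide="ignore"):
            return np.where(denom < 1e-12, np.inf, 1.96 * self.err0 / denom)


def _fit_pooled(tab: pd.DataFrame) -> tuple[np.ndarray, float]:
    X = sm.add_constant(pd.DataFrame({
        "qA": tab["qA"], "qB": tab["qB"], "qA_qB": tab["qA"] * tab["qB"]}))
    res = sm.OLS(tab["z"].to_numpy(), X).fit()
    rmse = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return res.params.to_numpy(), rmse


def ic_parameters(
    responses: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PooledNeuronalFit:
    """Pooled iso-response fit over a table of preference responses.

    ``responses`` is a :func:`response_table` output restricted to responses
    that passed the preference classification.  Confidence intervals for the
    derived slope and curvature come from a bootstrap over neurons, respecting
    that the response unit of replication is the neuron.
    """
    coef, rmse = _fit_pooled(responses)
    k_vals = responses["z"].to_numpy() - coef[0]
    rng = np.random.default_rng(seed)
    ids = responses["neuron"].unique()
    boot = None
    if n_boot > 0 and len(ids) > 1:
        boot = np.empty((n_boot, 4))
        for i in range(n_boot):
            pick = rng.choice(ids, size=len(ids), replace=True)
            tab = pd.concat([responses[responses["neuron"] == p] for p in pick])
            boot[i], _ = _fit_pooled(tab)
    return PooledNeuronalFit(
        beta0=float(coef[0]), beta1=float(coef[1]), beta2=float(coef[2]),
        beta3=float(coef[3]), err0=rmse, n=len(responses),
        k_values=k_vals, boot=boot,
    )


def _overlap(samples_a: np.ndarray, samples_b: np.ndarray) -> dict:
    """Mutual mean-in-CI overlap plus a two-sample t-test."""
    lo_b, hi_b = np.quantile(samples_b, [0.025, 0.975])
    lo_a, hi_a = np.quantile(samples_a, [0.025, 0.975])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(samples_a, samples_b, equal_var=False)
    return {
        "a_in_b": bool(lo_b <= np.mean(samples_a) <= hi_b),
        "b_in_a": bool(lo_a <= np.mean(samples_b) <= hi_a),
        "t_p": float(p),
    }


def compare_slopes(neuronal: PooledNeuronalFit, behavioral: BehavioralIC) -> dict:
    """Slope and curvature correspondence between neuronal and behavioral ICs.

    Slopes are compared as coefficient ratios (neuronal b2/b1 against
    behavioral a/b) and curvatures on the scale-free b3/b1 vs c/b
    convention; each parameter is compared separately in both directions
    (mean of one inside the 95% CI of the other) with a Welch t-test.
    """
    if neuronal.boot is None or behavioral.boot_coefs is None:
        raise ValueError("both fits must carry bootstrap samples")
    nb = neuronal.boot
    with np.errstate(divide="ignore", invalid="ignore"):
        n_slope = nb[:, 2] / nb[:, 1]
        n_curv = nb[:, 3] / nb[:, 1]
        bb = behavioral.boot_coefs
        b_slope = bb[:, 0] / bb[:, 1]
        b_curv = bb[:, 2] / bb[:, 1]
    keep = np.isfinite(n_slope) & np.isfinite(n_curv)
    keepb = np.isfinite(b_slope) & np.isfinite(b_curv)
    slope = _overlap(n_slope[keep], b_slope[keepb])
    curv = _overlap(n_curv[keep], b_curv[keepb])
    return {
        "slope_neuronal_in_behavioral": slope["a_in_b"],
        "slope_behavioral_in_neuronal": slope["b_in_a"],
        "slope_t_p": slope["t_p"],
        "curvature_neuronal_in_behavioral": curv["a_in_b"],
        "curvature_behavioral_in_neuronal": curv["b_in_a"],
        "curvature_t_p": curv["t_p"],
        "match": bool(slope["a_in_b"] and slope["b_in_a"]
                      and curv["a_in_b"] and curv["b_in_a"]),
    }


def out_of_sample_distance(
    new_responses: pd.DataFrame,
    fit: PooledNeuronalFit,
    levels: np.ndarray | None = None,
) -> dict:
    """Validate iso-response curves on held-out bundles.

    Each held-out response is assigned the iso-level curve whose level is
    nearest its own response strength (z minus the fitted offset), and the
    vertical distance in ml between the bundle position and that curve is
    compared with the +/-95% band.  Responses whose strength falls outside the
    training level range are matched to the nearest end curve and flagged as
    extrapolated.

    Returns per-response distances, the mean distance, and the fraction of
    responses inside the band.
    """
    if levels is None:
        levels = fit.level_grid()
    levels = np.sort(np.asarray(levels, dtype=float))
    qA = new_responses["qA"].to_numpy(dtype=float)
    qB = new_responses["qB"].to_numpy(dtype=float)
    k_resp = new_responses["z"].to_numpy(dtype=float) - fit.beta0
    matched = levels[np.argmin(np.abs(k_resp[:, None] - levels[None, :]), axis=1)]
    extrapolated = (k_resp < levels[0]) | (k_resp > levels[-1])
    qA_curve = np.array([fit.curve(k).qA(x) for k, x in zip(matched, qB)])
    dist = np.abs(qA - qA_curve)
    band = fit.band_width(qB)
    within = dist <= band
    return {
        "distance": dist,
        "matched_level": matched,
        "extrapolated": extrapolated,
        "within_band": within,
        "mean_distance": float(np.nanmean(dist)),
        "fraction_within": float(np.mean(within)),
    }


def population_map(
    responses: pd.DataFrame,
    n_levels: int = 10,
    qB_grid: np.ndarray | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> dict:
    """Population response surface and the derived iso-response curve family.

    Averages z across responses per bundle (the colored-map step), refits the
    pooled interaction model, and returns curves at decile levels with the
    residual-error band.  A single tested bundle yields a map without curves.
    """
    surface = responses.groupby(["qA", "qB"], as_index=False).agg(
        z=("z", "mean"), n_responses=("z", "size"))
    if len(surface) < 4:
        warnings.warn("too few distinct bundles for an iso-response family")
        return {"surface": surface, "fit": None, "curves": [], "qB_grid": None}
    fit = ic_parameters(responses, n_boot=n_boot, seed=seed)
    if qB_grid is None:
        qB_grid = np.linspace(responses["qB"].min(), responses["qB"].max(), 50)
    curves = [fit.curve(k) for k in fit.level_grid(n_levels)]
    return {"surface": surface, "fit": fit, "curves": curves,
            "qB_grid": qB_grid, "band": fit.band_width(qB_grid)}
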