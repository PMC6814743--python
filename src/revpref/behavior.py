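"""Behavioral analysis: indifference points, indifference curves, choice controls.

The psychometric stage fits a cumulative Weibull to the probability of
choosing the variable bundle as a function of its varied reward quantity and
reads off the indifference point (IP) at P = 0.5.  A series of IPs is then fit
by weighted least squares with the hyperbolic indifference-curve (IC) form

    d = a*x + b*y + c*x*y        (x = reward B, y = reward A)

normalized to d = 1 per curve (the coefficients are only identified up to a
common scale).  The marginal rate of substitution is the negative derivative
-dy/dx along the fitted curve.  Logistic control regressions check that choice
follows reward quantities rather than spatial or history variables, and a
bootstrap band around an early psychometric fit flags satiety drift in later
blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

__all__ = [
    "PsychometricFit",
    "BehavioralIC",
    "ControlRegressionResult",
    "fit_psychometric",
    "trade_off",
    "fit_ic",
    "mrs",
    "choice_control_variable",
    "choice_control_spatial",
    "detect_satiety",
]


# ---------------------------------------------------------------------------
# psychometric Weibull
# ---------------------------------------------------------------------------

def _weibull_p(x, alpha, gamma, guess=0.0, lapse=0.0):
    x = np.asarray(x, dtype=float)
    core = 1.0 - np.exp(-np.power(np.clip(x, 0, None) / alpha, gamma))
    return guess + (1.0 - guess - lapse) * core


@dataclass
class PsychometricFit:
    """Weibull psychometric fit of one indifference-point block."""

    ip: float
    alpha: float
    gamma: float
    ci95: tuple[float, float]
    n_trials: int
    varied_reward: str
    flagged: bool = False
    guess: float = 0.0
    lapse: float = 0.0
    quantities: np.ndarray = field(default_factory=lambda: np.array([]))
    boot_params: np.ndarray | None = None  # (n_boot, 2): alpha, gamma
    boot_ips: np.ndarray | None = None

    def predict(self, x):
        """Fitted probability of choosing the variable bundle at quantity x."""
        return _weibull_p(x, self.alpha, self.gamma, self.guess, self.lapse)

    def band(self, x, level: float = 0.95):
        """Pointwise bootstrap confidence band of the fitted curve at x."""
        if self.boot_params is None or len(self.boot_params) == 0:
            raise ValueError("fit carries no bootstrap samples")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        curves = np.array(
            [_weibull_p(x, a, g, self.guess, self.lapse) for a, g in self.boot_params]
        )
        q = (1.0 - level) / 2.0
        return np.quantile(curves, q, axis=0), np.quantile(curves, 1 - q, axis=0)


def _ip_from_params(alpha, gamma, guess, lapse):
    w = (0.5 - guess) / (1.0 - guess - lapse)
    return alpha * np.power(-np.log1p(-w), 1.0 / gamma)


def _fit_weibull_mle(x, chose, guess, lapse, x0=None):
    """Binomial MLE of (alpha, gamma) by Nelder-Mead on log-parameters."""
    x = np.asarray(x, dtype=float)
    chose = np.asarray(chose, dtype=float)

    def nll(theta):
        alpha, gamma = np.exp(theta)
        p = np.clip(_weibull_p(x, alpha, gamma, guess, lapse), 1e-9, 1 - 1e-9)
        return -np.sum(chose * np.log(p) + (1 - chose) * np.log(1 - p))

    if x0 is None:
        # crude initialization: alpha near the mid-grid, moderate steepness
        x0 = np.log([max(np.median(x[x > 0]), 1e-3), 2.0])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500})
    return np.exp(res.x)


def fit_psychometric(
    block: pd.DataFrame,
    guess: float = 0.0,
    lapse: float = 0.0,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PsychometricFit:
    """Fit the choice probability of the variable bundle and estimate the IP.

    Maximum-likelihood fit of a two-parameter cumulative Weibull
    ``P(x) = 1 - exp(-(x/alpha)^gamma)`` (optionally shifted by guess/lapse
    rates) to per-trial choices; the IP solves the fitted ``P = 0.5``.  The
    95% CI comes from a parametric bootstrap: binomial resampling at the
    fitted probabilities followed by refitting.

    Degenerate blocks: if every grid quantity was chosen all-or-none (perfect
    separation) the IP is the midpoint between the last never-chosen and first
    always-chosen quantity, flagged; if all trials show the same choice no IP
    exists in range and a ValueError is raised.
    """
    rng = np.random.default_rng(seed)
    varied = block.attrs.get("varied_reward")
    if varied is None:  # infer: which variable-bundle component varies
        varied = "A" if block["qA1"].nunique() > 1 else "B"
    qcol = "qA1" if varied == "A" else "qB1"
    x = block[qcol].to_numpy(dtype=float)
    chose = block["chose_variable"].to_numpy(dtype=bool)

    grid = np.unique(x)
    if len(grid) < 2:
        raise ValueError("need at least two distinct quantities of the varied reward")
    freq = np.array([chose[x == q].mean() for q in grid])
    if chose.all() or (~chose).all():
        raise ValueError("all trials share the same choice: no indifference point in range")

    flagged = bool(block.attrs.get("extrapolates", False))
    if np.all((freq == 0.0) | (freq == 1.0)):
        # perfect separation: no graded zone to fit
        last0 = grid[freq == 0.0].max()
        first1 = grid[freq == 1.0].min()
        ip = 0.5 * (last0 + first1)
        return PsychometricFit(
            ip=float(ip), alpha=float(ip), gamma=50.0,
            ci95=(float(last0), float(first1)), n_trials=len(block),
            varied_reward=varied, flagged=True, guess=guess, lapse=lapse,
            quantities=grid,
        )

    alpha, gamma = _fit_weibull_mle(x, chose, guess, lapse)
    ip = _ip_from_params(alpha, gamma, guess, lapse)

    boot_params = np.empty((n_boot, 2))
    boot_ips = np.empty(n_boot)
    p_hat = np.clip(_weibull_p(x, alpha, gamma, guess, lapse), 1e-9, 1 - 1e-9)
    x0 = np.log([alpha, gamma])
    for i in range(n_boot):
        resamp = rng.random(len(x)) < p_hat
        if resamp.all() or (~resamp).all():
            boot_params[i] = (alpha, gamma)
        else:
            boot_params[i] = _fit_weibull_mle(x, resamp, guess, lapse, x0=x0)
        boot_ips[i] = _ip_from_params(*boot_params[i], guess, lapse)
    if n_boot > 0:
        lo, hi = np.quantile(boot_ips, [0.025, 0.975])
    else:
        lo, hi = np.nan, np.nan
    return PsychometricFit(
        ip=float(ip), alpha=float(alpha), gamma=float(gamma),
        ci95=(float(lo), float(hi)), n_trials=len(block),
        varied_reward=varied, flagged=flagged, guess=guess, lapse=lapse,
        quantities=grid, boot_params=boot_params, boot_ips=boot_ips,
    )


def trade_off(reference, ip_bundle) -> tuple[float, float]:
    """Reward-A quantity given up and reward-B quantity gained at indifference.

    ``given_up = reference.qA - ip.qA``; ``gained = ip.qB - reference.qB``.
    Identical bundles trade nothing: (0, 0).
    """
    return (reference.qA - ip_bundle.qA, ip_bundle.qB - reference.qB)


# ---------------------------------------------------------------------------
# hyperbolic indifference curves
# ---------------------------------------------------------------------------

@dataclass
class BehavioralIC:
    """Hyperbolic indifference curve ``1 = a*x + b*y + c*x*y`` (d normalized to 1).

    ``slope`` is the linear-part slope convention -a/b (dy/dx at the origin of
    the linear form); ``curvature`` is the interaction coefficient c.
    """

    a: float
    b: float
    c: float
    d: float = 1.0
    adj_r2: float = np.nan
    ci_band: float = np.nan  # +/- ml in the y-direction
    ips: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # (qB, qA)
    weights: np.ndarray = field(default_factory=lambda: np.array([]))
    boot_coefs: np.ndarray | None = None  # (n_boot, 3): a, b, c
    pinned_c: bool = False

    @property
    def slope(self) -> float:
        return -self.a / self.b

    @property
    def curvature(self) -> float:
        return self.c

    def qA(self, qB):
        """Reward-A quantity on the curve at x-position qB."""
        qB = np.asarray(qB, dtype=float)
        return (self.d - self.a * qB) / (self.b + self.c * qB)

    def value(self, qA, qB):
        """Level of the hyperbolic form at a bundle position."""
        return self.a * np.asarray(qB) + self.b * np.asarray(qA) \
            + self.c * np.asarray(qA) * np.asarray(qB)

    def coef_ci(self, level: float = 0.95):
        """Bootstrap CIs of (a, b, c)."""
        if self.boot_coefs is None:
            raise ValueError("fit carries no bootstrap samples")
        q = (1.0 - level) / 2.0
        return np.quantile(self.boot_coefs, [q, 1 - q], axis=0).T


def _wls_hyperbola(x, y, w, pin_c=False):
    """Weighted LS of 1 = a*x + b*y (+ c*x*y)."""
    cols = [x, y] if pin_c else [x, y, x * y]
    X = np.column_stack(cols)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], sw, rcond=None)
    if pin_c:
        coef = np.append(coef, 0.0)
    return coef


def fit_ic(
    ips,
    weights=None,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    quantity_range: tuple[float, float] = (0.0, 0.9),
) -> BehavioralIC:
    """Fit a hyperbolic indifference curve to indifference points.

    Parameters
    ----------
    ips : array-like, shape (n, 2)
        IP coordinates as (qB, qA) pairs; at least 3 required.
    weights : array-like, optional
        Fit weights; the convention is inverse variance of each IP's bootstrap
        CI.  Defaults to equal weights.

    The gauge freedom (coefficients defined up to scale) is removed by fixing
    the curve level d = 1.  If the unrestricted fit yields a curve that is not
    a valid decreasing indifference curve over ``quantity_range`` (singular or
    rising branch), the interaction term is pinned to zero and the linear
    curve refit.
    """
    ips = np.asarray(ips, dtype=float)
    if ips.ndim != 2 or ips.shape[1] != 2 or len(ips) < 3:
        raise ValueError("need at least 3 indifference points as (qB, qA) pairs")
    x, y = ips[:, 0], ips[:, 1]
    w = np.ones(len(ips)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0) or len(w) != len(ips):
        raise ValueError("weights must be positive, one per IP")
    rng = np.random.default_rng(seed)

    def fit_once(xi, yi, wi):
        a, b, c = _wls_hyperbola(xi, yi, wi)
        lo, hi = quantity_range
        denom = b + c * np.linspace(lo, hi, 19)
        if (not np.all(np.isfinite((a, b, c)))) or np.any(denom <= 0) or b <= 0:
            a, b, c = _wls_hyperbola(xi, yi, wi, pin_c=True)
            return a, b, c, True
        return a, b, c, False

    a, b, c, pinned = fit_once(x, y, w)
    y_hat = (1.0 - a * x) / (b + c * x)
    resid = y - y_hat
    ss_res = np.sum(w * resid**2)
    ybar = np.average(y, weights=w)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    p = 2 if pinned else 3
    n = len(ips)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else r2
    band = 1.96 * np.sqrt(np.average(resid**2, weights=w))

    boot = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(ips[idx], axis=0)) < 3:
            boot[i] = (a, b, c)
        else:
            boot[i] = fit_once(x[idx], y[idx], w[idx])[:3]
    return BehavioralIC(
        a=float(a), b=float(b), c=float(c), adj_r2=float(adj),
        ci_band=float(band), ips=ips, weights=w, boot_coefs=boot,
        pinned_c=pinned,
    )


def mrs(ic: BehavioralIC, at_qB: float) -> float:
    """Marginal rate of substitution -dy/dx of the fitted curve at x = at_qB.

    For ``y(x) = (d - a*x)/(b + c*x)`` this is
    ``[a*(b + c*x) + c*(d - a*x)] / (b + c*x)**2``.
    """
    denom = ic.b + ic.c * at_qB
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("curve is singular at this quantity")
    return (ic.a * denom + ic.c * (ic.d - ic.a * at_qB)) / denom**2


# ---------------------------------------------------------------------------
# logistic choice controls
# ---------------------------------------------------------------------------

@dataclass
class ControlRegressionResult:
    """Standardized logistic regression of choice on task variables."""

    outcome: str
    params: pd.Series
    pvalues: pd.Series
    dropped: list[str]
    converged: bool
    separation: bool
    n: int


def _fit_logistic(ydat: np.ndarray, X: pd.DataFrame, outcome: str) -> ControlRegressionResult:
    dropped = [c for c in X.columns if X[c].std() == 0 or X[c].nunique() < 2]
    X = X.drop(columns=dropped)
    # standardized coefficients: z-score every regressor
    Xz = (X - X.mean()) / X.std()
    Xz = sm.add_constant(Xz)
    separation = bool(ydat.all() or (~ydat.astype(bool)).all())
    if separation or Xz.shape[1] < 2:
        nan = pd.Series(np.nan, index=Xz.columns)
        return ControlRegressionResult(outcome, nan, nan, dropped, False, True, len(ydat))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(ydat.astype(float), Xz).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params, pvals = res.params, res.pvalues
        except Exception:
            converged = False
            params = pd.Series(np.nan, index=Xz.columns)
            pvals = pd.Series(np.nan, index=Xz.columns)
    # huge coefficients signal quasi-separation
    separation = separation or (converged and np.nanmax(np.abs(params.values)) > 15)
    return ControlRegressionResult(outcome, params, pvals, dropped,
                                   converged, separation, len(ydat))


def _history(col: pd.Series) -> pd.Series:
    return col.shift(1)


def choice_control_variable(trials: pd.DataFrame) -> ControlRegressionResult:
    """Logistic regression of variable-bundle choice on reward and nuisance terms.

    Regressors: consecutive trial number, the four reward quantities of the
    reference and variable bundles, current left choice, reference-on-left,
    and previous variable-bundle choice.  Degenerate (constant) regressors are
    dropped and reported; perfect separation is flagged instead of fit.
    """
    t = trials[trials["n_options"] == 2].reset_index(drop=True)
    X = pd.DataFrame(
        {
            "trial_number": t["trial"],
            "ref_qA": t["qA0"],
            "ref_qB": t["qB0"],
            "var_qA": t["qA1"],
            "var_qB": t["qB1"],
            "chose_left": t["chose_left"].astype(float),
            "ref_left": t["ref_left"].astype(float),
            "prev_chose_variable": _history(t["chose_variable"].astype(float)),
        }
    ).iloc[1:]
    y = t["chose_variable"].to_numpy()[1:]
    return _fit_logistic(y, X, outcome="chose_variable")


def choice_control_spatial(trials: pd.DataFrame) -> ControlRegressionResult:
    """Logistic regression of left choice on side-wise rewards and history."""
    t = trials[trials["n_options"] == 2].reset_index(drop=True)
    ref_left = t["ref_left"].astype(bool).to_numpy()
    left_qA = np.where(ref_left, t["qA0"], t["qA1"])
    left_qB = np.where(ref_left, t["qB0"], t["qB1"])
    right_qA = np.where(ref_left, t["qA1"], t["qA0"])
    right_qB = np.where(ref_left, t["qB1"], t["qB0"])
    X = pd.DataFrame(
        {
            "trial_number": t["trial"],
            "left_qA": left_qA,
            "left_qB": left_qB,
            "right_qA": right_qA,
            "right_qB": right_qB,
            "ref_left": t["ref_left"].astype(float),
            "prev_chose_left": _history(t["chose_left"].astype(float)),
        }
    ).iloc[1:]
    y = t["chose_left"].to_numpy()[1:]
    return _fit_logistic(y, X, outcome="chose_left")


# ---------------------------------------------------------------------------
# satiety drift
# ---------------------------------------------------------------------------

def detect_satiety(
    early_fit: PsychometricFit,
    late_block: pd.DataFrame,
    level: float = 0.95,
) -> bool:
    """Flag a preference drift between an early fit and a later matched block.

    The late block's fitted psychometric curve is evaluated at the design
    quantities; the flag is raised when it leaves the early fit's bootstrap
    confidence band at one or more quantities.
    """
    late = fit_psychometric(late_block, guess=early_fit.guess,
                            lapse=early_fit.lapse, n_boot=0)
    grid = np.unique(late_block.attrs.get("quantity_grid", late.quantities))
    if not np.allclose(np.sort(grid), np.sort(early_fit.quantities)):
        raise ValueError("late block design does not match the early fit")
    lo, hi = early_fit.band(grid, level=level)
    p_late = late.predict(grid)
    return bool(np.any((p_late < lo) | (p_late > hi)))
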