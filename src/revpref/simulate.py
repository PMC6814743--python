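"""Synthetic session generator: trial designs, stochastic choices, Poisson spiking.

Produces trial tables with the statistical structure the downstream analyses
assume, so every stage of the pipeline is testable without recorded data:

* psychophysical indifference-point blocks (2 stimulus positions x 5 quantities
  x 8 repetitions = 80 trials per point),
* choice blocks (12 option pairs x 2 positions = 24 trial types, each repeated),
* anchor blocks pitting an A-only against a B-only bundle (for the
  common-currency weight),
* three-option blocks with matched two-option subsets (for the choice-axiom
  test),
* per-epoch Poisson spike counts for neurons drawn from revealed-preference,
  single-reward, chosen-value, and unmodulated tuning classes.

Trial tables are plain :class:`pandas.DataFrame` objects with one row per
trial; spike counts live in columns named ``<neuron>_<epoch>``.  Generator
metadata (ground truth, seeds, roles) is kept in ``DataFrame.attrs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bundles import Bundle, EPOCH_DURATIONS, UtilityModel, choice_probability

__all__ = [
    "NeuronSpec",
    "make_ip_block",
    "make_choice_block",
    "make_anchor_block",
    "make_warp_block",
    "simulate_neuron",
    "simulate_population",
    "simulate_binned_counts",
    "design_bundles_on_ics",
    "trial_bundles",
    "target_bundle",
]

#: Neuron tuning classes emulated by the generator.
NEURON_LABELS = (
    "rp_positive",
    "rp_inverse",
    "single_A",
    "single_B",
    "unmodulated",
    "chosen_value_abs",
    "chosen_value_rel",
)

#: Task epochs that can carry a tuned response (pretrial is always baseline).
TASK_EPOCHS = ("stimulus", "go", "choice", "reward")


@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth tuning of one simulated neuron.

    Parameters
    ----------
    label : str
        One of :data:`NEURON_LABELS`.
    baseline_rate : float
        Pretrial firing rate, impulses/s (> 0).
    gain : float
        Rate change per utility unit (revealed-preference and chosen-value
        classes) or per ml (single-reward classes).  ``rp_inverse`` applies the
        gain with a negative sign.
    responsive_epochs : tuple of str
        Task epochs in which the tuned signal is added to baseline.
    transform : callable, optional
        Monotone transform applied to the signal before the gain (the default
        identity makes rates linear in utility/quantity).
    """

    label: str
    baseline_rate: float = 10.0
    gain: float = 10.0
    responsive_epochs: tuple[str, ...] = ("stimulus",)
    transform: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.label not in NEURON_LABELS:
            raise ValueError(f"unknown neuron label {self.label!r}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        bad = set(self.responsive_epochs) - set(TASK_EPOCHS)
        if bad:
            raise ValueError(f"unknown task epochs {sorted(bad)}")


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

_BASE_COLUMNS = [
    "trial",
    "block",
    "n_options",
    "qA0",
    "qB0",
    "qA1",
    "qB1",
    "qA2",
    "qB2",
    "ref_left",
    "chosen",
    "chose_variable",
    "chose_left",
]


def _finalize(rows: list[dict], model: UtilityModel, rng: np.random.Generator,
              block: str, attrs: dict) -> pd.DataFrame:
    """Shuffle rows, sample choices, and assemble the trial table."""
    order = rng.permutation(len(rows))
    out = []
    for t, i in enumerate(order):
        r = dict(rows[i])
        opts = [Bundle(r[f"qA{k}"], r[f"qB{k}"]) for k in range(r["n_options"])]
        p = choice_probability(model, opts)
        r["chosen"] = int(rng.choice(len(opts), p=p))
        r["trial"] = t
        r["block"] = block
        out.append(r)
    df = pd.DataFrame(out)
    for k in ("qA2", "qB2"):
        if k not in df:
            df[k] = np.nan
    df["chose_variable"] = df["chosen"] == 1
    if "order" in df.columns:
        # three-option sets: leftmost displayed option given by the permutation
        df["chose_left"] = [
            str(o)[0] == str(c) for o, c in zip(df["order"], df["chosen"])
        ]
    else:
        df["chose_left"] = (df["chosen"] == 0) == df["ref_left"]
    cols = [c for c in _BASE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df = df[cols]
    df.attrs.update(attrs)
    return df


def make_ip_block(
    model: UtilityModel,
    reference: Bundle,
    varied_reward: str,
    fixed_other: float,
    quantity_grid: Sequence[float],
    reps: int = 8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Psychophysical block estimating one indifference point.

    The animal chooses between the fixed ``reference`` bundle and a variable
    bundle whose ``varied_reward`` ('A' or 'B') sweeps ``quantity_grid`` while
    the other component stays at ``fixed_other``.  Each grid quantity appears
    at both left-right stimulus arrangements ``reps`` times (the default design
    is 2 x 5 x 8 = 80 trials), pseudorandomly interleaved.

    The table's ``attrs`` record the design and the generator's analytic
    indifference point; ``attrs['extrapolates']`` is set when the grid fails to
    bracket that point (the downstream psychometric fit will extrapolate).
    """
    if varied_reward not in ("A", "B"):
        raise ValueError("varied_reward must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    rows = []
    for ref_left in (True, False):
        for q in quantity_grid:
            if varied_reward == "A":
                var = Bundle(qA=q, qB=fixed_other)
            else:
                var = Bundle(qA=fixed_other, qB=q)
            for _ in range(reps):
                rows.append(
                    dict(
                        n_options=2,
                        qA0=reference.qA,
                        qB0=reference.qB,
                        qA1=var.qA,
                        qB1=var.qB,
                        ref_left=ref_left,
                    )
                )
    if varied_reward == "A":
        analytic = model.indifference_qA(reference, fixed_other)
    else:
        analytic = model.indifference_qB(reference, fixed_other)
    grid = np.sort(np.asarray(quantity_grid, dtype=float))
    attrs = dict(
        block_type="ip",
        varied_reward=varied_reward,
        fixed_other=fixed_other,
        quantity_grid=list(grid),
        reference=(reference.qA, reference.qB),
        analytic_ip=float(analytic),
        extrapolates=not (grid[0] <= analytic <= grid[-1]),
    )
    return _finalize(rows, model, rng, "ip", attrs)


def make_choice_block(
    model: UtilityModel,
    bundle_pairs: Sequence[tuple[Bundle, Bundle]],
    reps: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Choice block: each (reference, variable) pair at both stimulus positions.

    With 12 pairs this reproduces the canonical 24-trial-type design; each
    trial type is repeated ``reps`` times and the whole block is shuffled.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ref, var in bundle_pairs:
        for ref_left in (True, False):
            for _ in range(reps):
                rows.append(
                    dict(
                        n_options=2,
                        qA0=ref.qA,
                        qB0=ref.qB,
                        qA1=var.qA,
                        qB1=var.qB,
                        ref_left=ref_left,
                    )
                )
    attrs = dict(block_type="choice", n_pairs=len(bundle_pairs), reps=reps)
    return _finalize(rows, model, rng, "choice", attrs)


def make_anchor_block(
    model: UtilityModel,
    anchor_qB: float,
    qA_grid: Sequence[float],
    reps: int = 8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Anchor block for the common-currency weight.

    Choice between a B-only reference ``(0, anchor_qB)`` and an A-only variable
    bundle whose reward-A quantity sweeps ``qA_grid``.  The reward-A quantity
    at choice indifference expresses the value of ``anchor_qB`` ml of reward B
    in ml of the numeraire reward A.
    """
    df = make_ip_block(
        model,
        reference=Bundle(0.0, anchor_qB),
        varied_reward="A",
        fixed_other=0.0,
        quantity_grid=qA_grid,
        reps=reps,
        seed=seed,
    )
    df["block"] = "anchor"
    df.attrs["block_type"] = "anchor"
    df.attrs["anchor_qB"] = float(anchor_qB)
    return df


def make_warp_block(
    model: UtilityModel,
    anchor1: Bundle,
    anchor2: Bundle,
    third: Bundle,
    reps: int = 30,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Three-option trials plus the matched two-option subset for axiom tests.

    ``anchor1`` must lie on the y-axis (qB = 0) and ``anchor2`` on the x-axis
    (qA = 0); ``third`` is an interior bundle.  Options are ordered
    (x = third, y = anchor1, z = anchor2); the two-option subset presents
    {x, y}.  Returns ``reps`` trials of each set size, interleaved.
    """
    if anchor1.qB != 0:
        raise ValueError("anchor1 must have qB = 0 (y-axis anchor)")
    if anchor2.qA != 0:
        raise ValueError("anchor2 must have qA = 0 (x-axis anchor)")
    rng = np.random.default_rng(seed)
    x, y, z = third, anchor1, anchor2
    rows = []
    for _ in range(reps):
        perm = rng.permutation(3)
        rows.append(
            dict(
                n_options=3,
                qA0=x.qA, qB0=x.qB,
                qA1=y.qA, qB1=y.qB,
                qA2=z.qA, qB2=z.qB,
                ref_left=False,
                order="".join(str(int(k)) for k in perm),
            )
        )
        rows.append(
            dict(
                n_options=2,
                qA0=x.qA, qB0=x.qB,
                qA1=y.qA, qB1=y.qB,
                ref_left=bool(rng.integers(2)),
            )
        )
    attrs = dict(
        block_type="warp",
        roles=("third", "anchor1", "anchor2"),
        bundles=dict(x=x.as_tuple(), y=y.as_tuple(), z=z.as_tuple()),
    )
    return _finalize(rows, model, rng, "warp", attrs)


# ---------------------------------------------------------------------------
# bundle helpers
# ---------------------------------------------------------------------------

def trial_bundles(row: pd.Series) -> list[Bundle]:
    """Option bundles of one trial row."""
    n = int(row["n_options"])
    return [Bundle(row[f"qA{k}"], row[f"qB{k}"]) for k in range(n)]


def target_bundle(row: pd.Series) -> Bundle:
    """The bundle a stimulus-locked tuned response refers to.

    For two-option trials this is the variable (non-reference) option — in
    choice-over-zero-bundle trials, the only rewarded bundle.  For three-option
    trials it is the chosen bundle.
    """
    if int(row["n_options"]) == 2:
        return Bundle(row["qA1"], row["qB1"])
    return Bundle(row[f"qA{int(row['chosen'])}"], row[f"qB{int(row['chosen'])}"])


def design_bundles_on_ics(
    model: UtilityModel,
    levels: Sequence[float],
    qB_values: Sequence[float],
    qA_max: float = 0.9,
) -> dict[float, list[Bundle]]:
    """Bundles lying exactly on the model's indifference curves.

    For each utility ``level`` and each x-position in ``qB_values``, solve for
    the reward-A quantity on that curve; positions leaving the quantity range
    are dropped.
    """
    out: dict[float, list[Bundle]] = {}
    for lev in levels:
        pts = []
        for qB in qB_values:
            qA = float(model.ic_qA(lev, qB))
            if 0.0 <= qA <= qA_max:
                pts.append(Bundle(qA, qB))
        out[float(lev)] = pts
    return out


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

def _signals(spec: NeuronSpec, trials: pd.DataFrame, model: UtilityModel) -> np.ndarray:
    """Per-trial tuned signal (utility units or ml) before gain."""
    sig = np.zeros(len(trials))
    for i, (_, row) in enumerate(trials.iterrows()):
        if spec.label == "unmodulated":
            continue
        if spec.label in ("rp_positive", "rp_inverse"):
            sig[i] = model.utility(target_bundle(row))
        elif spec.label == "single_A":
            sig[i] = target_bundle(row).qA
        elif spec.label == "single_B":
            sig[i] = target_bundle(row).qB
        else:  # chosen-value classes
            opts = trial_bundles(row)
            ch = int(row["chosen"])
            cv = model.utility(opts[ch])
            if spec.label == "chosen_value_abs":
                sig[i] = cv
            else:
                ucv = max(model.utility(o) for k, o in enumerate(opts) if k != ch)
                sig[i] = cv - ucv
    if spec.transform is not None:
        sig = np.asarray(spec.transform(sig), dtype=float)
    return sig


def _rates(spec: NeuronSpec, signal: np.ndarray) -> dict[str, np.ndarray]:
    gain = -spec.gain if spec.label == "rp_inverse" else spec.gain
    rates = {}
    for epoch in EPOCH_DURATIONS:
        if epoch in spec.responsive_epochs and spec.label != "unmodulated":
            r = spec.baseline_rate + gain * signal
        else:
            r = np.full_like(signal, spec.baseline_rate)
        rates[epoch] = np.clip(r, 0.0, None)
    return rates


def simulate_neuron(
    spec: NeuronSpec,
    trials: pd.DataFrame,
    model: UtilityModel,
    seed: int | np.random.Generator = 0,
    name: str = "n0",
) -> pd.DataFrame:
    """Append per-epoch Poisson spike counts for one neuron to ``trials``.

    Counts in each epoch are ``Poisson(rate * duration)`` with the rate law of
    the neuron's tuning class; the pretrial epoch always fires at baseline.
    Adds columns ``<name>_<epoch>`` and returns the same DataFrame.
    """
    rng = np.random.default_rng(seed)
    rates = _rates(spec, _signals(spec, trials, model))
    cols = {f"{name}_{epoch}": rng.poisson(rates[epoch] * dur)
            for epoch, dur in EPOCH_DURATIONS.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", pd.errors.PerformanceWarning)
        for k, v in cols.items():
            trials[k] = v
    specs = trials.attrs.setdefault("neurons", {})
    specs[name] = spec.label
    return trials


def simulate_population(
    specs: Sequence[NeuronSpec],
    trials: pd.DataFrame,
    model: UtilityModel,
    seed: int = 0,
    prefix: str = "n",
) -> pd.DataFrame:
    """Simulate a roster of neurons with independent child seeds.

    Returns a new trial table with all count columns appended in one pass
    (the input table is not modified).
    """
    ss = np.random.SeedSequence(seed)
    cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for i, (spec, child) in enumerate(zip(specs, ss.spawn(len(specs)))):
        rng = np.random.default_rng(child)
        rates = _rates(spec, _signals(spec, trials, model))
        name = f"{prefix}{i}"
        for epoch, dur in EPOCH_DURATIONS.items():
            cols[f"{name}_{epoch}"] = rng.poisson(rates[epoch] * dur)
        labels[name] = spec.label
    out = pd.concat([trials, pd.DataFrame(cols, index=trials.index)], axis=1)
    out.attrs = dict(trials.attrs)
    out.attrs.setdefault("neurons", {}).update(labels)
    return out


def simulate_binned_counts(
    spec: NeuronSpec,
    trials: pd.DataFrame,
    model: UtilityModel,
    seed: int | np.random.Generator = 0,
    epoch: str = "stimulus",
    bin_width: float = 0.05,
    active_window: tuple[float, float] | None = None,
) -> dict[str, np.ndarray]:
    """Fine-grained counts for the sliding-window task-relatedness test.

    Returns 50-ms (by default) binned Poisson counts for ``epoch`` and for the
    pretrial control, shapes (n_trials, n_bins).  ``active_window`` restricts
    the tuned modulation to a sub-interval (seconds from epoch onset), letting
    tests plant transient responses; outside the window the rate is baseline.
    """
    rng = np.random.default_rng(seed)
    sig = _signals(spec, trials, model)
    rates = _rates(spec, sig)[epoch]
    n_bins = int(round(EPOCH_DURATIONS[epoch] / bin_width))
    n_pre = int(round(EPOCH_DURATIONS["pretrial"] / bin_width))
    t_edges = np.arange(n_bins) * bin_width
    epoch_rates = np.tile(rates[:, None], (1, n_bins))
    if active_window is not None:
        t0, t1 = active_window
        outside = (t_edges < t0) | (t_edges >= t1)
        epoch_rates[:, outside] = spec.baseline_rate
    epoch_bins = rng.poisson(epoch_rates * bin_width)
    pre_bins = rng.poisson(spec.baseline_rate * bin_width, size=(len(trials), n_pre))
    return {"epoch": epoch_bins, "pretrial": pre_bins}
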