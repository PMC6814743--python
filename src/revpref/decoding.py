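"""Pseudo-population decoding of bundle identity and choice.

Neurons recorded (or simulated) independently are aggregated into
pseudo-populations: for a pair of classes (two indifference curves, or two
chosen bundles), 10 trials per class are drawn at random from each neuron and
paired across neurons into a 20 x n_neurons response matrix.  A linear
support-vector machine (or LDA) is scored by 20-fold leave-one-out
cross-validation, and the whole selection procedure is repeated over seeded
iterations (150 by default); chance level is established by shuffling the
class assignment within each neuron and comparing accuracy distributions with
a rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from .classify import zscore

__all__ = [
    "PseudoPopulation",
    "DecodingResult",
    "trialwise_responses",
    "assemble",
    "loocv_accuracy",
    "decode",
    "shuffle_null",
    "decode_with_null",
    "within_vs_across",
    "lda_project",
]


@dataclass
class PseudoPopulation:
    """A trials x neurons response matrix with class labels."""

    X: np.ndarray
    y: np.ndarray
    neurons: list[str]
    excluded: list[str] = field(default_factory=list)


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy over repeated pseudo-population draws."""

    accuracy_mean: float          # %
    accuracies: np.ndarray        # per-iteration %
    shuffle_mean: float = np.nan
    shuffle_accuracies: np.ndarray | None = None
    p_vs_shuffle: float = np.nan


def trialwise_responses(
    trials: pd.DataFrame,
    neurons,
    classes: np.ndarray,
    epoch: str = "stimulus",
) -> dict:
    """Per-neuron, per-class trial-level z responses.

    ``classes`` labels each trial (e.g. the IC rank of its bundle, or the
    chosen bundle); returns ``{neuron: {class: z array}}``.
    """
    classes = np.asarray(classes)
    out = {}
    for n in neurons:
        z = zscore(trials, n, epoch)
        out[n] = {c: z[classes == c] for c in np.unique(classes)}
    return out


def assemble(
    responses: dict,
    class_pair,
    n_per_class: int = 10,
    seed: int | np.random.Generator = 0,
) -> PseudoPopulation:
    """Draw one pseudo-population for a pair of classes.

    For every neuron with at least ``n_per_class`` trials in both classes,
    draws that many trials per class without replacement (independently per
    neuron); under-sampled neurons are excluded and listed.
    """
    rng = np.random.default_rng(seed)
    cols, kept, excluded = [], [], []
    for n, per_class in responses.items():
        zs = []
        ok = True
        for c in class_pair:
            z = np.asarray(per_class.get(c, ()))
            if len(z) < n_per_class:
                ok = False
                break
            zs.append(rng.choice(z, size=n_per_class, replace=False))
        if ok:
            cols.append(np.concatenate(zs))
            kept.append(n)
        else:
            excluded.append(n)
    if not cols:
        raise ValueError("no neuron has enough trials in both classes")
    X = np.column_stack(cols)
    y = np.repeat(np.arange(len(class_pair)), n_per_class)
    return PseudoPopulation(X=X, y=y, neurons=kept, excluded=excluded)


def _make_decoder(kind: str):
    if kind == "svm":
        return SVC(kernel="linear", C=1.0)
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError("decoder must be 'svm' or 'lda'")


def loocv_accuracy(pop: PseudoPopulation, decoder: str = "svm") -> float:
    """Leave-one-out accuracy (fraction in [0, 1]) for one assembly.

    Constant (degenerate) features are dropped before fitting; if none remain
    the decoder must guess and the accuracy is chance.
    """
    X, y = pop.X, pop.y
    keep = X.std(axis=0) > 0
    if not keep.any():
        return 1.0 / len(np.unique(y))
    X = X[:, keep]
    correct = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            clf = _make_decoder(decoder)
            try:
                clf.fit(X[mask], y[mask])
                correct += int(clf.predict(X[i:i + 1])[0] == y[i])
            except Exception:
                correct += int(np.random.default_rng(i).integers(2) == y[i])
    return correct / len(y)


def decode(
    responses: dict,
    class_pair,
    iterations: int = 150,
    n_per_class: int = 10,
    seed: int = 0,
    decoder: str = "svm",
    shuffle: bool = False,
) -> DecodingResult:
    """Mean leave-one-out accuracy over repeated pseudo-population draws.

    With ``shuffle=True`` the class assignment of each neuron's selected
    trials is permuted independently per neuron before scoring, which breaks
    any class information and estimates the chance distribution.
    """
    ss = np.random.SeedSequence(seed)
    accs = np.empty(iterations)
    for i, child in enumerate(ss.spawn(iterations)):
        rng = np.random.default_rng(child)
        pop = assemble(responses, class_pair, n_per_class, rng)
        if shuffle:
            for j in range(pop.X.shape[1]):
                pop.X[:, j] = rng.permutation(pop.X[:, j])
        accs[i] = loocv_accuracy(pop, decoder) * 100.0
    return DecodingResult(accuracy_mean=float(accs.mean()), accuracies=accs)


def shuffle_null(
    responses: dict,
    class_pair,
    iterations: int = 150,
    n_per_class: int = 10,
    seed: int = 0,
    decoder: str = "svm",
) -> DecodingResult:
    """Chance-level decoding from within-neuron label shuffling."""
    return decode(responses, class_pair, iterations, n_per_class, seed,
                  decoder, shuffle=True)


def decode_with_null(
    responses: dict,
    class_pair,
    iterations: int = 150,
    n_per_class: int = 10,
    seed: int = 0,
    decoder: str = "svm",
) -> DecodingResult:
    """Decoding accuracy with its shuffle null and a rank-sum comparison."""
    real = decode(responses, class_pair, iterations, n_per_class, seed, decoder)
    null = shuffle_null(responses, class_pair, iterations, n_per_class,
                        seed + 1, decoder)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ranksums(real.accuracies, null.accuracies)
    return DecodingResult(
        accuracy_mean=real.accuracy_mean, accuracies=real.accuracies,
        shuffle_mean=null.accuracy_mean, shuffle_accuracies=null.accuracies,
        p_vs_shuffle=float(p),
    )


def within_vs_across(
    responses: dict,
    class_ic: dict,
    iterations: int = 50,
    n_per_class: int = 10,
    seed: int = 0,
    decoder: str = "svm",
) -> dict:
    """Pairwise decoding of bundles on the same vs different curves.

    ``responses`` is keyed by bundle-class labels and ``class_ic`` maps each
    class to its IC rank.  Every class pair is decoded; pairs sharing an IC
    rank populate the within-curve side, the rest the across-curve side.
    Preference-coding populations should decode across but not within curves.
    """
    within, across = [], []
    for i, pair in enumerate(combinations(sorted(class_ic), 2)):
        res = decode(responses, pair, iterations, n_per_class, seed + i, decoder)
        rec = {"pair": pair, "accuracy": res.accuracy_mean}
        (within if class_ic[pair[0]] == class_ic[pair[1]] else across).append(rec)
    return {
        "within": within,
        "across": across,
        "within_mean": float(np.mean([r["accuracy"] for r in within])) if within else np.nan,
        "across_mean": float(np.mean([r["accuracy"] for r in across])) if across else np.nan,
    }


def lda_project(
    responses: dict,
    classes,
    n_per_class: int = 10,
    n_selections: int = 5,
    seed: int = 0,
) -> dict:
    """Low-dimensional discriminant view of class separation.

    Draws ``n_selections`` pseudo-populations, fits LDA on each, and returns
    the (up to) first two discriminant coordinates for plotting, superimposed
    across selections, together with the mean leave-one-out accuracy.  When
    the within-class scatter is singular, a shrinkage-regularized solver is
    used and reported.
    """
    ss = np.random.SeedSequence(seed)
    coords, labels, accs = [], [], []
    shrunk = False
    for child in ss.spawn(n_selections):
        rng = np.random.default_rng(child)
        pop = assemble(responses, list(classes), n_per_class, rng)
        keep = pop.X.std(axis=0) > 0
        X = pop.X[:, keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                lda = LinearDiscriminantAnalysis()
                proj = lda.fit(X, pop.y).transform(X)
            except Exception:
                lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
                proj = lda.fit(X, pop.y).transform(X)
                shrunk = True
        if proj.shape[1] < 2:
            proj = np.column_stack([proj[:, 0], np.zeros(len(proj))])
        coords.append(proj[:, :2])
        labels.append(pop.y)
        accs.append(loocv_accuracy(pop, "lda") * 100.0)
    return {
        "coords": coords,
        "labels": labels,
        "accuracy_mean": float(np.mean(accs)),
        "shrinkage_used": shrunk,
    }
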