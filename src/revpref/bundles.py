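"""Core domain objects: two-component reward bundles and the hyperbolic utility model.

A choice option is a *bundle* of two liquid rewards: reward A (plotted on the
y-axis of the indifference map) and reward B (x-axis), both in milliliters.
Subjective value over the bundle plane is modeled with the hyperbolic form
whose level sets are the behavioral indifference curves::

    u(qA, qB) = a*qB + b*qA + c*qA*qB

with ``a`` the coefficient on reward B (x), ``b`` the coefficient on reward A
(y), and ``c`` the interaction (curvature) term.  Stochastic choice between
bundles follows a logistic/softmax rule in utility differences with a
temperature parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Bundle",
    "UtilityModel",
    "make_utility",
    "choice_probability",
    "EPOCHS",
    "EPOCH_DURATIONS",
    "QUANTITY_RANGE",
]

#: Task epochs and their fixed durations in seconds.  The pretrial epoch is the
#: control baseline; the reward epoch covers delivery of both liquids.
EPOCH_DURATIONS: dict[str, float] = {
    "pretrial": 1.0,
    "stimulus": 2.0,
    "go": 1.0,
    "choice": 1.0,
    "reward": 2.0,
}

#: Task epochs in temporal order (pretrial first).
EPOCHS: tuple[str, ...] = tuple(EPOCH_DURATIONS)

#: Default reward-quantity range in ml used throughout the simulated designs.
QUANTITY_RANGE: tuple[float, float] = (0.0, 0.9)


@dataclass(frozen=True)
class Bundle:
    """A two-component reward bundle (quantities in ml).

    Attributes
    ----------
    qA : float
        Quantity of reward A (y-axis of the indifference map).
    qB : float
        Quantity of reward B (x-axis).
    """

    qA: float
    qB: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.qA) and np.isfinite(self.qB)):
            raise ValueError("bundle quantities must be finite")
        if self.qA < 0 or self.qB < 0:
            raise ValueError("bundle quantities must be non-negative")

    def as_tuple(self) -> tuple[float, float]:
        return (self.qA, self.qB)


@dataclass(frozen=True)
class UtilityModel:
    """Hyperbolic utility over bundles with a softmax choice temperature.

    ``utility(Bundle(qA, qB)) = a*qB + b*qA + c*qA*qB``; the empty bundle has
    utility zero.  ``temperature`` scales the softness of stochastic choice:
    the probability of choosing option *i* from a set is
    ``softmax(u_i / temperature)``.
    """

    a: float
    b: float
    c: float = 0.0
    temperature: float = 0.05

    def utility(self, bundle: Bundle) -> float:
        return self.a * bundle.qB + self.b * bundle.qA + self.c * bundle.qA * bundle.qB

    def utility_xy(self, qA, qB):
        """Vectorized utility from raw quantities (arrays allowed)."""
        qA = np.asarray(qA, dtype=float)
        qB = np.asarray(qB, dtype=float)
        return self.a * qB + self.b * qA + self.c * qA * qB

    def ic_qA(self, level: float, qB):
        """Quantity of reward A on the indifference curve at ``level``.

        Solves ``level = a*qB + b*qA + c*qA*qB`` for qA.
        """
        qB = np.asarray(qB, dtype=float)
        return (level - self.a * qB) / (self.b + self.c * qB)

    def indifference_qA(self, reference: Bundle, qB: float) -> float:
        """qA making ``Bundle(qA, qB)`` exactly indifferent to ``reference``."""
        return float(self.ic_qA(self.utility(reference), qB))

    def indifference_qB(self, reference: Bundle, qA: float) -> float:
        """qB making ``Bundle(qA, qB)`` exactly indifferent to ``reference``."""
        u = self.utility(reference)
        return (u - self.b * qA) / (self.a + self.c * qA)


def make_utility(
    a: float,
    b: float,
    c: float = 0.0,
    temperature: float = 0.05,
    quantity_range: tuple[float, float] = QUANTITY_RANGE,
) -> UtilityModel:
    """Build a :class:`UtilityModel`, rejecting non-monotone parameterizations.

    The utility surface must be strictly increasing in each reward over
    ``quantity_range``; since the partial derivatives ``du/dqB = a + c*qA`` and
    ``du/dqA = b + c*qB`` are linear in the other component, checking the two
    range endpoints suffices.

    Raises
    ------
    ValueError
        If monotonicity fails anywhere on the range, or temperature <= 0.
    """
    lo, hi = quantity_range
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    for other in (lo, hi):
        if a + c * other <= 0:
            raise ValueError(
                f"utility not increasing in reward B at qA={other:g} "
                f"(du/dqB = {a + c * other:g})"
            )
        if b + c * other <= 0:
            raise ValueError(
                f"utility not increasing in reward A at qB={other:g} "
                f"(du/dqA = {b + c * other:g})"
            )
    return UtilityModel(a=a, b=b, c=c, temperature=temperature)


def choice_probability(model: UtilityModel, options: Sequence[Bundle]) -> np.ndarray:
    """Probability of choosing each option in a 2- or 3-option set.

    Softmax of utilities scaled by the model temperature; for two options this
    reduces to a logistic in the utility difference.  Probabilities sum to 1
    and equal-utility options are chosen with equal probability.
    """
    if len(options) not in (2, 3):
        raise ValueError("option sets contain two or three bundles")
    u = np.array([model.utility(o) for o in options]) / model.temperature
    u -= u.max()  # numerical stability
    p = np.exp(u)
    return p / p.sum()
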