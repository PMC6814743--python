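"""Shared fixtures: ground-truth models and simulated sessions.

Expensive simulated populations are session-scoped; tests must not mutate
them.
"""

import numpy as np
import pytest

import revpref as rp
from revpref.bundles import Bundle

#: curves used throughout: mild convexity, reward A ~1.25x the per-ml value of B
CURVED = dict(a=1.0, b=1.25, c=0.4, temperature=0.05)
LEVELS = (0.3, 0.5, 0.7, 0.9)


@pytest.fixture(scope="session")
def linear_model():
    return rp.make_utility(1.0, 2.0, 0.0, temperature=0.05)


@pytest.fixture(scope="session")
def curved_model():
    return rp.make_utility(**CURVED)


@pytest.fixture(scope="session")
def grid_block(curved_model):
    """Choice-over-zero-bundle block on a 4x4 orthogonal quantity grid,
    with one planted neuron per tuning class."""
    qs = [0.1, 0.3, 0.5, 0.7]
    bundles = [Bundle(a, b) for a in qs for b in qs]
    zero = Bundle(0.0, 0.0)
    blk = rp.make_choice_block(curved_model, [(zero, b) for b in bundles],
                               reps=8, seed=11)
    specs = [
        rp.NeuronSpec("rp_positive", 10, 25),
        rp.NeuronSpec("rp_inverse", 22, 18),
        rp.NeuronSpec("single_A", 10, 30),
        rp.NeuronSpec("single_B", 10, 30),
        rp.NeuronSpec("unmodulated", 10, 0),
        rp.NeuronSpec("chosen_value_abs", 10, 30),
    ]
    blk = rp.simulate_population(specs, blk, curved_model, seed=12)
    labels = {f"n{i}": s.label for i, s in enumerate(specs)}
    return blk, labels


@pytest.fixture(scope="session")
def ic_block(curved_model):
    """Choice-over-zero-bundle block with bundles on four indifference
    curves (trade-off design), with planted neurons."""
    on = rp.design_bundles_on_ics(curved_model, LEVELS, (0.0, 0.15, 0.3, 0.45))
    bundles = [b for pts in on.values() for b in pts]
    zero = Bundle(0.0, 0.0)
    blk = rp.make_choice_block(curved_model, [(zero, b) for b in bundles],
                               reps=10, seed=21)
    specs = [
        rp.NeuronSpec("rp_positive", 10, 25),
        rp.NeuronSpec("rp_positive", 14, 20),
        rp.NeuronSpec("rp_inverse", 22, 15),
        rp.NeuronSpec("unmodulated", 10, 0),
        rp.NeuronSpec("single_A", 10, 30),
    ]
    blk = rp.simulate_population(specs, blk, curved_model, seed=22)
    labels = {f"n{i}": s.label for i, s in enumerate(specs)}
    return blk, labels
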