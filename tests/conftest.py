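import math

import numpy as np
import pytest
import scipy.special as sp

import crowdkit as ck
from crowdkit.landscape import HingeSpec, LandscapeParams


@pytest.fixture
def task4():
    return ck.TaskSpec(4)


@pytest.fixture
def task25():
    return ck.TaskSpec(25)


@pytest.fixture
def landscape_params():
    """A peripheral flanked-acuity landscape typical of 5 deg eccentricity:
    0.3 deg unflanked threshold at 75%, critical nominal spacing 4x."""
    return LandscapeParams(
        eccentricity=5.0,
        unflanked_threshold_size=0.3,
        beta_shared=6.0,
        guess=0.25,
        hinge=HingeSpec(hinge_location=math.log10(4.0), crowded_slope=-0.8),
        asymptote=0.99,
    )


def logistic_cells(
    mu=0.0, beta=3.0, guess=0.25, asymptote=1.0, xs=None, n=100, seed=None,
    task=None, ecc=5.0, size=0.5,
):
    """Cells from a known logistic over log10 spacing; exact counts when
    seed is None (noiseless rounding at large n), binomial otherwise."""
    if xs is None:
        xs = np.linspace(-0.8, 0.8, 7)
    task = task or ck.TaskSpec(round(1 / guess))
    rng = np.random.default_rng(seed) if seed is not None else None
    cells = []
    for x in xs:
        p = guess + (asymptote - guess) * sp.expit(beta * (x - mu))
        k = int(rng.binomial(n, p)) if rng is not None else int(round(p * n))
        cells.append(ck.StimulusCell(ecc, size, 10.0**x, task, k, n))
    return cells


@pytest.fixture
def make_logistic_cells():
    return logistic_cells
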