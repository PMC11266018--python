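"""Shared fixtures and independent brute-force oracles.

The oracles enumerate the empirical joint distribution with plain Counter
dictionaries and evaluate the defining sums directly; they share no code
with the estimators they check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from cvte.signals import ComplexSeries
from cvte.simulate import generate_pair


def brute_transfer_entropy(source, target, tau):
    """Plug-in TE (nats) by direct enumeration of
    sum p(x_t, x_p, y_p) log[ p(x_t|x_p, y_p) / p(x_t|x_p) ]."""
    source = list(source)
    target = list(target)
    trips = Counter()
    for t in range(tau, len(target)):
        trips[(target[t], target[t - tau], source[t - tau])] += 1
    n = sum(trips.values())
    pair_xp_yp = Counter()
    pair_x_xp = Counter()
    marg_xp = Counter()
    for (x, xp, yp), c in trips.items():
        pair_xp_yp[(xp, yp)] += c
        pair_x_xp[(x, xp)] += c
        marg_xp[xp] += c
    te = 0.0
    for (x, xp, yp), c in trips.items():
        p = c / n
        p_cond_full = c / pair_xp_yp[(xp, yp)]
        p_cond_red = pair_x_xp[(x, xp)] / marg_xp[xp]
        te += p * math.log(p_cond_full / p_cond_red)
    return te


def brute_partial_transfer_entropy(source, target, conditioner, tau):
    """Plug-in conditional MI I(x_t; y_p | x_p, z_p) in nats by direct
    enumeration: sum p log[ p(x|y,z') / p(x|z') ] with z' = (x_p, z_p)."""
    quads = Counter()
    for t in range(tau, len(target)):
        quads[(target[t], source[t - tau], target[t - tau],
               conditioner[t - tau])] += 1
    n = sum(quads.values())
    c_yz = Counter()
    c_xz = Counter()
    c_z = Counter()
    for (x, y, xp, zp), c in quads.items():
        c_yz[(y, xp, zp)] += c
        c_xz[(x, xp, zp)] += c
        c_z[(xp, zp)] += c
    val = 0.0
    for (x, y, xp, zp), c in quads.items():
        p = c / n
        p_cond_full = c / c_yz[(y, xp, zp)]
        p_cond_red = c_xz[(x, xp, zp)] / c_z[(xp, zp)]
        val += p * math.log(p_cond_full / p_cond_red)
    return val


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def l1_pair():
    return generate_pair("L1", T=146, seed=7)


@pytest.fixture
def white_pair(rng):
    """Two independent white complex-valued signals."""
    mk = lambda: ComplexSeries(rng.standard_normal(146),
                               rng.standard_normal(146))
    return mk(), mk()
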