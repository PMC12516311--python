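"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from thermoexpr.io_formats import LocusSequence
from thermoexpr.pwm_annotation import BindingSite, SiteMap
from thermoexpr.synthetic_data import build_model, make_fitter, make_scenario


# ---------------------------------------------------------------------------
# exhaustive partition-function oracle (independent of the DP implementation)

def brute_force_occupancy(intervals, tfs, weights, coop_tf=None,
                          coop_strength=1.0, coop_range=0.0):
    """Marginal occupancy by enumerating all 2^n binding configurations.

    ``intervals`` are half-open (start, end) pairs; overlapping sites cannot
    be simultaneously bound.  A configuration's weight is the product of its
    member weights times ``coop_strength`` for every consecutively bound
    (in end order) pair of ``coop_tf`` sites whose edge gap is within
    ``coop_range``.
    """
    n = len(intervals)
    Z = 0.0
    bound_mass = np.zeros(n)
    for config in itertools.product([0, 1], repeat=n):
        idx = [i for i in range(n) if config[i]]
        ok = True
        for a, i in enumerate(idx):
            for j in idx[a + 1:]:
                si, ei = intervals[i]
                sj, ej = intervals[j]
                if si < ej and sj < ei:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        w = 1.0
        for i in idx:
            w *= weights[i]
        order = sorted(idx, key=lambda i: intervals[i][1])
        for a in range(len(order) - 1):
            i, j = order[a], order[a + 1]
            if (coop_tf is not None and tfs[i] == coop_tf and tfs[j] == coop_tf
                    and intervals[j][0] - intervals[i][1] <= coop_range):
                w *= coop_strength
        Z += w
        for i in idx:
            bound_mass[i] += w
    return bound_mass / Z


def make_sitemap(site_specs, locus_length=400, offset=0):
    """A SiteMap from (tf, start, end, norm_score) tuples on a dummy locus."""
    locus = LocusSequence("A" * locus_length, origin_offset=offset)
    sites = tuple(
        BindingSite(tf, start, end, "+", score=1.0, norm_score=norm)
        for tf, start, end, norm in site_specs
    )
    return SiteMap(sites, locus)


# ---------------------------------------------------------------------------
# scenario fixtures (session-scoped; construction is deterministic)

@pytest.fixture(scope="session")
def minimal_scenario():
    return make_scenario("minimal", seed=11)


@pytest.fixture(scope="session")
def eve_scenario():
    return make_scenario("eve_like", seed=11)


@pytest.fixture(scope="session")
def two_logic_scenario():
    return make_scenario("two_logic", seed=11)


@pytest.fixture(scope="session")
def minimal_model(minimal_scenario):
    return build_model(minimal_scenario)


@pytest.fixture(scope="session")
def eve_model(eve_scenario):
    return build_model(eve_scenario)


@pytest.fixture(scope="session")
def minimal_fitter(minimal_scenario):
    return make_fitter(minimal_scenario)


@pytest.fixture(scope="session")
def eve_fitter(eve_scenario):
    return make_fitter(eve_scenario)
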