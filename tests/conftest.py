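"""Shared fixtures: small seeded synthetic bundles and brute-force oracles."""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pytest

from chromarm.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A 200-sample default-condition bundle shared across read-only tests."""
    return simulate_bundle(SimulationConfig(seed=7, n_samples=200))


@pytest.fixture(scope="session")
def tiny_genome_config():
    """Config with a minimal genome, for survival/clinical-only replicates."""
    def make(seed, n_samples=400, **kw):
        return SimulationConfig(
            seed=seed, n_samples=n_samples,
            arm_gene_counts={"3p": 12, "3q": 5}, fragile_site_size=12, **kw)
    return make


# ---------------------------------------------------------------------------
# Independent enumeration oracles (exact rational arithmetic)
# ---------------------------------------------------------------------------

def exact_table_probability(table) -> Fraction:
    """P(table | margins) = Π r_i! Π c_j! / (N! Π n_ij!) as a Fraction."""
    t = np.asarray(table, dtype=int)
    n = int(t.sum())
    num = Fraction(1)
    # equivalent product of multinomial coefficients, exact in Fractions
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    from math import factorial
    num = Fraction(
        int(np.prod([factorial(int(r)) for r in rows], dtype=object))
        * int(np.prod([factorial(int(c)) for c in cols], dtype=object)),
        factorial(n) * int(np.prod([factorial(int(v)) for v in t.ravel()],
                                   dtype=object)))
    return num


def enumerate_fixed_margin_tables(row_margins, col_margins):
    """Brute force: all non-negative integer tables with the given margins,
    by product over the free (r−1)×(c−1) cells."""
    r, c = len(row_margins), len(col_margins)
    free_ranges = [range(min(row_margins[i], col_margins[j]) + 1)
                   for i in range(r - 1) for j in range(c - 1)]
    for combo in product(*free_ranges):
        t = np.zeros((r, c), dtype=int)
        t[:r - 1, :c - 1] = np.asarray(combo).reshape(r - 1, c - 1)
        t[:r - 1, c - 1] = row_margins[:r - 1] - t[:r - 1, :c - 1].sum(axis=1)
        t[r - 1, :] = col_margins - t[:r - 1, :].sum(axis=0)
        if (t >= 0).all():
            yield t


def oracle_exact_p_bounds(table, rtol=1e-6):
    """Two-sided probability-mass exact p as (lower, upper) Fractions.

    The bounds bracket any implementation that resolves probability ties
    within relative tolerance ``rtol``: the lower bound includes only tables
    with probability strictly ≤ the observed, the upper also includes tables
    within ``rtol`` above it.
    """
    t = np.asarray(table, dtype=int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    t = t[rows > 0][:, cols > 0]
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return Fraction(1), Fraction(1)
    p_obs = exact_table_probability(t)
    slack = p_obs * Fraction(int(rtol * 10**9), 10**9)
    lo = Fraction(0)
    hi = Fraction(0)
    for cand in enumerate_fixed_margin_tables(rows, cols):
        q = exact_table_probability(cand)
        if q <= p_obs:
            lo += q
        if q <= p_obs + slack:
            hi += q
    return lo, hi


def random_contingency_table(rng, shape, total):
    """Throw ``total`` observations into an r×c table uniformly."""
    r, c = shape
    flat = rng.multinomial(total, np.full(r * c, 1.0 / (r * c)))
    return flat.reshape(r, c)
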