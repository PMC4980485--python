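"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from math import exp, lgamma, log1p

import numpy as np
import pytest

from clonaldrift.simdata import SimulationConfig, simulate_case


# ---------------------------------------------------------------------------
# independent oracles (deliberately written from first principles; they must
# not share code with the implementation they check)


def fisher_oracle(a: int, b: int, c: int, d: int, eps: float = 1e-7) -> float:
    """Two-sided Fisher p-value by explicit hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def lpmf(x: int) -> float:
        return (
            lgamma(r1 + 1) - lgamma(x + 1) - lgamma(r1 - x + 1)
            + lgamma(n - r1 + 1) - lgamma(c1 - x + 1) - lgamma(n - r1 - c1 + x + 1)
            - (lgamma(n + 1) - lgamma(c1 + 1) - lgamma(n - c1 + 1))
        )

    p_obs = lpmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = lpmf(x)
        if lp <= p_obs + log1p(eps):
            total += exp(lp)
    return min(1.0, total)


def llr_oracle(t_ref, t_var, n_ref, n_var, error_rate=0.001):
    """Somatic-vs-germline binomial LLR via scipy's logpmf (three models)."""
    from scipy.stats import binom

    t_depth, n_depth = t_ref + t_var, n_ref + n_var
    mle = max(t_var / t_depth if t_depth else 0.0, error_rate)
    ll_somatic = binom.logpmf(t_var, t_depth, mle) + binom.logpmf(
        n_var, n_depth, error_rate
    )
    ll_het = binom.logpmf(t_var, t_depth, 0.5) + binom.logpmf(n_var, n_depth, 0.5)
    ll_wt = binom.logpmf(t_var, t_depth, error_rate) + binom.logpmf(
        n_var, n_depth, error_rate
    )
    return ll_somatic - max(ll_het, ll_wt)


# ---------------------------------------------------------------------------
# shared simulated cases (session-scoped: several test modules reuse them)


@pytest.fixture(scope="session")
def stable_case():
    config = SimulationConfig(
        n_clones=3, scenario="stable", purity_by_sample=0.8,
        depth_mean=150, n_variants_per_clone=50, seed=7,
    )
    return simulate_case(config, min_vaf_separation=0.1)


@pytest.fixture(scope="session")
def collision_case():
    config = SimulationConfig(
        n_clones=4, scenario="collision", purity_by_sample=0.8,
        depth_mean=150, n_variants_per_clone=50, seed=11,
    )
    return simulate_case(config)


@pytest.fixture(scope="session")
def monoclonal_case():
    config = SimulationConfig(
        scenario="monoclonal", purity_by_sample=0.9,
        depth_mean=150, n_variants_per_clone=60, seed=5,
    )
    return simulate_case(config)
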