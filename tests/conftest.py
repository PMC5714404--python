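"""Shared oracles and helpers for the test suite.

The enumeration oracles compute hidden-path likelihoods by brute force
over all 2^n state sequences; they are deliberately naive so that any
agreement with the production recursions is meaningful.
"""

import itertools

import numpy as np

from bistable import DominanceSeries
from bistable.distributions import ig_pdf
from bistable.hbm import HBMiParams, ptilde_SS, ptilde_UU
from bistable.hmm import TwoStateHMMParams


def hmm_likelihood_enum(series: DominanceSeries, params: TwoStateHMMParams) -> float:
    """Brute-force sum over all 2^n hidden-state paths of the HMM."""
    d = series.durations
    n = d.size
    f = np.column_stack([ig_pdf(d, params.stable), ig_pdf(d, params.unstable)])
    pi = params.start_distribution()
    P = params.transition_matrix()
    total = 0.0
    for path in itertools.product((0, 1), repeat=n):
        term = pi[path[0]] * f[0, path[0]]
        for i in range(1, n):
            term *= P[path[i - 1], path[i]] * f[i, path[i]]
        total += term
    return total


def hbmi_likelihood_enum(series: DominanceSeries, params: HBMiParams) -> float:
    """Brute-force sum over all 2^n hidden-state paths of the HBMi, with
    duration-dependent transition probabilities evaluated at d_{i-1}."""
    d = series.durations
    n = d.size
    f = np.column_stack(
        [ig_pdf(d, params.stable_ig), ig_pdf(d, params.unstable_ig)]
    )
    pss = np.asarray(ptilde_SS(d, params))
    puu = np.asarray(ptilde_UU(d, params))
    pi = (params.pi_S, 1.0 - params.pi_S)
    total = 0.0
    for path in itertools.product((0, 1), repeat=n):
        term = pi[path[0]] * f[0, path[0]]
        for i in range(1, n):
            prev, cur = path[i - 1], path[i]
            if prev == 0:
                trans = pss[i - 1] if cur == 0 else 1.0 - pss[i - 1]
            else:
                trans = puu[i - 1] if cur == 1 else 1.0 - puu[i - 1]
            term *= trans * f[i, cur]
        total += term
    return total


def random_hmm_params(rng) -> TwoStateHMMParams:
    """A random, well-separated two-state parameter set."""
    return TwoStateHMMParams(
        mu_S=rng.uniform(60.0, 250.0),
        sigma_S=rng.uniform(10.0, 60.0),
        mu_U=rng.uniform(2.0, 10.0),
        sigma_U=rng.uniform(1.0, 6.0),
        p_SS=rng.uniform(0.3, 0.95),
        p_UU=rng.uniform(0.3, 0.95),
        pi_S=rng.uniform(0.1, 0.9),
    )


def random_hbmi_params(rng) -> HBMiParams:
    """A random full HBMi parameter set."""
    b_S = rng.uniform(2.0, 30.0)
    return HBMiParams(
        b_S=b_S,
        nu_S_star=rng.uniform(0.05, 0.5),
        b_U=rng.uniform(0.2, min(2.5, b_S)),
        nu_U_star=rng.uniform(0.3, 1.5),
        b_tilde_S=rng.uniform(0.0, 2.0 * b_S),
        b_tilde_U=rng.uniform(-3.0, 3.0),
        nu_B_star=rng.uniform(0.1, 1.0),
        pi_S=rng.uniform(0.1, 0.9),
    )
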