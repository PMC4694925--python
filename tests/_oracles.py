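"""Independent test oracles shared between the unit and acceptance suites."""

import numpy as np

from sornlab.channel import ChannelParams, posterior_given_counts


def unit_level_posterior(theta1, theta0, prior_a, a_bits, b_bits):
    """Naive Bayes posterior from per-unit Bernoulli factors (Eqs 20-21 route).

    Independent of the count-based closed form under test.
    """
    p_active_given_a = np.concatenate([np.full(10, theta1), np.full(10, 1 - theta0)])
    p_active_given_b = np.concatenate([np.full(10, 1 - theta0), np.full(10, theta1)])
    bits = np.concatenate([a_bits, b_bits]).astype(float)
    lik_a = np.prod(np.where(bits == 1, p_active_given_a, 1 - p_active_given_a))
    lik_b = np.prod(np.where(bits == 1, p_active_given_b, 1 - p_active_given_b))
    denom = prior_a * lik_a + (1 - prior_a) * lik_b
    return prior_a * lik_a / denom


def monte_carlo_posterior(ch: ChannelParams, f_a: float, n: int, rng):
    """Sampled expectation of the posterior over channel realizations.

    Returns (mean, standard error).
    """
    m = int(round(f_a * ch.n_units))
    n_a = rng.binomial(m, ch.theta1, n) + rng.binomial(ch.n_units - m, 1 - ch.theta0, n)
    n_b = rng.binomial(ch.n_units - m, ch.theta1, n) + rng.binomial(m, 1 - ch.theta0, n)
    samples = posterior_given_counts(ch, n_a, n_b)
    return samples.mean(), samples.std() / np.sqrt(n)
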