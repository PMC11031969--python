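"""Independent oracles for acceptance checks.

These compute expected values of generator outputs by numerical integration
over the latent-utility distribution and the discrete state grid — a route
entirely separate from the estimation code they are used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from ceatrial.config import GeneratorConfig
from ceatrial.valuesets import ValueSet


def _cell_probabilities(mu: float, sigma: float, utils: np.ndarray) -> np.ndarray:
    """P(latent N(mu, sigma) snaps to each sorted state utility).

    The generator truncates the latent to the value-set range and snaps to
    the nearest representable utility, so the outermost cells absorb the
    tails.
    """
    mids = (utils[1:] + utils[:-1]) / 2.0
    edges = np.concatenate(([-np.inf], mids, [np.inf]))
    cdf = norm.cdf((edges - mu) / sigma)
    return np.diff(cdf)


def latent_sigma(cfg: GeneratorConfig) -> float:
    """Marginal sd of the latent utility at one timepoint."""
    return float(
        np.sqrt(
            cfg.practice_sd_utility**2
            + cfg.utility_patient_sd**2
            + cfg.utility_noise_sd**2
        )
    )


def expected_snapped_utility(mu: float, sigma: float, value_set: ValueSet) -> float:
    _, utils = value_set.as_arrays()
    return float(np.sum(utils * _cell_probabilities(mu, sigma, utils)))


def expected_missing_prob(
    mu: float, sigma: float, coefs: tuple[float, float], value_set: ValueSet
) -> float:
    a, b = coefs
    _, utils = value_set.as_arrays()
    return float(np.sum(expit(a + b * utils) * _cell_probabilities(mu, sigma, utils)))


def true_delta_qaly(
    cfg: GeneratorConfig, value_set: ValueSet, discount_rate: float = 0.05
) -> float:
    """Marginal incremental QALY implied by the generator configuration.

    Per cohort: the 12-month utility shift after truncation and snapping,
    scaled by the trapezium/discount loading — survivors carry the shifted
    utility at both 12 and 24 months, decedents only at 12 months — and
    pooled across the adult and older cohorts with complete-case weights.
    """
    sigma = latent_sigma(cfg)
    num, den = 0.0, 0.0
    for cohort in ("adult", "older"):
        n = cfg.cohort_sizes.get(cohort, 0)
        if n == 0:
            continue
        mu = cfg.utility_means[cohort]
        shift = expected_snapped_utility(
            mu + cfg.true_effect_utility, sigma, value_set
        ) - expected_snapped_utility(mu, sigma, value_set)
        p_death = cfg.death_prob[cohort]
        loading = 0.5 + (2.0 - p_death) / (2.0 * (1.0 + discount_rate))
        weight = n * (1.0 - expected_missing_prob(mu, sigma, cfg.missing_prob_coefs, value_set))
        num += weight * shift * loading
        den += weight
    return num / den
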