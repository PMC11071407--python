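"""Count likelihoods for the expression model: Poisson, NB, ZIP, ZINB.

All four families share the mean parameterization mean = s * lambda with s a
size factor.  The negative binomial uses the (mean, dispersion) form with
variance m + m^2 / phi; zero-inflated families mix a point mass at zero (the
technical-dropout channel, weight theta) with the count process, so "true"
biological zeros can still arise from the Poisson/NB component.

Log-pmfs are written out explicitly (gammaln form) because the samplers also
need their gradients; scipy's frozen distributions serve as the independent
check in the test-suite, not as the implementation.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy.special import gammaln, logsumexp


class Family(str, Enum):
    poisson = "poisson"
    zip = "zip"
    nb = "nb"
    zinb = "zinb"

    @property
    def zero_inflated(self) -> bool:
        return self in (Family.zip, Family.zinb)

    @property
    def overdispersed(self) -> bool:
        return self in (Family.nb, Family.zinb)


def _poisson_logpmf_log(y, log_mu):
    # evaluated from log(mu) so extreme rates cannot underflow to log(0)
    return y * log_mu - np.exp(log_mu) - gammaln(y + 1)


def _nb_logpmf_log(y, log_mu, phi):
    # mean mu, variance mu + mu^2/phi  (phi = size/shape parameter)
    log_phi_mu = np.logaddexp(np.log(phi), log_mu)
    return (
        gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
        + phi * (np.log(phi) - log_phi_mu)
        + y * (log_mu - log_phi_mu)
    )


def count_log_likelihood(
    y,
    s,
    log_lambda,
    family: Family | str = Family.poisson,
    dispersion: float | np.ndarray = None,
    dropout: float | np.ndarray = None,
):
    """Exact log pmf of counts y under the chosen family, mean s*exp(log_lambda).

    ``dropout`` is the zero-inflation weight theta (probability of a
    technical zero); zero-inflated families evaluate
    log(theta * [y==0] + (1-theta) * pmf(y)).
    Broadcasts over all array arguments.
    """
    family = Family(family)
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    log_mu = np.log(s) + np.asarray(log_lambda, dtype=float)
    if family.overdispersed:
        phi = np.asarray(dispersion, dtype=float)
        if np.any(phi <= 0):
            raise ValueError("NB dispersion must be positive")
        base = _nb_logpmf_log(y, log_mu, phi)
    else:
        base = _poisson_logpmf_log(y, log_mu)
    if not family.zero_inflated:
        return base
    theta = np.asarray(dropout, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("dropout must lie in [0, 1]")
    theta = np.clip(theta, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore"):
        mixed = logsumexp(
            np.stack(np.broadcast_arrays(np.log(1 - theta) + base,
                                         np.where(y == 0, np.log(theta), -np.inf))),
            axis=0,
        )
    return mixed


def loglik_and_grads(y, s, log_lambda, family, dispersion=None, dropout=None):
    """Log pmf plus gradients wrt (log_lambda, log(dispersion), logit(dropout)).

    Used by the HMC sampler; gradients are with respect to the unconstrained
    parameterizations the sampler moves in.  Returns
    ``(logp, d/dlog_lambda, d/dlog_phi, d/dlogit_theta)`` with ``None`` for
    parameters the family does not carry.
    """
    family = Family(family)
    y = np.asarray(y, dtype=float)
    log_mu = np.log(np.asarray(s, dtype=float)) + np.asarray(log_lambda, dtype=float)
    mu = np.exp(log_mu)
    if family.overdispersed:
        phi = np.asarray(dispersion, dtype=float)
        base = _nb_logpmf_log(y, log_mu, phi)
        dbase_dll = (y - mu) * phi / (phi + mu)
        from scipy.special import digamma
        dbase_dlogphi = phi * (
            digamma(y + phi) - digamma(phi)
            + np.log(phi) - np.logaddexp(np.log(phi), log_mu) + 1.0
            - (y + phi) / (phi + mu)
        )
    else:
        base = _poisson_logpmf_log(y, log_mu)
        dbase_dll = y - mu
        dbase_dlogphi = None
    if not family.zero_inflated:
        return base, dbase_dll, dbase_dlogphi, None
    theta = np.clip(np.asarray(dropout, dtype=float), 1e-12, 1 - 1e-12)
    logp = count_log_likelihood(y, s, log_lambda, family, dispersion, theta)
    # responsibility of the count channel at y = 0
    w = np.where(y == 0, np.exp(np.log(1 - theta) + base - logp), 1.0)
    d_ll = w * dbase_dll
    d_logphi = w * dbase_dlogphi if dbase_dlogphi is not None else None
    # d logp / d theta, then chain through logit: dtheta/dlogit = theta(1-theta)
    dtheta = np.where(
        y == 0,
        (1.0 - np.exp(base)) * np.exp(-logp),
        -1.0 / (1 - theta),
    )
    d_logit = dtheta * theta * (1 - theta)
    return logp, d_ll, d_logphi, d_logit
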