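"""Binomial, zero-inflated binomial, and power-prior log-likelihoods.

The case counts entering the likelihood may be non-integer ("effective"
counts built from sampling weights), so the binomial pmf is generalized
through the log-Gamma function:

    log f(y; n, p) = lgamma(n+1) - lgamma(y+1) - lgamma(n-y+1)
                     + y log p + (n-y) log(1-p)

For integer y this is exactly the binomial log-pmf.  The zero-inflated
binomial (ZIB) adds a point mass omega at zero:

    f(y; n, p, omega) = omega * 1{y=0} + (1-omega) * Binom(y; n, p)

and the power prior tempers a historical cell's log-likelihood by
alpha0 in (0, 1], controlling how strongly historical data inform the
current parameter.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, xlog1py, xlogy


def binomial_loglik(y, n, p):
    """Log binomial "likelihood" allowing continuous case counts y.

    Vectorized over all arguments.  Requires 0 <= y <= n; p at the
    boundary with incompatible y yields -inf, not an exception.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= y <= n")
    coef = gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = coef + xlogy(y, p) + xlog1py(n - y, -p)
    return np.where(np.isnan(ll), -np.inf, ll)


def zib_loglik(y, n, p, omega):
    """Log pmf of the zero-inflated binomial, mixture marginalized.

    y = 0:  log(omega + (1-omega) (1-p)^n)
    y > 0:  log(1-omega) + binomial_loglik(y, n, p)

    omega = 0 reduces exactly to the binomial; omega = 1 puts all mass
    at zero.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any((omega < 0) | (omega > 1)):
        raise ValueError("omega must lie in [0, 1]")
    base = binomial_loglik(y, n, p)
    with np.errstate(divide="ignore"):
        log_om = np.log(omega)
        log_1m = np.log1p(-omega)
        zero_branch = np.logaddexp(log_om, log_1m + xlog1py(n, -p))
        pos_branch = log_1m + base
    return np.where(y == 0, zero_branch, pos_branch)


def power_prior_loglik(Y0, n0, p, alpha0, omega=0.0, use_zero_inflation=False):
    """Tempered historical-cell log-likelihood, alpha0 * log L(Y0 | p).

    alpha0 in (0, 1] scales how much the historical data inform p: the
    limit alpha0 -> 0 ignores them, alpha0 = 1 pools them fully with the
    current data.  With ``use_zero_inflation`` the historical likelihood
    is the ZIB with the same county-level omega.
    """
    if not 0.0 < alpha0 <= 1.0:
        raise ValueError(f"alpha0 must lie in (0, 1], got {alpha0}")
    if use_zero_inflation:
        ll = zib_loglik(Y0, n0, p, omega)
    else:
        ll = binomial_loglik(Y0, n0, p)
    return alpha0 * ll
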