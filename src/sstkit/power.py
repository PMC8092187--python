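"""A-priori power for the test of a product-moment correlation.

The exact route integrates the sampling density of the correlation
coefficient under a bivariate normal with true correlation ``rho`` over
the rejection region of the t-test of zero correlation.  The common
Fisher-z closed form is exposed for comparison; it is slightly
conservative for moderate effects and can differ from the exact answer
by one participant.
"""
from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats

from .config import ConfigurationError

_MIN_N = 4  # density/test need n - 2 >= 2


def correlation_sample_logpdf(r, rho: float, n: int):
    """Log density of the sample correlation for samples of size ``n``."""
    r = np.asarray(r, float)
    log_c = (np.log(n - 2) + special.gammaln(n - 1)
             + 0.5 * (n - 1) * np.log1p(-rho ** 2)
             - 0.5 * np.log(2 * np.pi) - special.gammaln(n - 0.5))
    out = (log_c + 0.5 * (n - 4) * np.log1p(-r ** 2)
           - (n - 1.5) * np.log1p(-rho * r)
           + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)))
    return out


def _critical_r(n: int, alpha: float, sided: str) -> float:
    df = n - 2
    q = 1 - alpha if sided == "one" else 1 - alpha / 2
    tcrit = stats.t.ppf(q, df)
    return float(tcrit / np.sqrt(df + tcrit ** 2))


def exact_correlation_power(rho: float, n: int, alpha: float = 0.05,
                            sided: str = "one") -> float:
    """Exact power of the level-``alpha`` test of zero correlation."""
    if sided not in ("one", "two"):
        raise ConfigurationError("sided must be 'one' or 'two'")
    if n < _MIN_N:
        raise ConfigurationError(f"n must be at least {_MIN_N}")
    rcrit = _critical_r(n, alpha, sided)
    pdf = lambda r: np.exp(correlation_sample_logpdf(r, rho, n))
    power, _ = integrate.quad(pdf, rcrit, 1.0, limit=200)
    if sided == "two":
        lower, _ = integrate.quad(pdf, -1.0, -rcrit, limit=200)
        power += lower
    return float(power)


def fisher_z_required_n(rho: float, alpha: float = 0.05, power: float = 0.80,
                        sided: str = "one") -> int:
    """Closed-form sample size from the Fisher-z approximation.

    n = ((z_{1-alpha} + z_{power}) / atanh(rho))^2 + 3, rounded up.
    """
    _validate(rho, alpha, power, sided)
    za = stats.norm.ppf(1 - alpha if sided == "one" else 1 - alpha / 2)
    zb = stats.norm.ppf(power)
    n = ((za + zb) / np.arctanh(rho)) ** 2 + 3
    return max(int(np.ceil(n - 1e-9)), _MIN_N)


def _validate(rho: float, alpha: float, power: float, sided: str) -> None:
    if not 0.0 < rho < 1.0:
        raise ConfigurationError("rho must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ConfigurationError("power must lie in (0, 1)")
    if sided not in ("one", "two"):
        raise ConfigurationError("sided must be 'one' or 'two'")


def required_n_correlation(rho: float, alpha: float = 0.05,
                           power: float = 0.80, sided: str = "one",
                           method: str = "exact", n_max: int = 1_000_000) -> int:
    """Smallest n whose test of zero correlation attains the target power."""
    _validate(rho, alpha, power, sided)
    if method == "fisher_z":
        return fisher_z_required_n(rho, alpha, power, sided)
    if method != "exact":
        raise ConfigurationError("method must be 'exact' or 'fisher_z'")
    # exponential bracket then bisection (power is increasing in n)
    lo, hi = _MIN_N, _MIN_N
    if exact_correlation_power(rho, lo, alpha, sided) >= power:
        return lo
    while exact_correlation_power(rho, hi, alpha, sided) < power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise ConfigurationError(
                f"target power {power} not attainable with n <= {n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if exact_correlation_power(rho, mid, alpha, sided) >= power:
            hi = mid
        else:
            lo = mid
    return hi
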