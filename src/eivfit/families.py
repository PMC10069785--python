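"""Exponential-family response distributions with canonical links.

Each family exposes the per-observation log-likelihood and its first two
derivatives with respect to the linear predictor eta.  With canonical links
the per-observation score and Jacobian in beta are then

    s_i = (dl/deta)_i * x_i,        J_i = (d2l/deta2)_i * x_i x_i',

which is all the Louis observed-information calculation needs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
import statsmodels.api as sm

__all__ = ["Family", "Gaussian", "BinomialLogit", "PoissonLog", "get_family"]


class Family:
    name: str = ""
    has_dispersion: bool = False

    def mean(self, eta):
        raise NotImplementedError

    def loglik_i(self, y, eta, dispersion=1.0):
        raise NotImplementedError

    def dl_deta(self, y, eta, dispersion=1.0):
        raise NotImplementedError

    def d2l_deta2(self, y, eta, dispersion=1.0):
        raise NotImplementedError

    def statsmodels_family(self):
        raise NotImplementedError

    def deviance_i(self, y, eta):
        """Unit deviance, used for GCV."""
        raise NotImplementedError


class Gaussian(Family):
    name = "gaussian"
    has_dispersion = True

    def mean(self, eta):
        return np.asarray(eta, dtype=float)

    def loglik_i(self, y, eta, dispersion=1.0):
        r = y - eta
        return -0.5 * (r * r / dispersion + np.log(2 * np.pi * dispersion))

    def dl_deta(self, y, eta, dispersion=1.0):
        return (y - eta) / dispersion

    def d2l_deta2(self, y, eta, dispersion=1.0):
        return -np.ones_like(np.asarray(eta, dtype=float)) / dispersion

    def statsmodels_family(self):
        return sm.families.Gaussian()

    def deviance_i(self, y, eta):
        return (y - eta) ** 2


class BinomialLogit(Family):
    name = "binomial"

    def mean(self, eta):
        return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))

    def loglik_i(self, y, eta, dispersion=1.0):
        # y*eta - log(1+exp(eta)), stable in both tails
        return y * eta - np.logaddexp(0.0, eta)

    def dl_deta(self, y, eta, dispersion=1.0):
        return y - self.mean(eta)

    def d2l_deta2(self, y, eta, dispersion=1.0):
        p = self.mean(eta)
        return -p * (1.0 - p)

    def statsmodels_family(self):
        return sm.families.Binomial()

    def deviance_i(self, y, eta):
        return -2.0 * self.loglik_i(y, eta)


class PoissonLog(Family):
    name = "poisson"

    def mean(self, eta):
        return np.exp(np.asarray(eta, dtype=float))

    def loglik_i(self, y, eta, dispersion=1.0):
        return y * eta - np.exp(eta) - gammaln(np.asarray(y, dtype=float) + 1.0)

    def dl_deta(self, y, eta, dispersion=1.0):
        return y - np.exp(eta)

    def d2l_deta2(self, y, eta, dispersion=1.0):
        return -np.exp(np.asarray(eta, dtype=float))

    def statsmodels_family(self):
        return sm.families.Poisson()

    def deviance_i(self, y, eta):
        mu = np.exp(eta)
        y = np.asarray(y, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * (term - (y - mu))


_FAMILIES = {
    "gaussian": Gaussian,
    "binomial": BinomialLogit,
    "poisson": PoissonLog,
}


def get_family(name) -> Family:
    if isinstance(name, Family):
        return name
    try:
        return _FAMILIES[name.lower()]()
    except KeyError:
        raise ValueError(
            f"unsupported family {name!r}; choose from {sorted(_FAMILIES)}"
        ) from None
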