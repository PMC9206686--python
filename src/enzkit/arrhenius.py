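"""Arrhenius analysis: activation energy from the temperature dependence of a rate.

ln k = ln A − Ea/(R·T).  Fitting ln k against 1/T by ordinary least squares
gives slope −Ea/R and intercept ln A.  The same engine serves both the
catalytic activation energy (rates = activities on the ascending limb of the
temperature–activity profile) and the inactivation activation energy
(rates = first-order inactivation constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R
from .exceptions import DegenerateDataError, InsufficientDataError


@dataclass(frozen=True)
class ArrheniusResults:
    """OLS fit of ln k on 1/T."""

    Ea: float  # kJ/mol
    A: float  # pre-exponential, same unit as the input rates
    slope: float  # K (equals −Ea/R)
    intercept: float  # ln A
    r_squared: float
    n_obs: int

    def predict_rate(self, temperature_k):
        T = np.asarray(temperature_k, dtype=float)
        return self.A * np.exp(-self.Ea * 1000.0 / (R * T))

    def summary(self) -> str:
        return (
            "Arrhenius fit (ln k vs 1/T)\n"
            f"Ea = {self.Ea:.4g} kJ/mol, A = {self.A:.4g}, "
            f"r² = {self.r_squared:.6f}, n = {self.n_obs}"
        )


class ArrheniusModel:
    """Arrhenius regression model.

    Parameters
    ----------
    temperatures_k : array-like
        Absolute temperatures (K), at least 3 distinct values
        (2 are accepted and solved exactly, with r² = 1).
    rates : array-like
        Positive rate constants or rate-proportional activities.
    """

    def __init__(self, temperatures_k, rates):
        T = np.asarray(temperatures_k, dtype=float)
        k = np.asarray(rates, dtype=float)
        if T.size != k.size:
            raise InsufficientDataError("temperatures and rates must have equal length")
        if T.size < 2:
            raise InsufficientDataError("insufficient data: need at least 2 temperatures")
        if np.unique(T).size < 2:
            raise DegenerateDataError("insufficient data: all temperatures identical")
        if np.any(k <= 0):
            raise DegenerateDataError("log undefined: all rates must be positive")
        if np.any(T <= 0):
            raise DegenerateDataError("temperatures must be positive (Kelvin)")
        self.T = T
        self.k = k

    def fit(self) -> ArrheniusResults:
        x = 1.0 / self.T
        y = np.log(self.k)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(resid @ resid) / ss_tot
        return ArrheniusResults(
            Ea=float(-slope * R / 1000.0),
            A=float(np.exp(intercept)),
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(min(max(r2, 0.0), 1.0)),
            n_obs=int(self.T.size),
        )


def arrhenius_activation_energy(temperatures_k, rates) -> ArrheniusResults:
    """Functional façade: Ea (kJ/mol), A, slope and r² from (T, k) data."""
    return ArrheniusModel(temperatures_k, rates).fit()
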