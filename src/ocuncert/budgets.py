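"""Measurement-uncertainty budgets: data plus model components.

The combined measurement uncertainty of a derived product y is the
root-sum-square of its data (radiometric) and model (algorithmic)
components:

    u_measurement(y) = sqrt( u_data^2(y) + u_model^2(y) )

For the two power-law POC algorithms, POC = a X^b with X either the
blue-to-green reflectance ratio (a = 203.2, b = -1.034) or the
particulate backscattering coefficient at 470 nm (a = 141253, b = 1.18),
the model variance from imperfect regression coefficients is

    u_model^2 = (X^b)^2 u^2(a) + (a X^b ln X)^2 u^2(b)
                + (a b X^(b-1))^2 u^2(X)

(coefficient covariance assumed zero; natural log, consistent with
d(X^b)/db).  Fractional contributions of named variance components are
reported as shares of the total variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "ModelCoefficientUncertainty",
    "UncertaintyBudget",
    "BAND_RATIO_POC_MODEL_U",
    "IOP_POC_MODEL_U",
    "IOP_POC_COEFFS",
    "poc_model_variance",
    "poc_iop_data_variance",
    "combine_measurement",
    "budget_fractions",
    "make_budget",
]


@dataclass(frozen=True)
class ModelCoefficientUncertainty:
    """Uncertainties of the power-law coefficients a, b and the input X."""

    u_a: float
    u_b: float
    u_X: float = 0.0

    def __post_init__(self):
        if self.u_a < 0 or self.u_b < 0 or self.u_X < 0:
            raise ValueError("coefficient uncertainties must be >= 0")


#: Published / re-derived coefficient uncertainties for the band-ratio
#: POC model (u_a in mg m^-3, u_b dimensionless).
BAND_RATIO_POC_MODEL_U = ModelCoefficientUncertainty(u_a=2.20, u_b=0.015)

#: Reported coefficient uncertainties for the IOP (bbp,470) POC model.
IOP_POC_MODEL_U = ModelCoefficientUncertainty(u_a=45534.0, u_b=0.046)

#: (a_poc, b_poc) of the IOP-based POC model, X = bbp(470) in m^-1.
IOP_POC_COEFFS = (141253.0, 1.18)


@dataclass(frozen=True)
class UncertaintyBudget:
    """Combined measurement uncertainty and per-source variance shares."""

    u_data: float
    u_model: float
    u_measurement: float
    fractions: Mapping[str, float]

    def __post_init__(self):
        rss = math.sqrt(self.u_data**2 + self.u_model**2)
        if abs(self.u_measurement - rss) > 1e-12 * max(rss, 1.0):
            raise ValueError("u_measurement must be the RSS of components")
        total = sum(self.fractions.values())
        if any(f < 0 for f in self.fractions.values()) or abs(total - 1) > 1e-9:
            raise ValueError("fractions must be >= 0 and sum to 1")


def poc_model_variance(X: float, a: float, b: float,
                       mu: ModelCoefficientUncertainty) -> float:
    """Model uncertainty u_model(POC) for POC = a X^b (positive root)."""
    if X <= 0:
        raise ValueError("X must be positive")
    xb = X**b
    var = ((xb * mu.u_a) ** 2
           + (a * xb * math.log(X) * mu.u_b) ** 2
           + (a * b * X ** (b - 1.0) * mu.u_X) ** 2)
    return math.sqrt(var)


def poc_iop_data_variance(b470: float, u_b470: float,
                          a: float = IOP_POC_COEFFS[0],
                          b: float = IOP_POC_COEFFS[1]) -> float:
    """Data uncertainty of the IOP POC model: |a b X^(b-1)| u_data(bbp,470).

    ``b470`` and its data uncertainty come from shifting the retrieved
    bbp at the reference band to 470 nm (see giop.bbp_shift).
    """
    if b470 <= 0:
        raise ValueError("bbp(470) must be positive")
    if u_b470 < 0:
        raise ValueError("u(bbp,470) must be >= 0")
    return abs(a * b * b470 ** (b - 1.0)) * u_b470


def combine_measurement(u_data: float, u_model: float) -> float:
    """Root-sum-square combination of data and model uncertainty."""
    if u_data < 0 or u_model < 0:
        raise ValueError("uncertainty components must be >= 0")
    return math.sqrt(u_data**2 + u_model**2)


def budget_fractions(components: Mapping[str, float]) -> dict[str, float]:
    """Variance share of each named uncertainty component.

    fraction_k = u_k^2 / sum_j u_j^2.
    """
    if any(u < 0 for u in components.values()):
        raise ValueError("uncertainty components must be >= 0")
    total = sum(u**2 for u in components.values())
    if total == 0:
        raise ValueError("all components are zero")
    return {k: u**2 / total for k, u in components.items()}


def make_budget(u_data: float,
                model_components: Mapping[str, float]) -> UncertaintyBudget:
    """Assemble a budget from a data component and named model components."""
    u_model = math.sqrt(sum(u**2 for u in model_components.values()))
    u_meas = combine_measurement(u_data, u_model)
    fr = budget_fractions({"data": u_data, **model_components})
    return UncertaintyBudget(u_data, u_model, u_meas, fr)
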