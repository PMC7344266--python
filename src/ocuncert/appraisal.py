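"""FOFM-vs-Monte-Carlo comparison statistics.

Uncertainties of bio-optical products are approximately log-normally
distributed, so the two methods are compared in log10 space: a
multiplicative bias

    bias = 10^{ mean( log10(reference) - log10(test) ) }

(reference = Monte-Carlo, treated as quasi-truth) and a Type-II
standardized-major-axis regression slope on the log-transformed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ComparisonStats", "log_bias", "type2_slope", "compare"]


@dataclass(frozen=True)
class ComparisonStats:
    bias: float
    slope: float
    n: int


def _positive(a, name: str) -> np.ndarray:
    x = np.asarray(a, dtype=float)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be positive and finite")
    return x


def log_bias(reference, test) -> float:
    """Multiplicative bias 10^mean(log10(ref) - log10(test))."""
    r = _positive(reference, "reference")
    t = _positive(test, "test")
    if r.shape != t.shape:
        raise ValueError("reference and test must have equal length")
    return float(10.0 ** np.mean(np.log10(r) - np.log10(t)))


def type2_slope(x, y) -> float:
    """Standardized-major-axis slope of log10(y) on log10(x).

    slope = sign(corr) * sigma_logy / sigma_logx; symmetric in the sense
    that slope(x, y) * slope(y, x) = 1.
    """
    lx = np.log10(_positive(x, "x"))
    ly = np.log10(_positive(y, "y"))
    if lx.size != ly.size or lx.size < 3:
        raise ValueError("need at least 3 paired positive values")
    sx = lx.std(ddof=1)
    sy = ly.std(ddof=1)
    if sx == 0:
        raise ValueError("zero variance in x")
    corr = np.corrcoef(lx, ly)[0, 1]
    sign = 1.0 if corr >= 0 else -1.0
    return float(sign * sy / sx)


def compare(reference, test) -> ComparisonStats:
    """Bias and SMA slope for one product's paired uncertainty estimates."""
    r = np.asarray(reference, float)
    return ComparisonStats(
        bias=log_bias(reference, test),
        slope=type2_slope(reference, test),
        n=r.size,
    )
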