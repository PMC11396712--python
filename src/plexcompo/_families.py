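"""Shared helpers for the three intensity-distribution families.

Parameter conventions (``params`` is always a ``(p1, p2)`` pair):

* ``normal``    — (mean, sd)
* ``lognormal`` — (meanlog, sdlog), i.e. location/scale of log intensity
* ``weibull``   — (shape, scale)
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

FAMILIES = ("normal", "lognormal", "weibull")


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def logpdf(family: str, params, x: np.ndarray) -> np.ndarray:
    """Log density on the original intensity scale; -inf outside support."""
    _check_family(family)
    x = np.asarray(x, dtype=float)
    p1, p2 = params
    if family == "normal":
        return stats.norm.logpdf(x, loc=p1, scale=p2)
    out = np.full(x.shape, -np.inf)
    pos = x > 0
    if family == "lognormal":
        out[pos] = stats.norm.logpdf(np.log(x[pos]), loc=p1, scale=p2) - np.log(x[pos])
    else:
        out[pos] = stats.weibull_min.logpdf(x[pos], c=p1, scale=p2)
    return out


def dist_mean(family: str, params) -> float:
    """Mean of the distribution (used to identify the 'positive' component)."""
    _check_family(family)
    p1, p2 = params
    if family == "normal":
        return float(p1)
    if family == "lognormal":
        return float(np.exp(p1 + 0.5 * p2**2))
    return float(p2 * special.gamma(1.0 + 1.0 / p1))


def sample(rng: np.random.Generator, family: str, params, size: int) -> np.ndarray:
    _check_family(family)
    p1, p2 = params
    if family == "normal":
        return rng.normal(p1, p2, size)
    if family == "lognormal":
        return rng.lognormal(p1, p2, size)
    return p2 * rng.weibull(p1, size)
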