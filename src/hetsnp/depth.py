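"""Extreme-value model of read mapping depth and the repeat-exclusion cutoff.

Mapped-read depth over a mixture of single-copy and repeated reference
sequences is strongly right-skewed: reads from all copies of a repeat
collapse onto one reference, inflating its depth severalfold.  A Gumbel
(type-I extreme value) distribution fitted to the pooled depths yields a
mean X̄ and standard deviation s from which the maximum-depth cutoff
floor(X̄ + k*s) is derived; sites above it are treated as repeat-derived
and excluded from SNP discovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

EULER_GAMMA = 0.5772156649015329


@dataclass
class DepthModel:
    """Fitted Gumbel depth distribution and the derived cutoff."""

    mu: float  # location, reads
    beta: float  # scale, reads (> 0)
    xbar: float  # implied mean, reads
    s: float  # implied SD, reads
    k: float  # cutoff multiplier
    cutoff: int  # floor(xbar + k*s), reads


def depth_cutoff(xbar: float, s: float, k: float) -> int:
    """Maximum-depth cutoff floor(xbar + k*s)."""
    if s < 0:
        raise ValueError("depth SD must be non-negative")
    return int(math.floor(xbar + k * s))


def fit_evd(depths, k: float = 0.5, moment_source: str = "fitted") -> DepthModel:
    """Fit a Gumbel distribution to per-site depths by maximum likelihood.

    ``moment_source`` picks where X̄ and s come from: "fitted" derives them
    from the MLE (mu, beta) via X̄ = mu + γ·beta and s = π·beta/√6;
    "sample" uses the sample moments of the data.  Method-of-moments is
    the fallback when the MLE does not converge.
    """
    if moment_source not in ("fitted", "sample"):
        raise ValueError(f"unknown moment_source {moment_source!r}")
    x = np.asarray(depths, dtype=float)
    if x.size < 30:
        raise ValueError(f"need >= 30 depth observations, got {x.size}")
    if np.any(x < 0):
        raise ValueError("depths must be non-negative")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) depth sample")
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    try:
        mu, beta = stats.gumbel_r.fit(x)
        if not np.isfinite(mu) or not np.isfinite(beta) or beta <= 0:
            raise RuntimeError("non-finite MLE")
    except Exception:
        # method-of-moments fallback
        beta = sd * math.sqrt(6.0) / math.pi
        mu = mean - EULER_GAMMA * beta
    if moment_source == "fitted":
        xbar = mu + EULER_GAMMA * beta
        s = math.pi * beta / math.sqrt(6.0)
    else:
        xbar, s = mean, sd
    return DepthModel(mu=float(mu), beta=float(beta), xbar=xbar, s=s, k=k,
                      cutoff=depth_cutoff(xbar, s, k))
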