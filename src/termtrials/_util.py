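"""Shared numeric helpers: reporting-style rounding, percentage formatting,
and a small distribution-law sampler used by the synthetic generator."""

from __future__ import annotations

import math
from typing import Any, Mapping

import numpy as np


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (registry reports print 39.5% as 40%,
    not banker's 40/38 ambiguity)."""
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    out = rounded / factor
    return out if ndigits > 0 else float(int(out))


def fmt_pct(count: float, denom: float) -> str:
    """Format a table percentage: integer percent, except one decimal below
    1% (so 2/217 prints as "0.9", matching registry-report style)."""
    if denom == 0:
        return "0"
    pct = 100.0 * count / denom
    if 0 < pct < 1:
        return f"{round_half_away(pct, 1):.1f}"
    return f"{int(round_half_away(pct)):d}"


def sample_law(rng: np.random.Generator, law: Mapping[str, Any], size: int) -> np.ndarray:
    """Sample from a small declarative distribution spec.

    Supported kinds:
      degenerate(value); lognormal(mu, sigma); beta(a, b[, scale]);
      gamma(shape, scale); uniform(low, high); normal(mu, sigma).
    """
    kind = law["kind"]
    if kind == "degenerate":
        return np.full(size, float(law["value"]))
    if kind == "lognormal":
        return rng.lognormal(mean=law["mu"], sigma=law["sigma"], size=size)
    if kind == "beta":
        return rng.beta(law["a"], law["b"], size=size) * law.get("scale", 1.0)
    if kind == "gamma":
        return rng.gamma(shape=law["shape"], scale=law["scale"], size=size)
    if kind == "uniform":
        return rng.uniform(law["low"], law["high"], size=size)
    if kind == "normal":
        return rng.normal(law["mu"], law["sigma"], size=size)
    raise ValueError(f"unknown distribution kind: {kind!r}")
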