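"""χ² goodness-of-fit test for Mendelian segregation ratios.

The classic single-gene check: do observed phenotype-class counts fit a
hypothesized ratio such as 3:1?  ``chi2 = Σ (obs − exp)² / exp`` with
``exp_i = total × ratio_i / Σratio`` and ``df = classes − 1``; the p-value
is the upper tail of the χ² distribution.  No continuity correction is
applied by default (Yates' correction is available behind a flag) —
uncorrected is the statistic segregation tables conventionally print.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["SegregationResult", "chi_square_segregation", "parse_ratio"]


@dataclass(frozen=True)
class SegregationResult:
    chi2: float
    df: int
    p_value: float
    expected: tuple[float, ...]


def parse_ratio(text: str) -> tuple[float, ...]:
    """Parse a ratio string like ``"3:1"`` or ``"1:2:1"``."""
    try:
        weights = tuple(float(x) for x in text.split(":"))
    except ValueError as exc:
        raise ValueError(f"cannot parse ratio {text!r}; expected e.g. '3:1'") from exc
    if len(weights) < 2 or any(w <= 0 for w in weights):
        raise ValueError(f"ratio needs >= 2 positive weights, got {text!r}")
    return weights


def chi_square_segregation(
    observed: Sequence[float],
    ratio: Sequence[float],
    yates: bool = False,
) -> SegregationResult:
    """Test observed class counts against a hypothesized segregation ratio.

    Parameters
    ----------
    observed
        Per-class counts, e.g. ``(135, 44)`` wild-type : mutant.
    ratio
        Per-class expected proportions (any positive weights; scale-free),
        e.g. ``(3, 1)``.
    yates
        Apply the Yates continuity correction ``(|obs − exp| − ½)²/exp``
        (only sensible for df = 1; off by default).
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need counts for at least 2 classes")
    if obs.size != w.size:
        raise ValueError("observed and ratio must have the same number of classes")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (w <= 0).any():
        raise ValueError("ratio weights must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    expected = total * w / w.sum()
    if (expected == 0).any():
        raise ValueError("an expected count is zero")
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    df = obs.size - 1
    p = float(sps.chi2.sf(chi2, df))
    return SegregationResult(chi2=chi2, df=df, p_value=p, expected=tuple(expected))
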