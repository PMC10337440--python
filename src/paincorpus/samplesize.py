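"""Minimum annotation count for a target estimation precision.

Standard sample-size form for estimating the sensitivity of a detector
of a class that occurs in a known fraction of items:

    n = ceil( z^2 * p * (1 - p) / (d^2 * prevalence) )

where ``z`` is the two-sided normal quantile for the stated confidence,
``p`` the expected sensitivity (or prevalence of the class of
interest), ``d`` the absolute half-width of the confidence interval,
and ``prevalence`` the fraction of items containing the class.  With
prevalence 1 this reduces to the usual single-proportion formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["SampleSizeSpec", "minimum_annotations", "formula_text"]


@dataclass(frozen=True)
class SampleSizeSpec:
    expected_sensitivity: float
    margin: float
    confidence: float = 0.95
    prevalence: float = 1.0

    def validate(self) -> None:
        for name in ("expected_sensitivity", "margin", "confidence",
                     "prevalence"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0) and not (name == "prevalence" and v == 1.0):
                raise ValueError(f"{name} = {v!r} must be in (0, 1)"
                                 + (" or 1" if name == "prevalence" else ""))


def _z(confidence: float) -> float:
    return float(norm.ppf(0.5 + confidence / 2.0))


def minimum_annotations(spec: SampleSizeSpec) -> int:
    """The smallest n meeting the precision target, always rounded up."""
    spec.validate()
    z = _z(spec.confidence)
    p = spec.expected_sensitivity
    n = (z * z * p * (1.0 - p)) / (spec.margin ** 2 * spec.prevalence)
    # guard the always-round-up rule against quantile round-off
    # (e.g. z for 95.45% confidence is 2 + O(1e-10))
    return math.ceil(round(n, 9))


def formula_text(spec: SampleSizeSpec) -> str:
    """The formula with the spec's numbers substituted, for display."""
    z = _z(spec.confidence)
    p = spec.expected_sensitivity
    n = minimum_annotations(spec)
    return (
        f"n = ceil(z^2 * p * (1 - p) / (d^2 * prevalence)) = "
        f"ceil({z:.4f}^2 * {p} * {1 - p:.6g} / "
        f"({spec.margin}^2 * {spec.prevalence})) = {n}"
    )
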