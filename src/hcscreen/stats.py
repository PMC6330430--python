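"""Validation statistics: confusion matrix, accuracy panel, exact binomial
confidence intervals, and sample-size planning.

The screening tool is binary (meets criteria / does not), so its agreement
with expert review reduces to a 2x2 table with cells

    A  true positives    B  false positives
    C  false negatives   D  true negatives

and the usual panel: sensitivity A/(A+C), specificity D/(D+B), accuracy
(A+D)/total.  Confidence intervals are Clopper-Pearson exact by default (beta
quantile formulation), with Wilson and Wald available as alternatives.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional

from scipy import stats as sps

__all__ = [
    "ConfusionMatrix",
    "IntervalEstimate",
    "CIMethod",
    "confusion",
    "accuracy_panel",
    "exact_binomial_ci",
    "binomial_ci",
    "sample_size_proportion",
    "event_rate",
    "MEETS",
    "DOES_NOT_MEET",
]

MEETS = "meets"
DOES_NOT_MEET = "does-not-meet"


class CIMethod(str, enum.Enum):
    CLOPPER_PEARSON = "clopper_pearson"
    WILSON = "wilson"
    WALD = "wald"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts A (TP), B (FP), C (FN), D (TN)."""

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.A + self.B + self.C + self.D


@dataclass(frozen=True)
class IntervalEstimate:
    """A proportion with a confidence interval, on the [0, 1] scale."""

    point: float
    lower: float
    upper: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError("require 0 <= lower <= point <= upper <= 1")

    def as_percent(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(point, lower, upper) as percentages rounded to ``ndigits``."""
        return tuple(round(100.0 * v, ndigits) for v in (self.point, self.lower, self.upper))


def _as_bool(label) -> bool:
    if isinstance(label, bool):
        return label
    if label in (MEETS, 1):
        return True
    if label in (DOES_NOT_MEET, 0):
        return False
    raise ValueError(f"unrecognized label: {label!r}")


def confusion(truth: Iterable, predicted: Iterable) -> ConfusionMatrix:
    """Tally paired per-event labels (truth = expert review, predicted = the
    tool) into the 2x2 table.  Labels may be booleans or the strings
    ``"meets"`` / ``"does-not-meet"``."""
    t = [_as_bool(x) for x in truth]
    p = [_as_bool(x) for x in predicted]
    if len(t) != len(p):
        raise ValueError(f"label sequences differ in length: {len(t)} vs {len(p)}")
    a = sum(1 for x, y in zip(t, p) if x and y)
    b = sum(1 for x, y in zip(t, p) if not x and y)
    c = sum(1 for x, y in zip(t, p) if x and not y)
    d = sum(1 for x, y in zip(t, p) if not x and not y)
    return ConfusionMatrix(A=a, B=b, C=c, D=d)


def exact_binomial_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> IntervalEstimate:
    """Clopper-Pearson exact interval via beta quantiles.

    lower = Beta(alpha/2; x, n-x+1), upper = Beta(1-alpha/2; x+1, n-x), with
    the boundary conventions lower=0 at x=0 and upper=1 at x=n.
    """
    if trials <= 0 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    x, n = successes, trials
    lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(sps.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return IntervalEstimate(point=x / n, lower=lower, upper=upper, confidence=confidence)


def binomial_ci(
    successes: int,
    trials: int,
    confidence: float = 0.95,
    method: CIMethod = CIMethod.CLOPPER_PEARSON,
) -> IntervalEstimate:
    """Binomial proportion CI with a selectable method (exact by default)."""
    method = CIMethod(method)
    if method is CIMethod.CLOPPER_PEARSON:
        return exact_binomial_ci(successes, trials, confidence)
    if trials <= 0 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    p = successes / trials
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    if method is CIMethod.WALD:
        half = z * math.sqrt(p * (1 - p) / trials)
        return IntervalEstimate(
            point=p,
            lower=max(0.0, p - half),
            upper=min(1.0, p + half),
            confidence=confidence,
        )
    # Wilson score
    n = trials
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return IntervalEstimate(
        point=min(max(p, center - half), center + half),
        lower=center - half,
        upper=center + half,
        confidence=confidence,
    )


def accuracy_panel(
    m: ConfusionMatrix,
    confidence: float = 0.95,
    method: CIMethod = CIMethod.CLOPPER_PEARSON,
) -> dict[str, Optional[IntervalEstimate]]:
    """Sensitivity, specificity and accuracy with confidence intervals.

    A quantity whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """
    out: dict[str, Optional[IntervalEstimate]] = {}
    for name, x, n in (
        ("sensitivity", m.A, m.A + m.C),
        ("specificity", m.D, m.D + m.B),
        ("accuracy", m.A + m.D, m.total),
    ):
        out[name] = binomial_ci(x, n, confidence, method) if n > 0 else None
    return out


def sample_size_proportion(
    assumed_p: float, delta: float, alpha: float = 0.05, power: float = 0.90
) -> int:
    """Smallest n for a one-sample proportion comparison by the
    normal-approximation formula n = (z_{1-a/2} + z_{1-b})^2 p(1-p) / d^2,
    rounded up."""
    if not 0.0 < assumed_p < 1.0:
        raise ValueError("assumed_p must be in (0, 1)")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    if not 0.0 < delta < min(assumed_p, 1.0 - assumed_p):
        raise ValueError("delta must be positive and feasible for assumed_p")
    z_a = float(sps.norm.ppf(1.0 - alpha / 2.0))
    z_b = float(sps.norm.ppf(power))
    n = (z_a + z_b) ** 2 * assumed_p * (1.0 - assumed_p) / delta**2
    return math.ceil(n)


def event_rate(events: int, pedigrees: int) -> float:
    """Events per pedigree, reported to 2 decimal places."""
    if pedigrees <= 0:
        raise ValueError("pedigree count must be positive")
    return round(events / pedigrees, 2)
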