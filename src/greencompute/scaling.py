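"""Per-unit normalization and runtime-scaling extrapolation.

Benchmarked footprints are tied to one input size (so many reads, variants,
Gb, ...).  To compare tools or predict other workloads they are normalized
per unit of work and extrapolated along the task's stated scaling law:
linear in input size for most read-based tools, or a power law
C' = C * (s'/s)^alpha for methods whose runtime grows super-linearly (e.g.
mixed-model association tests with time ~ O(N^1.5) in the sample size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "ScalingModel",
    "parse_scaling",
    "per_unit_footprint",
    "extrapolate",
    "fit_scaling_exponent",
    "mean_per_tool_ratio",
    "percent_change",
]

LINEAR = "linear"
POWER_LAW = "power-law"


@dataclass(frozen=True)
class ScalingModel:
    """How a task's footprint scales with its input size.

    ``kind`` is ``linear`` (exponent fixed at 1) or ``power-law`` with a
    positive exponent alpha.  ``reference_size`` is the input size (in
    ``unit``) at which a known footprint was measured; ``unit`` may carry a
    scale prefix such as ``million-reads``.
    """

    kind: str
    exponent: float = 1.0
    unit: str = ""
    reference_size: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (LINEAR, POWER_LAW):
            raise ValidationError(f"scaling kind must be {LINEAR!r} or {POWER_LAW!r}, got {self.kind!r}")
        if self.kind == LINEAR and self.exponent != 1.0:
            raise ValidationError("linear scaling requires exponent 1")
        if not (math.isfinite(self.exponent) and self.exponent > 0):
            raise ValidationError(f"exponent must be > 0, got {self.exponent!r}")
        if not (math.isfinite(self.reference_size) and self.reference_size > 0):
            raise ValidationError(f"reference_size must be > 0, got {self.reference_size!r}")

    def at(self, reference_size: float) -> "ScalingModel":
        return ScalingModel(self.kind, self.exponent, self.unit, reference_size)

    def to_token(self) -> str:
        """Serialize to the catalog token (``linear:<unit>`` / ``power:<a>:<unit>``)."""
        if self.kind == LINEAR:
            return f"linear:{self.unit}"
        return f"power:{self.exponent:g}:{self.unit}"


def parse_scaling(token: str) -> ScalingModel:
    """Parse a catalog scaling token: ``linear:<unit>`` or ``power:<alpha>:<unit>``."""
    parts = token.strip().split(":")
    if parts[0] == "linear" and len(parts) == 2:
        return ScalingModel(LINEAR, 1.0, parts[1])
    if parts[0] == "power" and len(parts) == 3:
        try:
            alpha = float(parts[1])
        except ValueError:
            raise ValidationError(f"bad power-law exponent in scaling token {token!r}") from None
        return ScalingModel(POWER_LAW, alpha, parts[2])
    raise ValidationError(f"bad scaling token {token!r}; expected linear:<unit> or power:<alpha>:<unit>")


def per_unit_footprint(kg_co2e: float, size: float, unit_scale: float = 1.0) -> float:
    """Footprint per unit of work: C / (size / unit_scale).

    ``unit_scale`` expresses "per million reads"-style units without 1e6
    bookkeeping at call sites: pass size in raw units and unit_scale=1e6,
    or size already in millions and unit_scale=1.
    """
    if not size > 0:
        raise ValidationError(f"size must be > 0, got {size!r}")
    if not unit_scale > 0:
        raise ValidationError(f"unit_scale must be > 0, got {unit_scale!r}")
    if kg_co2e < 0:
        raise ValidationError(f"kg_co2e must be >= 0, got {kg_co2e!r}")
    return kg_co2e / (size / unit_scale)


def extrapolate(kg_co2e: float, model: ScalingModel, target_size: float) -> float:
    """Predicted footprint at another input size: C * (s'/s_ref)^exponent."""
    if not target_size > 0:
        raise ValidationError(f"target_size must be > 0, got {target_size!r}")
    if kg_co2e < 0:
        raise ValidationError(f"kg_co2e must be >= 0, got {kg_co2e!r}")
    return kg_co2e * (target_size / model.reference_size) ** model.exponent


def fit_scaling_exponent(sizes: Sequence[float], kgs: Sequence[float]) -> tuple[float, float]:
    """Least-squares fit of log C against log size.

    Returns (exponent, prefactor): the slope alpha and the footprint the fit
    predicts at size 1.  Requires at least two distinct positive sizes and
    positive footprints.
    """
    s = np.asarray(sizes, dtype=float)
    c = np.asarray(kgs, dtype=float)
    if s.shape != c.shape or s.size < 2:
        raise ValidationError("need at least two (size, kg) pairs of equal length")
    if not (np.all(s > 0) and np.all(c > 0)):
        raise ValidationError("sizes and footprints must be > 0 for a log-log fit")
    if np.unique(s).size < 2:
        raise ValidationError("sizes must not all be equal")
    slope, intercept = np.polyfit(np.log(s), np.log(c), 1)
    return float(slope), float(np.exp(intercept))


def mean_per_tool_ratio(
    group_a: Mapping[str, tuple[float, float]],
    group_b: Mapping[str, tuple[float, float]],
) -> float:
    """Mean ratio of per-unit footprints between two matched tool groups.

    Each group maps tool name -> (kg_co2e, input size).  For every tool the
    per-unit footprint ratio a/b is formed; the arithmetic mean of the
    per-tool ratios is returned (not the ratio of group means, which would
    let one tool dominate).
    """
    if set(group_a) != set(group_b):
        raise ValidationError(
            f"tool sets differ: {sorted(set(group_a) ^ set(group_b))}"
        )
    if not group_a:
        raise ValidationError("tool groups must be nonempty")
    ratios = []
    for tool in group_a:
        kg_a, size_a = group_a[tool]
        kg_b, size_b = group_b[tool]
        pa = per_unit_footprint(kg_a, size_a)
        pb = per_unit_footprint(kg_b, size_b)
        if pb == 0:
            raise ValidationError(f"zero per-unit footprint for {tool!r} in group_b")
        ratios.append(pa / pb)
    return float(np.mean(ratios))


def percent_change(reference: float, other: float) -> float:
    """Signed percentage change of ``other`` relative to ``reference``."""
    if not reference > 0:
        raise ValidationError(f"reference must be > 0, got {reference!r}")
    return 100.0 * (other - reference) / reference
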