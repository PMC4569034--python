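"""Standardized reaction-norm metrics.

All four metrics are nonnegative ratios of an absolute trait-mean
difference to a same-unit standardizer, so they are unitless, scale
invariant (multiplying every cell mean by c != 0 changes nothing), and
range from 0 to +infinity:

* :func:`pair_plasticity` — |resident - nonresident| / |resident|.
  Near 0 means no plastic response; at the mean coefficient of variation
  (0.53 in the synthesis this package operationalizes) the shift equals
  about one within-population standard deviation.
* :func:`population_differentiation` — |AinA - BinB| standardized by the
  mean of the two resident means.  Distinguishes canalized blocks with no
  population differentiation from genetically differentiated ones.
* :func:`pair_adaptiveness` — how far a transplanted population's
  phenotype lands from the resident population's phenotype, standardized
  by the distance between the two resident phenotypes.  0 = perfect
  convergence on the resident optimum, values in (0, 1) = partial
  convergence, >= 1 = divergence (nonadaptive plasticity).
* :func:`block_adaptiveness` — the block-level analogue using the larger
  of the two populations' convergence failures over the common
  standardizer |AinA - BinB|.

Zero denominators are flagged ``degenerate``: the value is 0 when the
numerator is also 0 (no signal either way) and +infinity otherwise.
Degenerate results are excluded from CDFs and classified UNCLASSIFIED
downstream.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .records import TraitBlock

__all__ = [
    "Metric",
    "MetricResult",
    "pair_plasticity",
    "population_differentiation",
    "pair_adaptiveness",
    "block_adaptiveness",
    "block_metrics",
]


class Metric(str, enum.Enum):
    PLASTICITY = "plasticity"
    DIFFERENTIATION = "differentiation"
    PAIR_ADAPTIVENESS = "pair_adaptiveness"
    BLOCK_ADAPTIVENESS = "block_adaptiveness"


@dataclass(frozen=True)
class MetricResult:
    """A standardized ratio with provenance.

    ``population`` is "A" or "B" for the per-pair metrics and "BOTH" for
    the block-level ones.  ``degenerate`` marks zero-denominator cases.
    """

    value: float
    metric: Metric
    population: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("metric values are nonnegative by construction")


def _require_finite(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


def _ratio(numerator: float, denominator: float, metric: Metric, population: str) -> MetricResult:
    if denominator == 0.0:
        value = 0.0 if numerator == 0.0 else math.inf
        return MetricResult(value, metric, population, degenerate=True)
    return MetricResult(numerator / denominator, metric, population)


def pair_plasticity(
    resident_mean: float, nonresident_mean: float, population: str = "A"
) -> MetricResult:
    """Standardized trait shift of one population across environments."""
    _require_finite(resident_mean=resident_mean, nonresident_mean=nonresident_mean)
    return _ratio(
        abs(resident_mean - nonresident_mean),
        abs(resident_mean),
        Metric.PLASTICITY,
        population,
    )


def population_differentiation(AinA_mean: float, BinB_mean: float) -> MetricResult:
    """Standardized difference between the two resident phenotypes.

    The standardizer is the mean of the two resident means so the metric
    is symmetric under relabeling the populations.
    """
    _require_finite(AinA_mean=AinA_mean, BinB_mean=BinB_mean)
    return _ratio(
        abs(AinA_mean - BinB_mean),
        abs((AinA_mean + BinB_mean) / 2.0),
        Metric.DIFFERENTIATION,
        "BOTH",
    )


def pair_adaptiveness(
    own_resident_mean: float,
    own_nonresident_mean: float,
    other_resident_mean: float,
    population: str = "A",
) -> MetricResult:
    """Convergence of a transplanted population on the resident optimum.

    For population A the arguments are (AinA, AinB, BinB); for population
    B they are the mirror (BinB, BinA, AinA).  The denominator
    |own_resident - other_resident| is the same for both populations.
    """
    _require_finite(
        own_resident_mean=own_resident_mean,
        own_nonresident_mean=own_nonresident_mean,
        other_resident_mean=other_resident_mean,
    )
    return _ratio(
        abs(own_nonresident_mean - other_resident_mean),
        abs(own_resident_mean - other_resident_mean),
        Metric.PAIR_ADAPTIVENESS,
        population,
    )


def block_adaptiveness(block: TraitBlock | tuple[float, float, float, float]) -> MetricResult:
    """Block-level adaptiveness: the worse population's convergence failure.

    Accepts either a :class:`TraitBlock` or the four cell means in
    canonical order (AinA, AinB, BinB, BinA).
    """
    means = block.means if isinstance(block, TraitBlock) else tuple(block)
    aina, ainb, binb, bina = means
    _require_finite(AinA=aina, AinB=ainb, BinB=binb, BinA=bina)
    return _ratio(
        max(abs(ainb - binb), abs(bina - aina)),
        abs(aina - binb),
        Metric.BLOCK_ADAPTIVENESS,
        "BOTH",
    )


def block_metrics(block: TraitBlock) -> dict[str, MetricResult]:
    """All six metric evaluations of one block, keyed by metric/population."""
    aina, ainb, binb, bina = block.means
    return {
        "plasticity_A": pair_plasticity(aina, ainb, "A"),
        "plasticity_B": pair_plasticity(binb, bina, "B"),
        "differentiation": population_differentiation(aina, binb),
        "adaptiveness_A": pair_adaptiveness(aina, ainb, binb, "A"),
        "adaptiveness_B": pair_adaptiveness(binb, bina, aina, "B"),
        "block_adaptiveness": block_adaptiveness(block),
    }
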