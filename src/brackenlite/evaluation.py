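"""Scoring abundance estimates against a known truth.

Two metrics: the average relative error — the mean over truth species of
|R_true - R_est| / R_true — and the false-positive rate, the fraction of
reads assigned to species absent from the truth. Both are invariant under
species relabeling and uniform scaling of truth, estimate and total.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

__all__ = [
    "EvaluationResult",
    "average_relative_error",
    "false_positive_rate",
    "evaluate",
]


@dataclass(frozen=True)
class EvaluationResult:
    n: int
    per_species_relative_error: dict[int, float]
    average_relative_error: float
    false_positive_rate: float

    def __post_init__(self) -> None:
        if self.average_relative_error < 0:
            raise ValueError("average relative error must be >= 0")
        if not 0.0 <= self.false_positive_rate <= 1.0:
            raise ValueError("false-positive rate must be in [0, 1]")


def per_species_relative_errors(
    truth: Mapping[int, float], estimate: Mapping[int, float]
) -> dict[int, float]:
    """|R_true - R_est| / R_true per truth species; missing estimates count 0."""
    if not truth:
        raise ValueError("truth table is empty")
    errors: dict[int, float] = {}
    for species, true_reads in truth.items():
        if true_reads <= 0:
            raise ValueError(f"truth reads must be positive (species {species})")
        est = float(estimate.get(species, 0))
        errors[species] = abs(float(true_reads) - est) / float(true_reads)
    return errors


def average_relative_error(
    truth: Mapping[int, float], estimate: Mapping[int, float]
) -> float:
    """Mean relative error over truth species.

    The absolute value keeps over- and under-estimates from cancelling, so
    the metric behaves as an error rate.
    """
    errors = per_species_relative_errors(truth, estimate)
    return sum(errors.values()) / len(errors)


def false_positive_rate(
    truth: Mapping[int, float], estimate: Mapping[int, float], total_reads: float
) -> float:
    """Fraction of reads the estimate assigns to species absent from truth.

    The denominator is whatever the caller passes: total reads including
    unclassified by convention, or classified reads only for the stricter
    variant (the CLI exposes both).
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    fp = sum(float(v) for s, v in estimate.items() if s not in truth)
    return fp / float(total_reads)


def evaluate(
    truth: Mapping[int, float], estimate: Mapping[int, float], total_reads: float
) -> EvaluationResult:
    errors = per_species_relative_errors(truth, estimate)
    return EvaluationResult(
        n=len(errors),
        per_species_relative_error=errors,
        average_relative_error=sum(errors.values()) / len(errors),
        false_positive_rate=false_positive_rate(truth, estimate, total_reads),
    )
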