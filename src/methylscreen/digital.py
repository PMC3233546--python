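"""Digital-PCR molecule counting with most-probable-number correction.

A serum DNA aliquot is spread across the wells of a PCR plate at
limiting dilution and each well scored positive or negative for the
methylated target. With molecules landing in wells independently, the
number of molecules behind ``k`` positive wells out of ``N`` is
estimated by the Poisson (most-probable-number) correction

    λ̂ = −N · ln(1 − k/N),

which accounts for wells that received more than one molecule. Raw
positive-well counting ("naive") understates the true count as plates
approach saturation; plates with more than 15 hits per 96 wells are
flagged as saturated (scaled proportionally for other plate sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DigitalPlateSet",
    "DigitalQuant",
    "SaturationError",
    "estimate_molecules",
    "quantify_sample",
    "detection_call",
    "SATURATION_HITS_PER_96",
]

SATURATION_HITS_PER_96 = 15


class SaturationError(ValueError):
    """All wells positive: the molecule count cannot be estimated."""


@dataclass
class DigitalPlateSet:
    """Well-level results for one sample across one or more plates."""

    sample_id: str
    plates: list[tuple[int, int]]  # (wells_total, wells_positive)
    volume_assayed_ul: float       # serum-equivalent volume across all plates

    def __post_init__(self) -> None:
        if self.volume_assayed_ul <= 0:
            raise ValueError("volume_assayed_ul must be positive")
        for n, k in self.plates:
            if not 0 <= k <= n:
                raise ValueError(f"wells_positive {k} outside [0, {n}]")


@dataclass
class DigitalQuant:
    """Molecule quantification for one sample.

    ``concentration`` is molecules per ml serum,
    molecules_estimated × 1000 / volume_assayed_ul.
    """

    sample_id: str
    molecules_detected: int
    molecules_estimated: float
    concentration: float
    saturated: bool


def estimate_molecules(
    wells_total: int, wells_positive: int, method: str = "poisson"
) -> float:
    """Estimate template molecules on one plate from positive wells.

    ``naive`` returns the raw count k; ``poisson`` applies the
    most-probable-number correction −N·ln(1 − k/N). A fully positive
    plate carries no information about the count and raises
    :class:`SaturationError` under ``poisson``.
    """
    n, k = wells_total, wells_positive
    if not 0 <= k <= n:
        raise ValueError(f"wells_positive {k} outside [0, {n}]")
    if method == "naive":
        return float(k)
    if method == "poisson":
        if k == n:
            raise SaturationError(
                f"all {n} wells positive; molecule count not estimable"
            )
        return -n * math.log(1.0 - k / n)
    raise ValueError(f"unknown method {method!r}")


def is_saturated(wells_total: int, wells_positive: int,
                 hits_per_96: int = SATURATION_HITS_PER_96) -> bool:
    """Flag plates where multiple molecules per well become likely."""
    return wells_positive > hits_per_96 * wells_total / 96.0


def quantify_sample(
    plates: DigitalPlateSet, method: str = "poisson",
    saturation_hits_per_96: int = SATURATION_HITS_PER_96,
) -> DigitalQuant:
    """Sum per-plate estimates and scale to molecules per ml serum.

    The correction is applied per plate before summation (each plate is
    its own dilution); the saturation flag is raised if any single
    plate exceeds the hits threshold.
    """
    if not plates.plates:
        raise ValueError("at least one plate required")
    detected = sum(k for _, k in plates.plates)
    estimated = sum(estimate_molecules(n, k, method) for n, k in plates.plates)
    saturated = any(
        is_saturated(n, k, saturation_hits_per_96) for n, k in plates.plates
    )
    concentration = estimated * 1000.0 / plates.volume_assayed_ul
    return DigitalQuant(
        sample_id=plates.sample_id,
        molecules_detected=int(detected),
        molecules_estimated=float(estimated),
        concentration=float(concentration),
        saturated=saturated,
    )


def detection_call(quant: DigitalQuant, min_molecules: int = 1) -> bool:
    """Positive iff at least ``min_molecules`` raw positive wells."""
    if min_molecules < 1:
        raise ValueError("min_molecules must be >= 1")
    return quant.molecules_detected >= min_molecules
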