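"""Decoding mean activation into continuous number estimates.

The forward encoding fitted in :mod:`numercode.encoding` is a line
``MA = intercept + slope * n`` per inhibition strength, valid over that
strength's monotonic region.  Decoding simply inverts it:

    estimate = (MA - intercept) / slope

Estimates are real-valued and deliberately not clamped to the fitted
region — applying a strength tuned to one range of numbers to an input
from another range is exactly the mismatch (adaptation) experiment, and
the resulting out-of-region estimates carry the under/over-estimation
signature of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

from .dynamics import (
    NetworkParams,
    SimulationConfig,
    StimulusSpec,
    ensemble_mean_activation,
)
from .encoding import Codebook

__all__ = [
    "NumberEstimate",
    "decode",
    "estimation_error",
    "compare_numerosities",
    "ComparisonVerdict",
]


@dataclass(frozen=True)
class NumberEstimate:
    """A decoded numerosity with the strength that produced it.

    ``in_region`` is set when the true generating set size is known and
    records whether it lies inside the codebook region of ``beta_used``
    (decodes from outside that region are extrapolations).
    """

    estimate: float
    beta_used: float
    in_region: Optional[bool] = None

    def rounded(self) -> int:
        return int(round(self.estimate))


def decode(
    ma: float,
    beta: float,
    codebook: Codebook,
    set_size: Optional[int] = None,
) -> NumberEstimate:
    """Map a mean activation to a number estimate via the inverse fit."""
    entry = codebook[beta]  # raises KeyError naming the missing strength
    estimate = (float(ma) - entry.intercept) / entry.slope
    in_region = None
    if set_size is not None:
        in_region = set_size in entry.region
    return NumberEstimate(estimate=estimate, beta_used=beta, in_region=in_region)


def estimation_error(estimate: float, set_size: int) -> float:
    """Signed decode error, estimate minus true set size (negative =
    underestimation)."""
    est = estimate.estimate if isinstance(estimate, NumberEstimate) else float(estimate)
    return est - float(set_size)


@dataclass(frozen=True)
class ComparisonVerdict:
    verdict: str  # "first larger" | "second larger" | "equal"
    ma_difference: float  # MA(k1) - MA(k2)
    reliable: bool


def compare_numerosities(
    k1: int,
    k2: int,
    beta: float,
    params: Optional[NetworkParams] = None,
    config: Optional[SimulationConfig] = None,
    codebook: Optional[Codebook] = None,
) -> ComparisonVerdict:
    """Judge which of two set sizes is larger by comparing mean activation.

    Simulates both inputs at the same inhibition strength and compares the
    ensemble readouts directly — no decoding required.  When a codebook is
    supplied the verdict is flagged unreliable if either set size falls
    outside the strength's monotonic region (there the MA ordering need
    not track the numerical ordering).
    """
    if params is None:
        params = NetworkParams(beta=beta)
    else:
        params = replace(params, beta=beta)
    if config is None:
        config = SimulationConfig()
    ma1, _ = ensemble_mean_activation(params, StimulusSpec(set_size=k1), config)
    ma2, _ = ensemble_mean_activation(params, StimulusSpec(set_size=k2), config)
    diff = ma1 - ma2
    if diff > 0:
        verdict = "first larger"
    elif diff < 0:
        verdict = "second larger"
    else:
        verdict = "equal"
    reliable = True
    if codebook is not None and beta in codebook:
        region = codebook[beta].region
        reliable = (k1 in region) and (k2 in region)
    elif codebook is not None:
        reliable = False
    return ComparisonVerdict(verdict=verdict, ma_difference=diff, reliable=reliable)
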