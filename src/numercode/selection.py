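"""Inhibition selection: sensitivity argmax, error tables, and mismatch.

The network must pick an inhibition strength before it can decode.  The
Selection Algorithm measures, for each candidate strength, the local slope
of the ensemble mean-activation curve against set size at the current
input, and picks the strength with the steepest (most sensitive) slope —
for small inputs that is the strongest inhibition, for large inputs the
weakest.

The error table decodes every swept (set size, strength) cell with that
strength's own inverse fit, giving the signed estimation error landscape:
which strength is most accurate where, and what happens when a strength
adapted to one range is applied to an input from another (systematic
under- or over-estimation, the model's account of numerosity adaptation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import (
    NetworkParams,
    SimulationConfig,
    StimulusSpec,
    ensemble_mean_activation,
)
from .decode import NumberEstimate, decode, estimation_error
from .encoding import Codebook, SweepTable

__all__ = [
    "SensitivityProfile",
    "local_sensitivity",
    "select_beta",
    "estimate_with_selection",
    "build_error_table",
    "lowest_error_betas",
    "mismatch_estimate",
    "MismatchResult",
]

#: Estimates within this margin of the true set size count as accurate
#: (half a count either way).
ACCURACY_MARGIN = 0.5


def local_sensitivity(sweep: SweepTable, set_size: int, beta: float) -> float:
    """Finite-difference slope of ensemble MA vs set size at one strength.

    Central difference at interior grid points, one-sided at the edges.
    """
    sizes = sweep.set_sizes
    if len(sizes) < 2:
        raise ValueError("sweep must contain at least 2 set sizes")
    where = np.where(sizes == set_size)[0]
    if len(where) == 0:
        raise ValueError(f"set size {set_size} not in sweep grid")
    i = int(where[0])
    col = sweep.column(beta)
    if i == 0:
        j, k = 0, 1
    elif i == len(sizes) - 1:
        j, k = i - 1, i
    else:
        j, k = i - 1, i + 1
    return float((col[k] - col[j]) / (sizes[k] - sizes[j]))


@dataclass(frozen=True)
class SensitivityProfile:
    """Local MA-vs-set-size slope of every swept strength at one input."""

    set_size: int
    per_beta_slope: dict

    @classmethod
    def at(cls, sweep: SweepTable, set_size: int) -> "SensitivityProfile":
        slopes = {
            float(b): local_sensitivity(sweep, set_size, float(b))
            for b in sweep.betas
        }
        return cls(set_size=set_size, per_beta_slope=slopes)


def select_beta(
    sweep: SweepTable, candidate_betas: Sequence[float], set_size: int
) -> float:
    """Pick the candidate strength with the highest local sensitivity.

    Ties go to the larger strength (the small-number specialist).
    """
    candidates = list(candidate_betas)
    if not candidates:
        raise ValueError("select_beta: no candidate strengths")
    slopes = {b: local_sensitivity(sweep, set_size, b) for b in candidates}
    return max(candidates, key=lambda b: (slopes[b], b))


def estimate_with_selection(
    set_size: int,
    sweep: SweepTable,
    codebook: Codebook,
    candidates: Sequence[float],
    params: Optional[NetworkParams] = None,
    config: Optional[SimulationConfig] = None,
) -> NumberEstimate:
    """Full pipeline for one input: select a strength, simulate, decode.

    The chosen strength is found from the sweep's sensitivity profile; a
    fresh ensemble is then simulated at that strength and its mean
    readout decoded with the strength's inverse fit.
    """
    beta = select_beta(sweep, candidates, set_size)
    if beta not in codebook:
        raise KeyError(f"selected strength {beta} has no codebook entry")
    if params is None:
        params = NetworkParams(beta=beta)
    else:
        params = replace(params, beta=beta)
    if config is None:
        config = SimulationConfig()
    ma, _ = ensemble_mean_activation(params, StimulusSpec(set_size=set_size), config)
    return decode(ma, beta, codebook, set_size=set_size)


def build_error_table(sweep: SweepTable, codebook: Codebook) -> pd.DataFrame:
    """Signed and absolute decode error for every decodable sweep cell.

    Each strength decodes every set size with its own inverse fit,
    whether or not the set size lies in its monotonic region; the
    ``in_region`` column records which.  Strengths absent from the
    codebook are omitted.
    """
    rows = []
    for beta in sweep.betas:
        beta = float(beta)
        if beta not in codebook:
            continue
        entry = codebook[beta]
        col = sweep.column(beta)
        for n, ma in zip(sweep.set_sizes.tolist(), col.tolist()):
            est = decode(ma, beta, codebook, set_size=n)
            err = estimation_error(est, n)
            rows.append(
                {
                    "set_size": n,
                    "beta": beta,
                    "ma": ma,
                    "estimate": est.estimate,
                    "error": err,
                    "abs_error": abs(err),
                    "in_region": bool(est.in_region),
                }
            )
    return pd.DataFrame(rows)


def lowest_error_betas(
    error_table: pd.DataFrame, set_size: int, k: int = 3
) -> Tuple[float, ...]:
    """The k strengths with smallest absolute error at one set size.

    Sorted by ascending absolute error; exact ties resolved toward the
    larger strength.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = error_table[error_table["set_size"] == set_size]
    if sub.empty:
        raise ValueError(f"set size {set_size} not present in error table")
    ranked = sub.sort_values(
        by=["abs_error", "beta"], ascending=[True, False], kind="mergesort"
    )
    return tuple(float(b) for b in ranked["beta"].head(k))


@dataclass(frozen=True)
class MismatchResult:
    """Outcome of decoding with a mismatched (adapted) strength."""

    estimate: NumberEstimate
    error: float
    label: str  # "underestimate" | "overestimate" | "accurate"


def mismatch_estimate(
    set_size: int,
    beta_adapted: float,
    sweep: Optional[SweepTable],
    codebook: Codebook,
    params: Optional[NetworkParams] = None,
    config: Optional[SimulationConfig] = None,
) -> MismatchResult:
    """Simulate an input under an adapted strength and decode regardless.

    Models the adaptation aftereffect: a network still set to the
    strength appropriate for a previously processed range decodes the new
    input with that range's inverse fit, producing underestimation when
    the adapted strength is too high for the input and overestimation
    when it is too low.  If a sweep containing the condition is supplied
    its tabulated MA is reused; otherwise a fresh ensemble is simulated.
    """
    entry = codebook[beta_adapted]
    ma = None
    if sweep is not None:
        try:
            ma = sweep.ma(set_size, beta_adapted)
        except (KeyError, IndexError):
            ma = None
    if ma is None:
        p = NetworkParams(beta=beta_adapted) if params is None else replace(
            params, beta=beta_adapted
        )
        cfg = config or SimulationConfig()
        ma, _ = ensemble_mean_activation(p, StimulusSpec(set_size=set_size), cfg)
    est = decode(ma, beta_adapted, codebook, set_size=set_size)
    err = estimation_error(est, set_size)
    if err < -ACCURACY_MARGIN:
        label = "underestimate"
    elif err > ACCURACY_MARGIN:
        label = "overestimate"
    else:
        label = "accurate"
    return MismatchResult(estimate=est, error=err, label=label)
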