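"""Numerosity encoding: the sweep, monotonic regions and linear fits.

A sweep simulates the network at every combination of set size (1-50) and
inhibition strength (0.01-0.15 in steps of 0.01) and records the
ensemble-averaged mean activation.  For each inhibition strength the mean
activation rises monotonically with set size only over a limited interval;
points are taken from that monotonic region only and an ordinary
least-squares line is fitted through them.  The per-strength (region,
slope, intercept) entries form the *codebook*: the learned forward relation
whose inverse turns a mean activation back into a number estimate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import (
    NetworkParams,
    SimulationConfig,
    StimulusSpec,
    _simulate_batch,
)

__all__ = [
    "SweepTable",
    "MonotonicRegion",
    "CodebookEntry",
    "Codebook",
    "run_sweep",
    "detect_monotonic_region",
    "fit_line",
    "build_codebook",
]

logger = logging.getLogger(__name__)

DEFAULT_SET_SIZES = tuple(range(1, 51))
DEFAULT_BETAS = tuple(round(0.01 * i, 2) for i in range(1, 16))


@dataclass(frozen=True)
class MonotonicRegion:
    """Inclusive set-size bounds of a monotone-increasing segment."""

    beta: float
    n_lo: int
    n_hi: int

    def __post_init__(self) -> None:
        if self.n_lo > self.n_hi:
            raise ValueError("n_lo must be <= n_hi")

    def __contains__(self, n: int) -> bool:
        return self.n_lo <= n <= self.n_hi

    @property
    def length(self) -> int:
        return self.n_hi - self.n_lo + 1


@dataclass
class SweepTable:
    """Ensemble mean activation indexed by (set size, inhibition strength)."""

    set_sizes: np.ndarray
    betas: np.ndarray
    ma_mean: np.ndarray  # shape (len(set_sizes), len(betas))
    ma_sd: np.ndarray
    n_runs: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.set_sizes = np.asarray(self.set_sizes, dtype=int)
        self.betas = np.asarray(self.betas, dtype=float)
        shape = (len(self.set_sizes), len(self.betas))
        self.ma_mean = np.asarray(self.ma_mean, dtype=float)
        self.ma_sd = np.asarray(self.ma_sd, dtype=float)
        if self.ma_mean.shape != shape or self.ma_sd.shape != shape:
            raise ValueError(
                f"ma_mean/ma_sd must have shape {shape}, got "
                f"{self.ma_mean.shape}/{self.ma_sd.shape}"
            )
        if np.any(self.ma_sd < 0):
            raise ValueError("ma_sd must be non-negative")
        for grid, name in ((self.set_sizes, "set_sizes"), (self.betas, "betas")):
            if len(grid) > 1 and not np.all(np.diff(grid) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    def beta_index(self, beta: float) -> int:
        i = int(np.argmin(np.abs(self.betas - beta)))
        if abs(self.betas[i] - beta) > 1e-9:
            raise KeyError(f"beta {beta} not in sweep grid")
        return i

    def column(self, beta: float) -> np.ndarray:
        """MA-vs-set-size series for one inhibition strength."""
        return self.ma_mean[:, self.beta_index(beta)]

    def ma(self, set_size: int, beta: float) -> float:
        si = int(np.where(self.set_sizes == set_size)[0][0])
        return float(self.ma_mean[si, self.beta_index(beta)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, n in enumerate(self.set_sizes):
            for bi, b in enumerate(self.betas):
                rows.append(
                    {
                        "set_size": int(n),
                        "beta": float(b),
                        "ma_mean": self.ma_mean[si, bi],
                        "ma_sd": self.ma_sd[si, bi],
                        "n_runs": self.n_runs,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SweepTable":
        set_sizes = np.sort(df["set_size"].unique())
        betas = np.sort(df["beta"].unique())
        ma_mean = np.full((len(set_sizes), len(betas)), np.nan)
        ma_sd = np.full_like(ma_mean, np.nan)
        si = {int(n): i for i, n in enumerate(set_sizes)}
        bi = {float(b): i for i, b in enumerate(betas)}
        for row in df.itertuples():
            ma_mean[si[int(row.set_size)], bi[float(row.beta)]] = row.ma_mean
            ma_sd[si[int(row.set_size)], bi[float(row.beta)]] = row.ma_sd
        return cls(
            set_sizes=set_sizes,
            betas=betas,
            ma_mean=ma_mean,
            ma_sd=ma_sd,
            n_runs=int(df["n_runs"].iloc[0]),
        )

    @classmethod
    def from_csv(cls, path) -> "SweepTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


def run_sweep(
    set_sizes: Sequence[int] = DEFAULT_SET_SIZES,
    betas: Sequence[float] = DEFAULT_BETAS,
    params_base: Optional[NetworkParams] = None,
    config: Optional[SimulationConfig] = None,
    presentation_steps: int = 100,
    input_current: float = 1.0,
) -> SweepTable:
    """Simulate every (set size, beta) cell and tabulate ensemble MA.

    Cells are independent: each (set size, beta, run) triple has its own
    noise stream derived from ``config.seed``, so any cell reproduces a
    standalone :func:`~numercode.dynamics.ensemble_mean_activation` call
    at the same condition.
    """
    from dataclasses import replace

    if params_base is None:
        params_base = NetworkParams()
    if config is None:
        config = SimulationConfig()
    set_sizes = [int(k) for k in set_sizes]
    betas = [float(b) for b in betas]
    if not set_sizes or not betas:
        raise ValueError("set_sizes and betas must be non-empty")

    ma_mean = np.empty((len(set_sizes), len(betas)))
    ma_sd = np.empty_like(ma_mean)
    index_lists = [tuple(range(k)) for k in set_sizes]
    for bi, beta in enumerate(betas):
        params = replace(params_base, beta=beta)
        ma = _simulate_batch(
            params,
            set_sizes,
            config,
            presentation_steps=presentation_steps,
            input_current=input_current,
            node_index_lists=index_lists,
        )
        ma_mean[:, bi] = ma.mean(axis=1)
        ma_sd[:, bi] = ma.std(axis=1, ddof=1) if config.n_runs > 1 else 0.0
        logger.info("sweep: beta=%.3g done (%d set sizes)", beta, len(set_sizes))

    provenance = {
        "alpha": params_base.alpha,
        "lam": params_base.lam,
        "noise_sd": params_base.noise_sd,
        "n_nodes": params_base.n_nodes,
        "total_steps": config.total_steps,
        "dt": config.dt,
        "presentation_steps": presentation_steps,
        "seed": config.seed,
        "n_runs": config.n_runs,
    }
    return SweepTable(
        set_sizes=np.array(set_sizes),
        betas=np.array(betas),
        ma_mean=ma_mean,
        ma_sd=ma_sd,
        n_runs=config.n_runs,
        provenance=provenance,
    )


def detect_monotonic_region(
    series: Sequence[Tuple[int, float]],
    tol: float = 0.0,
    beta: float = float("nan"),
    min_rise: float = 0.0,
    step_floor: float = 0.0,
) -> Optional[MonotonicRegion]:
    """Longest contiguous run over which MA increases step to step.

    A step from point ``i-1`` to ``i`` continues a run when
    ``ma[i] - ma[i-1] > -tol`` with ``tol > 0`` (slack for ensemble
    noise), or strictly ``ma[i] > ma[i-1]`` at the default ``tol = 0``
    (plateaus terminate a run).  Ties on run length are broken toward the
    run with the larger total MA rise.  Returns ``None`` when no run of at
    least two points exists.

    Two optional guards qualify what counts as an *encoding* region on
    noisy ensemble data: runs whose total rise does not exceed
    ``min_rise`` are discarded (a chain of sub-noise up-ticks on a
    plateau is not a monotone code), and leading/trailing steps smaller
    than ``step_floor`` are trimmed (the region is delimited by
    increases distinguishable from the ensemble noise floor).  Both
    default to 0, which is the plain longest-run rule.
    """
    pts = list(series)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    ns = [int(n) for n, _ in pts]
    ma = [float(m) for _, m in pts]

    raw_runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(ma)):
        ok = (ma[i] - ma[i - 1] > -tol) if tol > 0 else (ma[i] > ma[i - 1])
        if not ok:
            if i - start >= 2:
                raw_runs.append((start, i - 1))
            start = i
    if len(ma) - start >= 2:
        raw_runs.append((start, len(ma) - 1))

    runs: list[tuple[int, int]] = []
    for lo, hi in raw_runs:
        if step_floor > 0:
            while lo < hi and ma[lo + 1] - ma[lo] < step_floor:
                lo += 1
            while hi > lo and ma[hi] - ma[hi - 1] < step_floor:
                hi -= 1
        if hi - lo < 1:
            continue
        if min_rise > 0 and ma[hi] - ma[lo] <= min_rise:
            continue
        runs.append((lo, hi))
    if not runs:
        return None
    best = max(runs, key=lambda r: (r[1] - r[0], ma[r[1]] - ma[r[0]]))
    return MonotonicRegion(beta=beta, n_lo=ns[best[0]], n_hi=ns[best[1]])


def fit_line(points: Sequence[Tuple[float, float]]) -> Tuple[float, float, float]:
    """OLS fit of MA on set size; returns (slope, intercept, rms residual)."""
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points to fit a line")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all set sizes identical; line fit undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    return float(slope), float(intercept), resid


@dataclass(frozen=True)
class CodebookEntry:
    region: MonotonicRegion
    slope: float
    intercept: float
    fit_residual: float


class Codebook:
    """Per-inhibition-strength linear encoding relations and their regions.

    Only strengths with a non-empty monotone-increasing region and a
    positive fitted slope are entered, so the inverse map (decoding) is
    always well defined.
    """

    def __init__(self, entries: Optional[Dict[float, CodebookEntry]] = None):
        self.entries: Dict[float, CodebookEntry] = dict(entries or {})

    def __contains__(self, beta: float) -> bool:
        return self._key(beta) is not None

    def __len__(self) -> int:
        return len(self.entries)

    def betas(self) -> Tuple[float, ...]:
        return tuple(sorted(self.entries))

    def _key(self, beta: float) -> Optional[float]:
        for b in self.entries:
            if abs(b - beta) <= 1e-9:
                return b
        return None

    def __getitem__(self, beta: float) -> CodebookEntry:
        key = self._key(beta)
        if key is None:
            raise KeyError(
                f"inhibition strength {beta} has no codebook entry "
                f"(available: {sorted(self.entries)})"
            )
        return self.entries[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "beta": b,
                "n_lo": e.region.n_lo,
                "n_hi": e.region.n_hi,
                "slope": e.slope,
                "intercept": e.intercept,
                "residual": e.fit_residual,
            }
            for b, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        # pandas' default float repr is shortest-round-trip, so the CSV is
        # lossless
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            f"{b:g}": {
                "n_lo": e.region.n_lo,
                "n_hi": e.region.n_hi,
                "slope": e.slope,
                "intercept": e.intercept,
                "residual": e.fit_residual,
            }
            for b, e in sorted(self.entries.items())
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Codebook":
        entries = {}
        for row in df.itertuples():
            beta = float(row.beta)
            entries[beta] = CodebookEntry(
                region=MonotonicRegion(beta=beta, n_lo=int(row.n_lo), n_hi=int(row.n_hi)),
                slope=float(row.slope),
                intercept=float(row.intercept),
                fit_residual=float(row.residual),
            )
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "Codebook":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    @classmethod
    def from_json(cls, path) -> "Codebook":
        payload = json.loads(Path(path).read_text())
        rows = [
            {"beta": float(b), **vals} for b, vals in payload.items()
        ]
        return cls.from_frame(pd.DataFrame(rows))


#: Noise-floor multipliers used by :func:`build_codebook` when deriving
#: the region-detection guards from the sweep's own ensemble sd: a step
#: counts as a real increase if it exceeds STEP_FLOOR_Z standard errors
#: of an MA difference, and a run is a real encoding region if its total
#: rise exceeds MIN_RISE_Z of them.
STEP_FLOOR_Z = 2.0
MIN_RISE_Z = 3.0


def build_codebook(sweep: SweepTable, tol: float = 0.0) -> Codebook:
    """Detect each strength's monotonic region and fit its encoding line.

    The noise guards of :func:`detect_monotonic_region` are derived per
    strength from the sweep's ensemble sd (the standard error of an MA
    difference between neighbouring set sizes), so plateau noise does not
    masquerade as an encoding region.  Strengths whose series has no
    qualifying run, or whose fitted slope is not positive, are skipped
    with a warning: their mean activation does not encode set size over
    any interval and cannot be decoded.
    """
    entries: Dict[float, CodebookEntry] = {}
    for beta in sweep.betas:
        bi = sweep.beta_index(beta)
        col = sweep.column(beta)
        sd = sweep.ma_sd[:, bi]
        sem_diff = float(np.sqrt(2.0) * np.median(sd) / np.sqrt(max(sweep.n_runs, 1)))
        series = list(zip(sweep.set_sizes.tolist(), col.tolist()))
        region = detect_monotonic_region(
            series,
            tol=tol,
            beta=float(beta),
            min_rise=MIN_RISE_Z * sem_diff,
            step_floor=STEP_FLOOR_Z * sem_diff,
        )
        if region is None:
            logger.warning("beta=%.3g: no monotone-increasing region; skipped", beta)
            continue
        pts = [(n, m) for n, m in series if region.n_lo <= n <= region.n_hi]
        slope, intercept, resid = fit_line(pts)
        if slope <= 0:
            logger.warning("beta=%.3g: non-positive fitted slope; skipped", beta)
            continue
        entries[float(beta)] = CodebookEntry(
            region=region, slope=slope, intercept=intercept, fit_residual=resid
        )
    return Codebook(entries)
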