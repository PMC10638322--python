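"""Reproducible figure-level pipelines.

Each experiment is a pure function of (configuration, seed): it runs the
relevant part of the package, writes CSV artifacts (the tested surface)
plus an optional plot, and returns an :class:`ExperimentReport` with the
output manifest and headline summary numbers.  Re-running with the same
configuration reproduces every file byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import NetworkParams, SimulationConfig
from .encoding import (
    DEFAULT_BETAS,
    DEFAULT_SET_SIZES,
    Codebook,
    SweepTable,
    build_codebook,
    run_sweep,
)
from .ranges import RangeCover, minimal_cover
from .selection import build_error_table, lowest_error_betas, select_beta

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "reproduce_fig3",
    "reproduce_fig4",
    "reproduce_fig5",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a figure pipeline needs, in one serialisable record."""

    set_sizes: Sequence[int] = DEFAULT_SET_SIZES
    betas: Sequence[float] = DEFAULT_BETAS
    n_nodes: int = 64
    alpha: float = 2.2
    lam: float = 1.0
    noise_sd: float = 0.03
    presentation_steps: int = 100
    total_steps: int = 5000
    dt: float = 1.0
    n_runs: int = 30
    seed: int = 0
    tol: float = 0.0
    target: tuple = (1, 50)

    def params(self) -> NetworkParams:
        return NetworkParams(
            n_nodes=self.n_nodes,
            alpha=self.alpha,
            lam=self.lam,
            noise_sd=self.noise_sd,
        )

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            total_steps=self.total_steps,
            dt=self.dt,
            seed=self.seed,
            n_runs=self.n_runs,
        )

    def snapshot(self) -> dict:
        d = asdict(self)
        d["set_sizes"] = list(self.set_sizes)
        d["betas"] = list(self.betas)
        d["target"] = list(self.target)
        return d

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Load from a YAML or JSON mapping of the field names."""
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if "set_sizes" in data:
            data["set_sizes"] = tuple(int(n) for n in data["set_sizes"])
        if "betas" in data:
            data["betas"] = tuple(float(b) for b in data["betas"])
        if "target" in data:
            data["target"] = tuple(data["target"])
        return cls(**data)


@dataclass
class ExperimentReport:
    config: dict
    outputs: List[str] = field(default_factory=list)
    summary: Dict[str, object] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config": self.config, "outputs": self.outputs, "summary": self.summary},
                indent=2,
                default=str,
            )
        )


def _ensure_outdir(out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_or_load_sweep(cfg: ExperimentConfig, out_dir, name="sweep.csv") -> SweepTable:
    """Load the sweep CSV if it already exists in out_dir, else run it."""
    out = _ensure_outdir(out_dir)
    path = out / name
    if path.exists():
        logger.info("reusing existing sweep %s", path)
        return SweepTable.from_csv(path)
    sweep = run_sweep(
        set_sizes=cfg.set_sizes,
        betas=cfg.betas,
        params_base=cfg.params(),
        config=cfg.sim_config(),
        presentation_steps=cfg.presentation_steps,
    )
    sweep.to_csv(path)
    return sweep


def _plot_fig3(sweep: SweepTable, codebook: Codebook, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    show = [b for b in (0.01, 0.02, 0.04, 0.10, 0.15) if b in codebook]
    cmap = plt.get_cmap("viridis")
    for i, b in enumerate(show):
        col = sweep.column(b)
        color = cmap(i / max(len(show) - 1, 1))
        ax.plot(sweep.set_sizes, col, ".", ms=4, alpha=0.4, color=color)
        e = codebook[b]
        mask = (sweep.set_sizes >= e.region.n_lo) & (sweep.set_sizes <= e.region.n_hi)
        ax.plot(sweep.set_sizes[mask], col[mask], "o", ms=5, color=color,
                label=f"beta={b:g}")
        xs = np.array([e.region.n_lo, e.region.n_hi])
        ax.plot(xs, e.intercept + e.slope * xs, "k--", lw=1)
    ax.set_xlabel("set size (input numerosity)")
    ax.set_ylabel("mean activation")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reproduce_fig3(
    cfg: ExperimentConfig, out_dir="results/fig3", plot: bool = True
) -> ExperimentReport:
    """Sweep + monotonic regions + linear fits (the encoding landscape)."""
    out = _ensure_outdir(out_dir)
    sweep = run_or_load_sweep(cfg, out)
    codebook = build_codebook(sweep, tol=cfg.tol)
    codebook.to_csv(out / "codebook.csv")
    codebook.to_json(out / "codebook.json")
    outputs = [str(out / "sweep.csv"), str(out / "codebook.csv"), str(out / "codebook.json")]
    if plot:
        _plot_fig3(sweep, codebook, out / "fig3.png")
        outputs.append(str(out / "fig3.png"))
    summary = {
        f"{b:g}": [codebook[b].region.n_lo, codebook[b].region.n_hi]
        for b in codebook.betas()
    }
    report = ExperimentReport(config=cfg.snapshot(), outputs=outputs,
                              summary={"regions": summary})
    report.write(out / "report.json")
    return report


def reproduce_fig4(
    cfg: ExperimentConfig, out_dir="results/fig4", top_k: int = 3
) -> ExperimentReport:
    """Error table and the lowest-error strengths per numerosity."""
    out = _ensure_outdir(out_dir)
    sweep = run_or_load_sweep(cfg, out)
    codebook = build_codebook(sweep, tol=cfg.tol)
    table = build_error_table(sweep, codebook)
    table.to_csv(out / "error_table.csv", index=False, float_format="%.12g")

    rows = []
    for n in sweep.set_sizes.tolist():
        best = lowest_error_betas(table, n, k=top_k)
        rows.append({"set_size": n, **{f"beta_rank{i+1}": b for i, b in enumerate(best)}})
    ranking = pd.DataFrame(rows)
    ranking.to_csv(out / "lowest_error_betas.csv", index=False, float_format="%.12g")

    # exponential-decay summary of best strength vs numerosity:
    # least squares on log(beta) = log(a) - c * n
    ns = ranking["set_size"].to_numpy(dtype=float)
    best_beta = ranking["beta_rank1"].to_numpy(dtype=float)
    decay_rate, log_a = np.polyfit(ns, np.log(best_beta), 1)
    summary = {
        "decay_rate": float(-decay_rate),
        "amplitude": float(np.exp(log_a)),
        "best_beta_at_max_n": float(best_beta[-1]),
    }
    report = ExperimentReport(
        config=cfg.snapshot(),
        outputs=[str(out / "error_table.csv"), str(out / "lowest_error_betas.csv")],
        summary=summary,
    )
    report.write(out / "report.json")
    return report


def reproduce_fig5(
    cfg: ExperimentConfig,
    out_dir="results/fig5",
    fixed_betas: Optional[Sequence[float]] = None,
) -> ExperimentReport:
    """Estimate-vs-input curves per fixed strength plus the selection policy.

    The fixed strengths default to the minimal cover's chosen set; the
    selection policy picks among the same set by local sensitivity.
    """
    out = _ensure_outdir(out_dir)
    sweep = run_or_load_sweep(cfg, out)
    codebook = build_codebook(sweep, tol=cfg.tol)
    regions = [codebook[b].region for b in codebook.betas()]
    cover = minimal_cover(regions, target=tuple(cfg.target))
    cover.to_json(out / "range_cover.json")
    if fixed_betas is None:
        fixed_betas = list(cover.betas)
    table = build_error_table(sweep, codebook)

    rows = []
    for n in sweep.set_sizes.tolist():
        row = {"set_size": n}
        for b in fixed_betas:
            cell = table[(table.set_size == n) & (np.isclose(table.beta, b))]
            row[f"estimate_beta_{b:g}"] = (
                float(cell["estimate"].iloc[0]) if len(cell) else np.nan
            )
        chosen = select_beta(sweep, list(fixed_betas), n)
        cell = table[(table.set_size == n) & (np.isclose(table.beta, chosen))]
        row["selection_beta"] = chosen
        row["estimate_selection"] = (
            float(cell["estimate"].iloc[0]) if len(cell) else np.nan
        )
        rows.append(row)
    estimates = pd.DataFrame(rows)
    estimates.to_csv(out / "estimates.csv", index=False, float_format="%.12g")

    report = ExperimentReport(
        config=cfg.snapshot(),
        outputs=[str(out / "estimates.csv"), str(out / "range_cover.json")],
        summary={
            "cover_betas": list(cover.betas),
            "intervals": [list(iv) for _, iv in cover.chosen],
            "uncovered": cover.uncovered,
        },
    )
    report.write(out / "report.json")
    return report
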