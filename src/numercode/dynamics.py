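"""Recurrent on-center/off-surround network dynamics.

The model is a single layer of ``N`` rate units (default 64, an 8x8 grid).
Each unit excites itself with strength ``alpha`` and inhibits every other
unit with strength ``beta`` through the saturating transfer function
``F(x) = x / (1 + x)`` (zero for non-positive input).  The state evolves by
explicit Euler steps of

    dx_i/dt = -lambda * x_i + alpha * F(x_i) - beta * sum_{j != i} F(x_j)
              + I_i + noise_i

with an external current ``I_i = 1`` injected into the first ``k`` units
("set size" k) during an initial presentation window, and zero-mean Gaussian
noise added independently per unit and per step.  Activations are rates and
are kept non-negative (the state is rectified at zero after every step);
without rectification the mutual inhibition drives all silent units to
large negative values and the network mean no longer encodes numerosity.

The scalar readout is the mean activation ``MA = (1/N) * sum_i x_i`` of the
steady state, which grows monotonically with set size over an
inhibition-dependent range and is the quantity decoded into number
estimates elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NetworkParams",
    "StimulusSpec",
    "SimulationConfig",
    "NetworkState",
    "activation",
    "euler_step",
    "simulate_run",
    "mean_activation",
    "ensemble_mean_activation",
    "analytic_fixed_point",
    "run_seed_sequence",
]

#: Per-step noise standard deviation used throughout (Gaussian, mean 0).
DEFAULT_NOISE_SD = 0.03


@dataclass(frozen=True)
class NetworkParams:
    """Constants of the recurrent network.

    Parameters
    ----------
    n_nodes:
        Number of units ``N`` (64 for the 8x8 object-location grid).
    alpha:
        Self-excitation strength (2.2; varying it does not change the
        qualitative shape of the code, so it is held fixed).
    beta:
        Mutual-inhibition strength; the model's one adaptable parameter,
        swept over 0.01-0.15.
    lam:
        Decay constant of each unit.
    noise_sd:
        Standard deviation of the per-unit, per-step additive noise.
    """

    n_nodes: int = 64
    alpha: float = 2.2
    beta: float = 0.01
    lam: float = 1.0
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError(f"n_nodes must be >= 1, got {self.n_nodes}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class StimulusSpec:
    """Input specification: which units are driven, how hard, for how long.

    ``set_size`` is the model's representation of stimulus numerosity: the
    count of units receiving ``input_current`` during the first
    ``presentation_steps`` Euler steps.  By full exchange symmetry of the
    network the identity of the driven units is immaterial; they default to
    indices ``0..set_size-1`` unless ``node_indices`` is given (e.g. by the
    object-location-map front end).
    """

    set_size: int
    input_current: float = 1.0
    presentation_steps: int = 100
    node_indices: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.set_size < 0:
            raise ValueError(f"set_size must be >= 0, got {self.set_size}")
        if self.presentation_steps < 0:
            raise ValueError("presentation_steps must be >= 0")
        if self.node_indices is not None:
            idx = tuple(int(i) for i in self.node_indices)
            if len(idx) != self.set_size:
                raise ValueError(
                    f"node_indices has length {len(idx)} but set_size is "
                    f"{self.set_size}"
                )
            if len(set(idx)) != len(idx):
                raise ValueError("node_indices must be distinct")
            object.__setattr__(self, "node_indices", idx)

    def resolve_indices(self, n_nodes: int) -> Tuple[int, ...]:
        if self.set_size > n_nodes:
            raise ValueError(
                f"set_size {self.set_size} exceeds network size {n_nodes}"
            )
        if self.node_indices is not None:
            if any(i < 0 or i >= n_nodes for i in self.node_indices):
                raise ValueError("node index out of range")
            return self.node_indices
        return tuple(range(self.set_size))


@dataclass(frozen=True)
class SimulationConfig:
    """Integration horizon, step size, ensemble size and reproducibility.

    One step of the explicit Euler scheme advances time by ``dt`` (a "time
    step" of the original description corresponds to ``dt = 1``).  The
    stimulus presentation occupies the first ``presentation_steps`` of
    ``total_steps`` (100 of 5000 by default), leaving a long relaxation to
    steady state.  ``steady_window`` is the number of trailing steps whose
    mean-activation values are averaged for the readout; the default of 1
    reads the final state only.

    ``seed`` may be an int or a tuple of ints; every simulated run draws
    its noise from an independent stream derived from
    ``(seed, set_size, round(beta * 1000), run_index)``, so ensembles are
    reproducible run-by-run regardless of batching.
    """

    total_steps: int = 5000
    dt: float = 1.0
    seed: int | Tuple[int, ...] = 0
    n_runs: int = 30
    steady_window: int = 1

    def __post_init__(self) -> None:
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 1 <= self.steady_window <= self.total_steps:
            raise ValueError("steady_window must be in [1, total_steps]")


@dataclass
class NetworkState:
    """Vector of unit activations plus the current step index."""

    activations: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=float)
        if self.activations.ndim != 1:
            raise ValueError("activations must be a 1-D vector")
        if not np.all(np.isfinite(self.activations)):
            raise ValueError("activations must be finite")


def activation(x):
    """Saturating transfer function ``F(x) = x/(1+x)`` for x > 0, else 0.

    Accepts scalars or arrays; output lies in ``[0, 1)`` and is
    non-decreasing.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("activation: input must be finite")
    out = np.where(x > 0, x / (1.0 + x), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def euler_step(
    state: NetworkState,
    params: NetworkParams,
    drive: np.ndarray,
    noise: np.ndarray,
    dt: float = 1.0,
    rectify: bool = True,
) -> NetworkState:
    """Advance the network by one explicit Euler step.

    ``drive`` is the external current vector ``I`` and ``noise`` the
    pre-sampled noise vector for this step (injected rather than drawn
    here so the update is exactly testable).  The inhibition each unit
    receives is ``beta`` times the summed output of all *other* units.
    With ``rectify`` (the default) the new state is clipped at zero,
    matching the non-negative-rate interpretation used everywhere else in
    the package; ``rectify=False`` exposes the raw linear update.
    """
    x = state.activations
    n = params.n_nodes
    drive = np.asarray(drive, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if x.shape != (n,) or drive.shape != (n,) or noise.shape != (n,):
        raise ValueError(
            f"state/drive/noise must all have shape ({n},); got "
            f"{x.shape}, {drive.shape}, {noise.shape}"
        )
    fx = activation(x)
    total = fx.sum()
    dx = (
        -params.lam * x
        + params.alpha * fx
        - params.beta * (total - fx)
        + drive
        + noise
    )
    new = x + dt * dx
    if rectify:
        np.maximum(new, 0.0, out=new)
    return NetworkState(activations=new, t=state.t + 1)


def mean_activation(state: NetworkState) -> float:
    """Network readout: arithmetic mean of the raw activations."""
    return float(state.activations.mean())


def run_seed_sequence(
    seed: int | Sequence[int], set_size: int, beta: float, run: int
) -> np.random.SeedSequence:
    """Seed sequence for one run of one (set size, inhibition) condition.

    Keying the stream on the physical condition rather than on grid
    position makes a sweep cell bit-identical to a standalone ensemble at
    the same condition and seed.
    """
    base = (seed,) if isinstance(seed, int) else tuple(int(s) for s in seed)
    return np.random.SeedSequence(
        base + (int(set_size), int(round(beta * 1000)), int(run))
    )


def _simulate_batch(
    params: NetworkParams,
    set_sizes: Sequence[int],
    config: SimulationConfig,
    presentation_steps: int,
    input_current: float,
    node_index_lists: Sequence[Tuple[int, ...]],
    noise_chunk: int = 500,
) -> np.ndarray:
    """Vectorised core: all runs of all listed set sizes at one beta.

    Returns per-run readouts with shape ``(len(set_sizes), n_runs)``.
    Noise for each (condition, run) pair comes from its own generator,
    drawn in chunks; chunking does not change the stream.
    """
    n = params.n_nodes
    runs = config.n_runs
    conds = len(set_sizes)
    batch = conds * runs
    rngs = [
        np.random.default_rng(run_seed_sequence(config.seed, k, params.beta, r))
        for k in set_sizes
        for r in range(runs)
    ]
    drive = np.zeros((batch, n))
    for ci, idx in enumerate(node_index_lists):
        for i in idx:
            drive[ci * runs : (ci + 1) * runs, i] = input_current

    x = np.zeros((batch, n))
    dt = config.dt
    lam, alpha, beta = params.lam, params.alpha, params.beta
    window = config.steady_window
    ma_acc = np.zeros(batch)
    noise_sd = params.noise_sd

    t = 0
    total = config.total_steps
    while t < total:
        m = min(noise_chunk, total - t)
        if noise_sd > 0:
            noise = np.stack([rng.normal(0.0, noise_sd, size=(m, n)) for rng in rngs])
        else:
            noise = None
        for j in range(m):
            fx = x / (1.0 + x)  # x >= 0 always holds after rectification
            s = fx.sum(axis=1, keepdims=True)
            dx = -lam * x + alpha * fx - beta * (s - fx)
            if t + j < presentation_steps:
                dx = dx + drive
            if noise is not None:
                dx = dx + noise[:, j, :]
            x += dt * dx
            np.maximum(x, 0.0, out=x)
            if t + j >= total - window:
                ma_acc += x.mean(axis=1)
        t += m
    ma = (ma_acc / window).reshape(conds, runs)
    return ma


def simulate_run(
    params: NetworkParams,
    stim: StimulusSpec,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[NetworkState, float]:
    """Single run from the all-zero state; returns final state and readout.

    The stimulus current is applied for ``stim.presentation_steps`` steps,
    then switched off; fresh noise is drawn every step from ``rng`` (or
    from the run-0 stream of ``config.seed`` if none is given).  The
    readout is the mean activation of the final state, averaged over the
    trailing ``config.steady_window`` steps when that is larger than 1.
    """
    idx = stim.resolve_indices(params.n_nodes)
    n = params.n_nodes
    if rng is None:
        rng = np.random.default_rng(
            run_seed_sequence(config.seed, stim.set_size, params.beta, 0)
        )
    drive_on = np.zeros(n)
    for i in idx:
        drive_on[i] = stim.input_current
    drive_off = np.zeros(n)
    state = NetworkState(activations=np.zeros(n), t=0)
    window = config.steady_window
    ma_acc = 0.0
    for t in range(config.total_steps):
        drive = drive_on if t < stim.presentation_steps else drive_off
        if params.noise_sd > 0:
            noise = rng.normal(0.0, params.noise_sd, size=n)
        else:
            noise = np.zeros(n)
        state = euler_step(state, params, drive, noise, dt=config.dt)
        if t >= config.total_steps - window:
            ma_acc += mean_activation(state)
    return state, ma_acc / window


def ensemble_mean_activation(
    params: NetworkParams,
    stim: StimulusSpec,
    config: SimulationConfig,
) -> Tuple[float, float]:
    """Mean and sd of the steady-state readout over ``n_runs`` runs.

    Runs draw noise from independent per-run streams derived from
    ``config.seed``, so the result is deterministic for a given seed and
    identical whether runs are executed singly or batched.
    """
    idx = stim.resolve_indices(params.n_nodes)
    ma = _simulate_batch(
        params,
        [stim.set_size],
        config,
        presentation_steps=stim.presentation_steps,
        input_current=stim.input_current,
        node_index_lists=[idx],
    )[0]
    sd = float(ma.std(ddof=1)) if config.n_runs > 1 else 0.0
    return float(ma.mean()), sd


def analytic_fixed_point(
    k: int, params: NetworkParams, rectified: bool = True
) -> Tuple[float, float]:
    """Noise-free symmetric steady state with ``k`` co-active units.

    Solves ``lam * x = (alpha - beta*(k-1)) * F(x)`` for the active units:
    ``x_active = (alpha - beta*(k-1))/lam - 1`` when that gain exceeds the
    decay, else 0 (the active state cannot sustain itself).  With
    ``rectified`` (default) the silent units rest at 0, matching the
    simulated dynamics; with ``rectified=False`` the silent units take the
    unconstrained linear balance ``-beta * k * F(x_active) / lam``.
    """
    if not 0 <= k <= params.n_nodes:
        raise ValueError(f"k must be in [0, {params.n_nodes}], got {k}")
    if k == 0:
        return 0.0, 0.0
    gain = params.alpha - params.beta * (k - 1)
    if gain > params.lam:
        x_active = gain / params.lam - 1.0
    else:
        x_active = 0.0
    if rectified:
        x_inactive = 0.0
    else:
        x_inactive = -params.beta * k * activation(x_active) / params.lam
    return x_active, x_inactive


def predicted_mean_activation(k: int, params: NetworkParams) -> float:
    """Noise-free MA of the symmetric k-winner state (rectified model)."""
    x_active, x_inactive = analytic_fixed_point(k, params)
    n = params.n_nodes
    return (k * x_active + (n - k) * x_inactive) / n


def default_params(beta: float = 0.01, **overrides) -> NetworkParams:
    """The standard 64-unit network at a given inhibition strength."""
    return replace(NetworkParams(beta=beta), **overrides)
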