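"""Ensemble ODE/SDE simulation of gene circuits with random kinetics.

Gene expression snapshots are generated in the random-circuit-perturbation
(RACIPE) style: for a signed topology, an ensemble of ODE models is drawn
with kinetic parameters sampled uniformly from wide ranges, and each model
is integrated from a random initial condition. The resulting steady (or
late-time) states mimic the cell-to-cell heterogeneity of single-cell
transcriptomics.

The rate law for a target gene A with regulators B_i is

    dA/dt = (G_A / Π_act λ_i) · Π_i H(B_i; B0_i, n_i, λ_i) − k_A · A

where H is the shifted Hill function ``λ + (1−λ)/(1 + (B/B0)^n)``: it runs
from 1 at B = 0 to λ as B → ∞, so λ > 1 encodes activation and λ < 1
inhibition. The prefactor divides G by λ over the *activating* in-edges
only, so that G is the maximum production rate — reached under full
activation and absent inhibition (an inhibitory factor already peaks at 1
when its regulator is off). Stochastic trajectories add Gaussian white noise per gene
(Euler–Maruyama, states clipped at zero), optionally with a time-varying
production multiplier on one gene (a signal schedule) or an explicit
unspliced/spliced mRNA split with a constant splicing rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn import GRNTopology
from .matrix import ExpressionMatrix, apply_dropout, normalize_log, zscore

__all__ = [
    "KineticParameters",
    "SimulationConfig",
    "SignalSchedule",
    "Trajectory",
    "sample_parameters",
    "shifted_hill",
    "derivative",
    "simulate_steady_states",
    "simulate_trajectory_sde",
    "simulate_with_splicing",
    "ExpressionMatrix",
    "normalize_log",
    "zscore",
    "apply_dropout",
]

DEFAULT_SPLICING_RATE = 0.7


@dataclass
class ParameterRanges:
    """Sampling ranges for random kinetic parameters (RACIPE convention)."""

    production: tuple[float, float] = (1.0, 100.0)
    degradation: tuple[float, float] = (0.1, 1.0)
    hill_range: tuple[int, int] = (1, 6)
    fold_change: tuple[float, float] = (1.0, 100.0)
    threshold_spread: tuple[float, float] = (0.02, 1.98)


@dataclass
class KineticParameters:
    """Kinetic parameters for one or more models of a fixed topology.

    All arrays carry a leading model axis: ``production`` and
    ``degradation`` are (n_models, n_genes); ``fold_change``, ``hill`` and
    ``threshold`` are (n_models, n_edges), aligned with the topology's edge
    order. ``fold_change`` is > 1 on activating edges and in (0, 1) on
    inhibiting ones.
    """

    genes: list[str]
    production: np.ndarray
    degradation: np.ndarray
    fold_change: np.ndarray
    hill: np.ndarray
    threshold: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.production <= 0) or np.any(self.degradation <= 0):
            raise ValueError("production and degradation rates must be positive")
        if np.any(self.fold_change <= 0):
            raise ValueError("fold changes must be positive")
        if np.any(self.hill < 1):
            raise ValueError("Hill coefficients must be >= 1")
        if self.threshold.size and np.any(self.threshold <= 0):
            raise ValueError("regulation thresholds must be positive")

    @property
    def n_models(self) -> int:
        return self.production.shape[0]

    def model(self, i: int) -> "KineticParameters":
        """Single-model view (model axis kept, length 1)."""
        return KineticParameters(
            genes=self.genes,
            production=self.production[i : i + 1],
            degradation=self.degradation[i : i + 1],
            fold_change=self.fold_change[i : i + 1],
            hill=self.hill[i : i + 1],
            threshold=self.threshold[i : i + 1],
        )


@dataclass
class SimulationConfig:
    """Knobs for ensemble and trajectory simulation.

    ``noise_level`` is the dimensionless amplitude multiplying the per-gene
    expression scale in the SDE; ``print_interval`` is the recording spacing
    of trajectories (0 means steady state only). All time quantities share
    the model's arbitrary time unit (degradation rates are 0.1–1 per unit).
    """

    n_models: int = 2000
    noise_level: float = 0.0
    step_size: float = 0.02
    total_time: float = 100.0
    print_interval: float = 0.0
    seed: int = 0
    convergence_tol: float = 1e-6
    ranges: ParameterRanges = field(default_factory=ParameterRanges)

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.total_time < self.step_size:
            raise ValueError("total_time must be at least one step")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")


@dataclass
class SignalSchedule:
    """Trapezoidal production multiplier s(t) applied to one gene.

    s rises linearly from 1 to ``fold`` over [0, t_rise], holds at ``fold``
    for ``t_hold`` time units, decays linearly back to 1 over ``t_fall``,
    and is 1 afterwards.
    """

    target_gene: str
    fold: float
    t_rise: float
    t_hold: float
    t_fall: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("signal fold must be >= 1")
        if min(self.t_rise, self.t_hold, self.t_fall) < 0:
            raise ValueError("signal phase durations must be non-negative")

    def value(self, t: float) -> float:
        if t < 0:
            return 1.0
        if t < self.t_rise:
            return 1.0 + (self.fold - 1.0) * (t / self.t_rise if self.t_rise else 1.0)
        t -= self.t_rise
        if t < self.t_hold:
            return self.fold
        t -= self.t_hold
        if t < self.t_fall:
            return self.fold - (self.fold - 1.0) * (t / self.t_fall)
        return 1.0


@dataclass
class Trajectory:
    """Time-ordered states of a single model.

    ``states`` is (n_times, n_genes); for splicing simulations ``unspliced``
    holds the companion track and ``states`` the spliced (regulating) one.
    """

    times: np.ndarray
    states: np.ndarray
    genes: list[str]
    params: KineticParameters
    unspliced: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.genes)
        df.insert(0, "time", self.times)
        if self.unspliced is not None:
            for i, g in enumerate(self.genes):
                df[f"{g}_unspliced"] = self.unspliced[:, i]
        return df

    def to_expression(self, stride: int = 1, scale: str = "raw") -> ExpressionMatrix:
        """View snapshots of the trajectory as an expression matrix."""
        states = self.states[::stride]
        idx = [f"t{i}" for i in range(states.shape[0])]
        return ExpressionMatrix(
            pd.DataFrame(np.maximum(states, 0.0), index=idx, columns=self.genes),
            scale=scale,
        )


def sample_parameters(
    topology: GRNTopology,
    seed: int | np.random.Generator | None = None,
    n_models: int = 1,
    ranges: ParameterRanges | None = None,
) -> KineticParameters:
    """Draw random kinetic parameters for ``n_models`` models.

    Marginals follow the RACIPE convention: production G ~ U[1, 100],
    degradation k ~ U[0.1, 1], Hill coefficient n uniform on {1..6},
    fold change λ ~ U[1, 100] for activations and 1/U[1, 100] for
    inhibitions, and each edge's threshold ~ U[0.02·M, 1.98·M] around the
    regulator's half-maximal level M = G/(2k) in that model (the
    half-functional rule).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = ranges or ParameterRanges()
    ng, ne = topology.n_genes, topology.n_edges
    G = rng.uniform(*r.production, size=(n_models, ng))
    k = rng.uniform(*r.degradation, size=(n_models, ng))
    n_hill = rng.integers(r.hill_range[0], r.hill_range[1] + 1, size=(n_models, ne))
    fold = rng.uniform(*r.fold_change, size=(n_models, ne))
    src, _tgt, sgn = topology.edge_arrays()
    sgn = np.asarray(sgn)
    lam = np.where(sgn[None, :] == 1, fold, 1.0 / fold) if ne else fold
    # Half-functional threshold: centred on the regulator's M = G/(2k).
    if ne:
        M = G[:, src] / (2.0 * k[:, src])
        thr = rng.uniform(r.threshold_spread[0], r.threshold_spread[1], size=(n_models, ne)) * M
    else:
        thr = np.empty((n_models, 0))
    return KineticParameters(
        genes=list(topology.genes),
        production=G,
        degradation=k,
        fold_change=lam,
        hill=n_hill.astype(float),
        threshold=thr,
    )


def shifted_hill(B, B0, n, lam):
    """Shifted Hill regulation factor λ + (1−λ) / (1 + (B/B0)^n).

    Equals 1 at B = 0 and tends to λ as B ≫ B0; at B = B0 it is (1+λ)/2.
    Accepts scalars or broadcastable arrays.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("regulator level must be non-negative")
    if np.any(np.asarray(B0) <= 0):
        raise ValueError("threshold must be positive")
    if np.any(np.asarray(n) < 1):
        raise ValueError("Hill coefficient must be >= 1")
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("fold change must be positive")
    ratio = (B / B0) ** n
    return lam + (1.0 - lam) / (1.0 + ratio)


class _CompiledCircuit:
    """Edge bookkeeping for vectorized rate evaluation."""

    def __init__(self, topology: GRNTopology, params: KineticParameters):
        if list(topology.genes) != list(params.genes):
            raise ValueError("parameter gene order does not match topology")
        self.topology = topology
        src, tgt, sgn = topology.edge_arrays()
        self.src = np.asarray(src, dtype=int)
        self.tgt = np.asarray(tgt, dtype=int)
        self.sgn = np.asarray(sgn, dtype=int)
        self.params = params
        ng = topology.n_genes
        # G is the MAXIMUM production rate: divide by λ over activating
        # in-edges (whose shifted Hill saturates at λ > 1) so that full
        # activation yields G. Inhibitory factors already peak at 1.
        lam_prod = np.ones((params.n_models, ng))
        for e, t in enumerate(self.tgt):
            if self.sgn[e] == 1:
                lam_prod[:, t] *= params.fold_change[:, e]
        self.base_rate = params.production / lam_prod

    def production(self, state: np.ndarray) -> np.ndarray:
        """Production term (n_models × n_genes) at the given state."""
        p = self.base_rate.copy()
        if self.src.size:
            B = state[:, self.src]
            H = shifted_hill(
                np.maximum(B, 0.0),
                self.params.threshold,
                self.params.hill,
                self.params.fold_change,
            )
            for e, t in enumerate(self.tgt):
                p[:, t] *= H[:, e]
        return p


def derivative(
    state: np.ndarray,
    topology: GRNTopology,
    params: KineticParameters,
    signal: SignalSchedule | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """Deterministic rates dA/dt at ``state`` ((n_models, n_genes) or (n_genes,))."""
    state = np.atleast_2d(np.asarray(state, dtype=float))
    if np.any(state < 0):
        raise ValueError("state must be non-negative")
    circuit = _CompiledCircuit(topology, params)
    return _derivative_compiled(circuit, state, signal, t)


def _signal_multiplier(
    circuit: _CompiledCircuit, signal: SignalSchedule | None, t: float
) -> np.ndarray | float:
    if signal is None:
        return 1.0
    if signal.target_gene not in circuit.topology.genes:
        raise KeyError(f"signal target {signal.target_gene!r} not in topology")
    s = np.ones(circuit.topology.n_genes)
    s[circuit.topology.gene_index()[signal.target_gene]] = signal.value(t)
    return s


def _derivative_compiled(circuit, state, signal, t):
    s = _signal_multiplier(circuit, signal, t)
    return s * circuit.production(state) - circuit.params.degradation * state


def _euler_ensemble(circuit, state, config, signal=None, t0=0.0):
    """Fixed-step Euler to t0 + total_time; returns final state."""
    h = config.step_size
    n_steps = int(round(config.total_time / h))
    for step in range(n_steps):
        rate = _derivative_compiled(circuit, state, signal, t0 + step * h)
        state = np.maximum(state + h * rate, 0.0)
    return state


def simulate_steady_states(
    topology: GRNTopology,
    config: SimulationConfig,
    signal: SignalSchedule | None = None,
    initial_states: np.ndarray | None = None,
    params: KineticParameters | None = None,
) -> ExpressionMatrix:
    """RACIPE-style snapshot ensemble: one late-time state per random model.

    For each model, parameters are sampled (unless supplied), the initial
    condition is drawn uniformly in [0, G/k] per gene, and the ODE is
    integrated with fixed-step Euler to ``total_time``. Each row of the
    returned raw matrix is one model's final state; a per-model convergence
    flag (max |dA/dt| below ``convergence_tol``) is attached — oscillatory
    models legitimately never converge and are retained. Models whose state
    blows up to non-finite values are dropped with a warning.
    """
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = sample_parameters(topology, rng, n_models=config.n_models)
    circuit = _CompiledCircuit(topology, params)
    cap = params.production / params.degradation
    if initial_states is None:
        state = rng.uniform(0.0, 1.0, size=cap.shape) * cap
    else:
        state = np.array(initial_states, dtype=float)
        if state.shape != cap.shape:
            raise ValueError("initial_states shape must be (n_models, n_genes)")
    state = _euler_ensemble(circuit, state, config, signal)
    ok = np.all(np.isfinite(state), axis=1)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} model(s) with non-finite states")
        state = state[ok]
        params_kept = ok
    else:
        params_kept = np.ones(state.shape[0], dtype=bool)
    t_end = config.total_time
    rate = _derivative_compiled(
        _CompiledCircuit(topology, _mask_params(params, params_kept)),
        state,
        signal,
        t_end,
    )
    converged = np.max(np.abs(rate), axis=1) < config.convergence_tol
    idx = [f"model_{i}" for i in np.nonzero(params_kept)[0]]
    df = pd.DataFrame(state, index=idx, columns=topology.genes)
    return ExpressionMatrix(df, scale="raw", converged=converged)


def _mask_params(params: KineticParameters, mask: np.ndarray) -> KineticParameters:
    if mask.all():
        return params
    return KineticParameters(
        genes=params.genes,
        production=params.production[mask],
        degradation=params.degradation[mask],
        fold_change=params.fold_change[mask],
        hill=params.hill[mask],
        threshold=params.threshold[mask],
    )


def _trajectory_noise_scale(
    topology: GRNTopology, params: KineticParameters, config: SimulationConfig
) -> np.ndarray:
    """Per-gene noise scale: time-averaged expression of a deterministic run.

    The SDE noise amplitude is specified relative to each gene's typical
    expression; here that is the mean over the second half of a
    deterministic trajectory of the same model (which averages over a limit
    cycle when there is one).
    """
    circuit = _CompiledCircuit(topology, params)
    h = config.step_size
    n_steps = int(round(config.total_time / h))
    state = params.production / params.degradation * 0.5
    acc = np.zeros_like(state)
    n_acc = 0
    for step in range(n_steps):
        rate = _derivative_compiled(circuit, state, None, step * h)
        state = np.maximum(state + h * rate, 0.0)
        if step >= n_steps // 2:
            acc += state
            n_acc += 1
    return np.maximum(acc / max(n_acc, 1), 1e-12)


def simulate_trajectory_sde(
    topology: GRNTopology,
    params: KineticParameters,
    config: SimulationConfig,
    signal: SignalSchedule | None = None,
    initial_state: np.ndarray | None = None,
    noise_scale: np.ndarray | None = None,
) -> Trajectory:
    """Euler–Maruyama trajectory of a single model.

    Each step applies ``A += f(A)·h + ξ_A·√h·N(0,1)`` with the state clipped
    at zero; the per-gene amplitude ξ_A is ``noise_level`` times a per-gene
    expression scale (``noise_scale`` if supplied, otherwise the
    deterministic time-average of the same model). States are recorded every
    ``print_interval`` time units. With ``noise_level = 0`` this reduces
    exactly to deterministic Euler integration.
    """
    if params.n_models != 1:
        raise ValueError("trajectory simulation expects a single model; use .model(i)")
    if config.print_interval <= 0:
        raise ValueError("print_interval must be positive for trajectories")
    rng = np.random.default_rng(config.seed)
    circuit = _CompiledCircuit(topology, params)
    if config.noise_level > 0:
        if noise_scale is None:
            noise_scale = _trajectory_noise_scale(topology, params, config)
        xi = config.noise_level * np.asarray(noise_scale, dtype=float).reshape(1, -1)
    else:
        xi = None
    cap = params.production / params.degradation
    if initial_state is None:
        state = rng.uniform(0.0, 1.0, size=cap.shape) * cap
    else:
        state = np.array(initial_state, dtype=float).reshape(cap.shape)
    h = config.step_size
    sqrt_h = np.sqrt(h)
    n_steps = int(round(config.total_time / h))
    record_every = max(int(round(config.print_interval / h)), 1)
    times = [0.0]
    states = [state[0].copy()]
    for step in range(1, n_steps + 1):
        t = (step - 1) * h
        rate = _derivative_compiled(circuit, state, signal, t)
        state = state + h * rate
        if xi is not None:
            state = state + xi * sqrt_h * rng.standard_normal(state.shape)
        state = np.maximum(state, 0.0)
        if not np.all(np.isfinite(state)):
            warnings.warn("trajectory diverged to non-finite values; truncating")
            break
        if step % record_every == 0:
            times.append(step * h)
            states.append(state[0].copy())
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        genes=list(topology.genes),
        params=params,
    )


def simulate_with_splicing(
    topology: GRNTopology,
    params: KineticParameters,
    config: SimulationConfig,
    beta: float = DEFAULT_SPLICING_RATE,
    initial_state: np.ndarray | None = None,
    noise_scale: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory with an explicit unspliced/spliced mRNA split.

    Unspliced transcripts are produced at the regulated rate and convert to
    spliced ones at constant rate ``beta``; spliced transcripts degrade at
    the gene's rate k and are the species read by regulators:

        dU/dt = production(S) − β·U,   dS/dt = β·U − k·S.

    At a stationary point of an isolated gene, U* = G/β and S* = G/k. As
    β → ∞ the spliced track approaches the model without splicing. Noise,
    when enabled, is applied to both tracks with the same per-gene scale.
    """
    if beta <= 0:
        raise ValueError("splicing rate beta must be positive")
    if params.n_models != 1:
        raise ValueError("trajectory simulation expects a single model; use .model(i)")
    if config.print_interval <= 0:
        raise ValueError("print_interval must be positive for trajectories")
    rng = np.random.default_rng(config.seed)
    circuit = _CompiledCircuit(topology, params)
    if config.noise_level > 0:
        if noise_scale is None:
            noise_scale = _trajectory_noise_scale(topology, params, config)
        xi = config.noise_level * np.asarray(noise_scale, dtype=float).reshape(1, -1)
    else:
        xi = None
    cap = params.production / params.degradation
    if initial_state is None:
        spliced = rng.uniform(0.0, 1.0, size=cap.shape) * cap
    else:
        spliced = np.array(initial_state, dtype=float).reshape(cap.shape)
    unspliced = spliced * params.degradation / beta  # start near splicing balance
    h = config.step_size
    sqrt_h = np.sqrt(h)
    n_steps = int(round(config.total_time / h))
    record_every = max(int(round(config.print_interval / h)), 1)
    times = [0.0]
    s_states = [spliced[0].copy()]
    u_states = [unspliced[0].copy()]
    for step in range(1, n_steps + 1):
        prod = circuit.production(spliced)
        dU = prod - beta * unspliced
        dS = beta * unspliced - params.degradation * spliced
        unspliced = unspliced + h * dU
        spliced = spliced + h * dS
        if xi is not None:
            unspliced = unspliced + xi * sqrt_h * rng.standard_normal(spliced.shape)
            spliced = spliced + xi * sqrt_h * rng.standard_normal(spliced.shape)
        unspliced = np.maximum(unspliced, 0.0)
        spliced = np.maximum(spliced, 0.0)
        if step % record_every == 0:
            times.append(step * h)
            s_states.append(spliced[0].copy())
            u_states.append(unspliced[0].copy())
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(s_states),
        genes=list(topology.genes),
        params=params,
        unspliced=np.asarray(u_states),
    )
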