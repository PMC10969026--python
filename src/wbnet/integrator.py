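"""Fixed-step stochastic simulation of the coupled network.

The network is advanced with classic fourth-order Runge-Kutta at step
``h = 1/fs``.  The external input is Gaussian pulse density noise,
sampled once per region per step and held constant across the four RK4
stages of that step (piecewise-constant drive, the convention the
single-node model is usually simulated with; ``sigma2`` is the variance
of these per-step samples, with no step-size rescaling).

Randomness is organised so that every (seed, repetition, region) triple
owns an independent, reproducible stream: repetition r of a run seeds a
``SeedSequence([seed, r])`` whose first child drives the random initial
conditions and whose remaining N children drive the per-region noise.
A single-region simulation fed one of those streams therefore
reproduces the corresponding region of an uncoupled network run
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import numpy.typing as npt

from .model import N_STATE, CoupledSystem, network_derivatives, node_output

__all__ = [
    "SimulationConfig",
    "RegionTimeSeries",
    "IntegrationDivergenceError",
    "simulate",
    "simulate_repetitions",
]


class IntegrationDivergenceError(RuntimeError):
    """The trajectory left the finite range (e.g. coupling too strong)."""

    def __init__(self, step: int, time: float, regions: list[int], rep: int | None = None):
        self.step = step
        self.time = time
        self.regions = regions
        self.rep = rep
        where = f" in repetition {rep}" if rep is not None else ""
        super().__init__(
            f"integration diverged at step {step} (t = {time:.4f} s) "
            f"in region(s) {regions}{where}"
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol of one simulation experiment.

    fs : sampling rate (Hz); the RK4 step is 1/fs.
    duration : total simulated time (s).
    transient : leading stretch discarded to forget initial values (s).
    n_reps : repetitions with different initial values and noise.
    seed : master seed; all streams derive from (seed, repetition).
    init_scale : initial state components are uniform on [0, init_scale] (mV).
    """

    fs: float = 1000.0
    duration: float = 2.0
    transient: float = 1.0
    n_reps: int = 20
    seed: int = 0
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not (0 <= self.transient < self.duration):
            raise ValueError("need 0 <= transient < duration")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.init_scale < 0:
            raise ValueError("init_scale must be >= 0")

    @property
    def n_steps(self) -> int:
        return round(self.duration * self.fs)

    @property
    def n_transient(self) -> int:
        return round(self.transient * self.fs)

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class RegionTimeSeries:
    """Post-transient pyramidal output of every region.

    values : (N, T) array of y_out in mV.
    fs : sampling rate (Hz).
    t0 : time of the first retained sample (s).
    labels : region labels.
    """

    values: npt.NDArray[np.float64]
    fs: float
    t0: float = 0.0
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (regions x time) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series values must be finite")
        labels = tuple(self.labels) if self.labels else tuple(
            f"R{i + 1:03d}" for i in range(v.shape[0])
        )
        if len(labels) != v.shape[0]:
            raise ValueError("label count does not match region count")
        object.__setattr__(self, "labels", labels)
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


def _streams(seed: int, rep: int, n_regions: int):
    """(initial-condition generator, list of per-region noise generators)."""
    children = np.random.SeedSequence([int(seed), int(rep)]).spawn(n_regions + 1)
    ic_rng = np.random.default_rng(children[0])
    noise_rngs = [np.random.default_rng(c) for c in children[1:]]
    return ic_rng, noise_rngs


def draw_noise(
    config: SimulationConfig,
    n_regions: int,
    mu: float,
    sigma2: float,
    rep: int = 0,
) -> npt.NDArray[np.float64]:
    """Per-step external input samples p_i(t) ~ N(mu, sigma2), shape
    (n_steps, N); column i comes from region i's private stream."""
    _, noise_rngs = _streams(config.seed, rep, n_regions)
    sd = float(np.sqrt(sigma2))
    p = np.empty((config.n_steps, n_regions))
    for i, rng in enumerate(noise_rngs):
        p[:, i] = rng.normal(mu, sd, config.n_steps)
    return p


def _make_deriv(system: CoupledSystem):
    """Build an unchecked vector-field evaluator for the hot loop.

    Operation-for-operation identical to
    :func:`wbnet.model.network_derivatives` (asserted in the test
    suite), with parameter products hoisted out of the loop and input
    validation dropped; non-finite values are caught once per step by
    the integrator instead.
    """
    prm = system.params
    A, B, G, a, b, g = prm.A, prm.B, prm.G, prm.a, prm.b, prm.g
    C1, C2, C3, C4, C5, C6, C7 = (
        prm.C1, prm.C2, prm.C3, prm.C4, prm.C5, prm.C6, prm.C7
    )
    e2, r, v0 = 2.0 * prm.e0, prm.r, prm.v0
    w_t = system.connectome.weights.T
    cg = system.c_global
    from scipy.special import expit

    def deriv(y: np.ndarray, p: np.ndarray) -> np.ndarray:
        y0, y4 = y[:, 0], y[:, 4]
        s_pyr = e2 * expit(r * ((y[:, 1] - y[:, 2] - y[:, 3]) - v0))
        coupling = cg * (s_pyr @ w_t)
        dy = np.empty_like(y)
        dy[:, :5] = y[:, 5:]
        dy[:, 5] = A * a * s_pyr - 2.0 * a * y[:, 5] - a * a * y0
        dy[:, 6] = (
            A * a * (p + coupling + C2 * (e2 * expit(r * (C1 * y0 - v0))))
            - 2.0 * a * y[:, 6]
            - a * a * y[:, 1]
        )
        s_slow = e2 * expit(r * (C3 * y0 - v0))
        dy[:, 7] = B * b * C4 * s_slow - 2.0 * b * y[:, 7] - b * b * y[:, 2]
        dy[:, 8] = (
            G * g * C7 * (e2 * expit(r * ((C5 * y0 - y4) - v0)))
            - 2.0 * g * y[:, 8]
            - g * g * y[:, 3]
        )
        dy[:, 9] = B * b * C6 * s_slow - 2.0 * b * y[:, 9] - b * b * y4
        return dy

    return deriv


def _rk4(
    y: npt.NDArray[np.float64],
    system: CoupledSystem,
    noise: npt.NDArray[np.float64],
    h: float,
    n_transient: int,
    rep: int | None = None,
) -> npt.NDArray[np.float64]:
    """Integrate and return the retained (post-transient) output samples."""
    n_steps = noise.shape[0]
    n = system.n_regions
    deriv = _make_deriv(system)
    out = np.empty((n_steps - n_transient, n))
    k = 0
    for step in range(n_steps):
        p = noise[step]
        with np.errstate(over="ignore", invalid="ignore"):
            k1 = deriv(y, p)
            k2 = deriv(y + 0.5 * h * k1, p)
            k3 = deriv(y + 0.5 * h * k2, p)
            k4 = deriv(y + h * k3, p)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)):
            bad = np.where(~np.isfinite(y).all(axis=-1))[0]
            raise IntegrationDivergenceError(step + 1, (step + 1) * h, bad.tolist(), rep)
        if step >= n_transient:
            out[k] = node_output(y)
            k += 1
    return out


def simulate(
    system: CoupledSystem,
    config: SimulationConfig,
    rep: int = 0,
    *,
    initial_state: npt.NDArray[np.float64] | None = None,
    noise: npt.NDArray[np.float64] | None = None,
) -> RegionTimeSeries:
    """Run one repetition and return the post-transient output series.

    ``initial_state`` (N, 10) and ``noise`` (n_steps, N) override the
    seed-derived draws; they exist for matched-stream experiments
    (e.g. comparing a coupled network at c_global = 0 against
    independent single-region runs).
    """
    n = system.n_regions
    ic_rng, _ = _streams(config.seed, rep, n)
    y0 = ic_rng.uniform(0.0, config.init_scale, size=(n, N_STATE))
    if initial_state is not None:
        y0 = np.array(initial_state, dtype=float)
        if y0.shape != (n, N_STATE):
            raise ValueError(f"initial_state must have shape ({n}, {N_STATE})")
    if noise is None:
        noise = draw_noise(config, n, system.params.mu, system.params.sigma2, rep)
    else:
        noise = np.asarray(noise, dtype=float)
        if noise.shape != (config.n_steps, n):
            raise ValueError(f"noise must have shape ({config.n_steps}, {n})")

    h = 1.0 / config.fs
    values = _rk4(y0, system, noise, h, config.n_transient, rep)
    return RegionTimeSeries(
        values=values.T,
        fs=config.fs,
        t0=(config.n_transient + 1) * h,
        labels=system.connectome.labels,
    )


def simulate_repetitions(
    system: CoupledSystem, config: SimulationConfig
) -> list[RegionTimeSeries]:
    """All ``config.n_reps`` repetitions, each from its own (seed, rep)
    substream and individually reproducible via ``simulate(..., rep=r)``."""
    return [simulate(system, config, rep=r) for r in range(config.n_reps)]


def initial_state(system: CoupledSystem, config: SimulationConfig, rep: int = 0):
    """The seed-derived random initial state of a given repetition."""
    ic_rng, _ = _streams(config.seed, rep, system.n_regions)
    return ic_rng.uniform(0.0, config.init_scale, size=(system.n_regions, N_STATE))
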