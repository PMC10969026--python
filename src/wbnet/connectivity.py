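"""Phase-locking-value functional connectivity and global-coupling fitting.

The phase of each region's output is extracted with the Hilbert
transform; the phase-locking value between regions i and j is the
modulus of the time-averaged unit phasor of their phase difference,

    rho_ij = | (1/T) sum_t exp(i (theta_i(t) - theta_j(t))) |,

equal to 1 for a constant phase difference and near 1/sqrt(T) for
independent phases.  Simulated and reference FC matrices are compared
by the Pearson correlation of their strictly-lower-triangle entries,
and the global coupling coefficient is fitted by sweeping a grid and
taking the argmax of that correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.stats import pearsonr

from .connectome import ConnectomeMatrix
from .integrator import (
    IntegrationDivergenceError,
    RegionTimeSeries,
    SimulationConfig,
    simulate_repetitions,
)
from .model import CoupledSystem
from .params import WendlingParams

__all__ = [
    "PhaseMatrix",
    "FCMatrix",
    "CouplingSweepResult",
    "DegenerateSignalError",
    "instantaneous_phase",
    "plv",
    "fc_matrix",
    "fc_from_phases",
    "average_fc",
    "fc_similarity",
    "inclusive_grid",
    "sweep_coupling",
]


class DegenerateSignalError(ValueError):
    """A region's signal is (numerically) constant; its phase is undefined."""


@dataclass(frozen=True)
class PhaseMatrix:
    """Instantaneous phases theta_i(t) in radians, shape (N, T)."""

    theta: npt.NDArray[np.float64]
    fs: float

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", th)
        if th.ndim != 2:
            raise ValueError("theta must be 2-D (regions x time)")
        if not np.all(np.isfinite(th)):
            raise ValueError("phases must be finite")

    @property
    def n_regions(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric PLV functional-connectivity matrix with unit diagonal."""

    rho: npt.NDArray[np.float64]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "rho", r)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError(f"FC matrix must be square, got {r.shape}")
        n = r.shape[0]
        labels = tuple(self.labels) if self.labels else tuple(
            f"R{i + 1:03d}" for i in range(n)
        )
        if len(labels) != n:
            raise ValueError("label count does not match FC size")
        object.__setattr__(self, "labels", labels)
        if not np.all(np.isfinite(r)):
            raise ValueError("FC entries must be finite")
        if not np.array_equal(r, r.T):
            raise ValueError("FC matrix must be symmetric")
        if np.any(np.diag(r) != 1.0):
            raise ValueError("FC diagonal must be 1 by convention")
        if r.min() < 0 or r.max() > 1:
            raise ValueError("PLV entries must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.rho.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a flat vector."""
        i, j = np.tril_indices(self.n_regions, k=-1)
        return self.rho[i, j]


@dataclass(frozen=True)
class CouplingSweepResult:
    """PCC-vs-C curve of a global-coupling sweep and its optimum.

    Grid points where the simulation diverged carry NaN in
    ``pcc_values`` and are excluded from the argmax.
    """

    c_values: npt.NDArray[np.float64]
    pcc_values: npt.NDArray[np.float64]
    best_c: float
    best_pcc: float

    def __post_init__(self) -> None:
        c = np.asarray(self.c_values, dtype=float)
        p = np.asarray(self.pcc_values, dtype=float)
        object.__setattr__(self, "c_values", c)
        object.__setattr__(self, "pcc_values", p)
        if c.shape != p.shape:
            raise ValueError("c_values and pcc_values must have equal length")
        finite = p[np.isfinite(p)]
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("PCC values must lie in [-1, 1]")


def _bandpass_sos(band: tuple[float, float], fs: float):
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} must lie inside (0, fs/2) = (0, {fs / 2})")
    return butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def instantaneous_phase(
    series: RegionTimeSeries, band: tuple[float, float] | None = None
) -> PhaseMatrix:
    """Hilbert-transform phase of each region's (demeaned) output.

    An optional zero-phase band-pass (4th-order Butterworth, forward
    and backward) can be applied first; by default the broadband signal
    is used.  A numerically constant region raises
    :class:`DegenerateSignalError`.
    """
    x = series.values
    if x.shape[1] < 16:
        raise ValueError("need at least 16 samples for a meaningful phase estimate")
    x = x - x.mean(axis=1, keepdims=True)
    scale = np.max(np.abs(series.values), axis=1)
    degenerate = np.max(np.abs(x), axis=1) <= 1e-12 * np.maximum(scale, 1.0)
    if np.any(degenerate):
        bad = [series.labels[i] for i in np.where(degenerate)[0]]
        raise DegenerateSignalError(
            f"constant signal, phase undefined for region(s) {bad}"
        )
    if band is not None:
        x = sosfiltfilt(_bandpass_sos(band, series.fs), x, axis=1)
    theta = np.angle(hilbert(x, axis=1))
    return PhaseMatrix(theta=theta, fs=series.fs)


def plv(phases: PhaseMatrix, i: int, j: int) -> float:
    """Phase-locking value between regions i and j, in [0, 1]."""
    n = phases.n_regions
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"region indices ({i}, {j}) out of range for N={n}")
    d = phases.theta[i] - phases.theta[j]
    return float(np.abs(np.exp(1j * d).mean()))


def fc_from_phases(phases: PhaseMatrix, labels: tuple[str, ...] = ()) -> FCMatrix:
    """All pairwise PLVs from a phase matrix (vectorised complex product)."""
    z = np.exp(1j * phases.theta)
    t = phases.theta.shape[1]
    r = np.abs(z @ z.conj().T) / t
    # enforce exact symmetry and the diagonal/range conventions
    iu = np.triu_indices(phases.n_regions, k=1)
    rho = np.zeros_like(r)
    rho[iu] = np.clip(r[iu], 0.0, 1.0)
    rho = rho + rho.T
    np.fill_diagonal(rho, 1.0)
    return FCMatrix(rho=rho, labels=labels)


def fc_matrix(
    series: RegionTimeSeries, band: tuple[float, float] | None = None
) -> FCMatrix:
    """PLV functional-connectivity matrix of a simulated series."""
    if series.n_regions < 2:
        raise ValueError("need at least 2 regions for an FC matrix")
    phases = instantaneous_phase(series, band=band)
    return fc_from_phases(phases, labels=series.labels)


def average_fc(fcs: list[FCMatrix]) -> FCMatrix:
    """Element-wise mean of FC matrices (e.g. across repetitions)."""
    if not fcs:
        raise ValueError("average_fc needs at least one matrix")
    n = fcs[0].n_regions
    for fc in fcs[1:]:
        if fc.n_regions != n:
            raise ValueError("FC matrices must share one shape")
    mean = np.mean([fc.rho for fc in fcs], axis=0)
    np.fill_diagonal(mean, 1.0)
    mean = np.clip((mean + mean.T) / 2.0, 0.0, 1.0)
    return FCMatrix(rho=mean, labels=fcs[0].labels)


def fc_similarity(sim: FCMatrix, ref: FCMatrix) -> float:
    """Pearson correlation of the strictly-lower-triangle entries."""
    if sim.n_regions != ref.n_regions:
        raise ValueError("FC matrices differ in size")
    if sim.n_regions < 3:
        raise ValueError("need at least 3 regions (>= 3 lower-triangle entries)")
    a, b = sim.lower_triangle(), ref.lower_triangle()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: a lower triangle has zero variance")
    return float(pearsonr(a, b).statistic)


def inclusive_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Evenly spaced grid from lo to hi inclusive (endpoint kept when it
    lies on the step lattice, within floating-point tolerance)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError(f"grid bounds inverted: {lo} > {hi}")
    n = int(np.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(n + 1)


def sweep_coupling(
    connectome: ConnectomeMatrix,
    params: WendlingParams,
    config: SimulationConfig,
    ref: FCMatrix,
    c_min: float = 0.0,
    c_max: float = 80.0,
    c_step: float = 0.1,
    band: tuple[float, float] | None = None,
) -> CouplingSweepResult:
    """Fit the global coupling coefficient by grid search.

    For each C on the inclusive grid the full protocol is run
    (``config.n_reps`` repetitions, per-repetition PLV matrices averaged
    element-wise) and compared to ``ref`` by lower-triangle Pearson
    correlation.  Divergent grid points are recorded as NaN and skipped;
    ties at the maximum go to the smallest C.
    """
    grid = inclusive_grid(c_min, c_max, c_step)
    pcc = np.full(grid.shape, np.nan)
    for k, c in enumerate(grid):
        system = CoupledSystem(params=params, connectome=connectome, c_global=float(c))
        try:
            reps = simulate_repetitions(system, config)
            sim_fc = average_fc([fc_matrix(r, band=band) for r in reps])
            pcc[k] = fc_similarity(sim_fc, ref)
        except IntegrationDivergenceError:
            continue
    if not np.any(np.isfinite(pcc)):
        raise RuntimeError("coupling sweep failed: every grid point diverged")
    best_idx = int(np.nanargmax(pcc))  # first occurrence -> smallest C on ties
    return CouplingSweepResult(
        c_values=grid,
        pcc_values=pcc,
        best_c=float(grid[best_idx]),
        best_pcc=float(pcc[best_idx]),
    )
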