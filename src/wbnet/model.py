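"""The coupled Wendling vector field.

One region is a 10-dimensional ODE: five synaptic kernel outputs
``y0..y4`` (mV) and their time derivatives ``y5..y9``.  Regions are
coupled through the pyramidal output ``y_out = y1 - y2 - y3``: region
``i`` receives ``c_global * sum_j C_ij * S(y_out_j)`` as an extra pulse
density on its excitatory input, where ``C_ij`` is the max-normalized
structural connectivity and ``S`` the firing-rate sigmoid.  Coupling is
instantaneous (no conduction delays) and the connectome's zero diagonal
rules out self-coupling.

Everything in this module is a pure function of its arguments; the
stochastic external input ``p`` is sampled by the integrator and passed
in as data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy.special import expit

from .connectome import ConnectomeMatrix
from .params import WendlingParams

__all__ = ["sigmoid", "node_output", "network_derivatives", "CoupledSystem", "N_STATE"]

#: state variables per region (y0..y4 and their derivatives y5..y9)
N_STATE = 10


def sigmoid(v: npt.ArrayLike, params: WendlingParams) -> np.ndarray | float:
    """Potential-to-firing-rate sigmoid ``S(v) = 2 e0 / (1 + exp(r (v0 - v)))``.

    Strictly increasing, bounded by (0, 2 e0), equal to ``e0`` at
    ``v = v0``.  Evaluated through :func:`scipy.special.expit` so large
    |v| cannot overflow.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid input potential must be finite")
    out = 2.0 * params.e0 * expit(params.r * (v - params.v0))
    return out if out.ndim else float(out)


def node_output(state_row: npt.ArrayLike) -> np.ndarray | float:
    """Pyramidal-population output potential ``y_out = y1 - y2 - y3`` (mV).

    ``state_row`` is one region's 10-vector, or an array whose last axis
    has length 10 (then outputs are returned per region).
    """
    y = np.asarray(state_row, dtype=float)
    if y.shape[-1] != N_STATE:
        raise ValueError(f"state must have {N_STATE} components, got {y.shape[-1]}")
    out = y[..., 1] - y[..., 2] - y[..., 3]
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class CoupledSystem:
    """A whole-brain network: one shared parameter set, one connectome,
    one global coupling coefficient.

    The effective coupling from region j to region i is
    ``c_global * C_ij``; a single scalar rescales the whole relative
    connectivity matrix.
    """

    params: WendlingParams
    connectome: ConnectomeMatrix
    c_global: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c_global) and self.c_global >= 0):
            raise ValueError(f"c_global must be finite and >= 0, got {self.c_global}")

    @property
    def n_regions(self) -> int:
        return self.connectome.n_regions

    @property
    def effective_coupling(self) -> np.ndarray:
        """CS_ij = c_global * C_ij (nonnegative, zero diagonal)."""
        return self.c_global * self.connectome.weights


def network_derivatives(
    state: npt.NDArray[np.float64],
    system: CoupledSystem,
    p: npt.NDArray[np.float64],
) -> npt.NDArray[np.float64]:
    """Time derivative of the full network state.

    Parameters
    ----------
    state:
        Array of shape ``(..., N, 10)``; row i is region i's state.
    system:
        The coupled network definition.
    p:
        External pulse density per region, shape ``(..., N)`` — the
        integrator's per-step noise sample (1/s).

    Returns
    -------
    Array of the same shape as ``state``.
    """
    y = np.asarray(state, dtype=float)
    n = system.n_regions
    if y.shape[-2:] != (n, N_STATE):
        raise ValueError(f"state shape {y.shape} does not match ({n}, {N_STATE})")
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != n:
        raise ValueError(f"p must have one entry per region ({n}), got shape {p.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to network_derivatives")

    prm = system.params
    A, B, G = prm.A, prm.B, prm.G
    a, b, g = prm.a, prm.b, prm.g

    y0 = y[..., 0]
    y1, y2, y3, y4 = y[..., 1], y[..., 2], y[..., 3], y[..., 4]
    y5, y6, y7, y8, y9 = y[..., 5], y[..., 6], y[..., 7], y[..., 8], y[..., 9]

    s_pyr = sigmoid(y1 - y2 - y3, prm)  # firing rate of the pyramidal output
    # long-range drive: c_global * sum_j C_ij * S(y_out_j)
    coupling = system.c_global * (s_pyr @ system.connectome.weights.T)

    dy = np.empty_like(y)
    dy[..., 0] = y5
    dy[..., 1] = y6
    dy[..., 2] = y7
    dy[..., 3] = y8
    dy[..., 4] = y9
    dy[..., 5] = A * a * s_pyr - 2.0 * a * y5 - a * a * y0
    dy[..., 6] = (
        A * a * (p + coupling + prm.C2 * sigmoid(prm.C1 * y0, prm))
        - 2.0 * a * y6
        - a * a * y1
    )
    dy[..., 7] = B * b * prm.C4 * sigmoid(prm.C3 * y0, prm) - 2.0 * b * y7 - b * b * y2
    dy[..., 8] = (
        G * g * prm.C7 * sigmoid(prm.C5 * y0 - y4, prm) - 2.0 * g * y8 - g * g * y3
    )
    dy[..., 9] = B * b * prm.C6 * sigmoid(prm.C3 * y0, prm) - 2.0 * b * y9 - b * b * y4
    return dy
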