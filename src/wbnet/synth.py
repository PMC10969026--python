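"""Synthetic connectomes, reference FC matrices and canonical graphs.

The empirical MRI-derived matrices this kind of model is normally built
on are not redistributable, so this module generates stand-ins with the
structure such data exhibit: an even number of regions split into two
hemispheres, symmetric nonnegative weights normalised by the global
maximum, zero self-connections, and heavier intra- than
inter-hemispheric connections.  Weight magnitudes are drawn log-normal
(fiber-count-like heavy tails); everything is seed-reproducible.

``make_reference_fc`` runs the full simulate-then-PLV pipeline at a
known coupling C* so that coupling-recovery experiments have a ground
truth; ``make_canonical_graph`` provides the standard graph-theory test
beds (complete, ring lattice, Watts-Strogatz, uniform random, path,
star).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import FCMatrix, average_fc, fc_matrix
from .connectome import ConnectomeMatrix, desikan_killiany_labels, generic_labels
from .graph import AdjacencyMatrix
from .integrator import SimulationConfig, simulate_repetitions
from .model import CoupledSystem
from .params import WendlingParams

__all__ = [
    "SyntheticSCSpec",
    "GenerationError",
    "make_synthetic_sc",
    "make_reference_fc",
    "make_canonical_graph",
]


class GenerationError(RuntimeError):
    """The requested synthetic object could not be generated."""


@dataclass(frozen=True)
class SyntheticSCSpec:
    """Recipe for a synthetic structural connectome.

    n_regions : even number of regions, half per hemisphere.
    intra_hemisphere_mean / inter_hemisphere_mean :
        mean magnitude of log-normal weights within / between
        hemispheres (arbitrary units; only their ratio survives the
        final max-normalisation).
    density : fraction of region pairs carrying a nonzero connection.
    sigma_log : log-scale spread of the weight distribution.
    seed : generator seed.
    """

    n_regions: int = 68
    intra_hemisphere_mean: float = 1.0
    inter_hemisphere_mean: float = 0.35
    density: float = 0.6
    sigma_log: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_regions % 2:
            raise ValueError("n_regions must be an even number >= 2")
        if not (0 < self.density <= 1):
            raise ValueError("density must lie in (0, 1]")
        if self.intra_hemisphere_mean <= 0 or self.inter_hemisphere_mean <= 0:
            raise ValueError("hemispheric mean weights must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


def make_synthetic_sc(spec: SyntheticSCSpec = SyntheticSCSpec()) -> ConnectomeMatrix:
    """Draw a synthetic max-normalised structural connectome.

    Each unordered region pair is retained with probability
    ``density``; retained pairs get a log-normal magnitude whose mean is
    ``intra_hemisphere_mean`` within a hemisphere and
    ``inter_hemisphere_mean`` across hemispheres.
    """
    n = spec.n_regions
    rng = np.random.default_rng(spec.seed)
    half = n // 2
    hemi = np.repeat([0, 1], half)
    intra = hemi[:, None] == hemi[None, :]

    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < spec.density
    if not present.any():
        raise GenerationError("density too low: generated connectome has no edges")

    # log-normal with prescribed linear-scale mean: mu_log = ln(mean) - s^2/2
    s = spec.sigma_log
    mean_pair = np.where(
        intra[iu, ju], spec.intra_hemisphere_mean, spec.inter_hemisphere_mean
    )
    mags = rng.lognormal(np.log(mean_pair) - s * s / 2.0, s)

    w = np.zeros((n, n))
    w[iu[present], ju[present]] = mags[present]
    w = w + w.T
    w /= w.max()
    labels = desikan_killiany_labels() if n == 68 else generic_labels(n)
    return ConnectomeMatrix(weights=w, labels=tuple(labels))


def make_reference_fc(
    connectome: ConnectomeMatrix,
    params: WendlingParams,
    config: SimulationConfig,
    c_star: float,
    band: tuple[float, float] | None = None,
) -> FCMatrix:
    """Ground-truth FC: run the full protocol at coupling ``c_star`` and
    average the per-repetition PLV matrices."""
    system = CoupledSystem(params=params, connectome=connectome, c_global=c_star)
    reps = simulate_repetitions(system, config)
    return average_fc([fc_matrix(r, band=band) for r in reps])


def make_canonical_graph(
    kind: str,
    size: int,
    seed: int | None = None,
    k: int = 6,
    p: float = 0.1,
    m: int | None = None,
) -> AdjacencyMatrix:
    """Standard test-bed graphs as binary adjacency matrices.

    kind : one of complete, ring_lattice, watts_strogatz, random, path,
        star.  ``k`` is the lattice/WS neighbour count, ``p`` the WS
        rewiring probability, ``m`` the edge count of the uniform
        random graph (defaults to k*size/2, matching a WS graph).
    """
    if size < 3:
        raise ValueError("size must be >= 3")
    if kind == "complete":
        g = nx.complete_graph(size)
    elif kind == "ring_lattice":
        g = nx.watts_strogatz_graph(size, k, 0.0)
    elif kind == "watts_strogatz":
        g = nx.watts_strogatz_graph(size, k, p, seed=seed)
    elif kind == "random":
        g = nx.gnm_random_graph(size, m if m is not None else k * size // 2, seed=seed)
    elif kind == "path":
        g = nx.path_graph(size)
    elif kind == "star":
        g = nx.star_graph(size - 1)
    else:
        raise ValueError(f"unknown canonical graph kind {kind!r}")
    a = nx.to_numpy_array(g, dtype=np.int8, nodelist=range(size))
    return AdjacencyMatrix(a=a)
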