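"""Structural connectome container.

A connectome here is a symmetric, max-normalized matrix of relative
coupling strengths between cortical regions (e.g. white-matter fiber
counts divided by the maximum count over all region pairs), with zero
self-connections.  Region ordering follows the Desikan-Killiany
convention: the 34 left-hemisphere regions first (``LH.`` prefix), then
the 34 right-hemisphere homologues (``RH.`` prefix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = ["ConnectomeMatrix", "desikan_killiany_labels", "DK_REGION_ABBREVIATIONS"]

# Desikan-Killiany cortical parcellation, 34 regions per hemisphere,
# in the standard numbering (1-34 per hemisphere).
DK_REGION_ABBREVIATIONS: tuple[str, ...] = (
    "BK", "CAC", "CMF", "CU", "EN", "FU", "IP", "IT", "IST", "LO",
    "LOF", "LG", "MOF", "MT", "PH", "PAC", "POP", "POR", "PTR", "PCL",
    "POC", "PCG", "PRC", "PCU", "RAC", "RMF", "SF", "SP", "ST", "SMG",
    "FP", "TP", "TT", "IN",
)


def desikan_killiany_labels() -> list[str]:
    """68 region labels, left hemisphere (1-34) then right (35-68)."""
    return [f"LH.{ab}" for ab in DK_REGION_ABBREVIATIONS] + [
        f"RH.{ab}" for ab in DK_REGION_ABBREVIATIONS
    ]


def generic_labels(n: int) -> list[str]:
    """LH./RH. fallback labels for an even number of generic regions."""
    half = n // 2
    return [f"LH.R{i + 1:03d}" for i in range(half)] + [
        f"RH.R{i + 1:03d}" for i in range(n - half)
    ]


@dataclass(frozen=True)
class ConnectomeMatrix:
    """Labeled, max-normalized structural connectivity matrix.

    Invariants (checked at construction): square, symmetric, zero
    diagonal, all entries in [0, 1] with the maximum equal to 1 when any
    connection exists.
    """

    weights: npt.NDArray[np.float64]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectome must be square, got shape {w.shape}")
        n = w.shape[0]
        labels = tuple(self.labels) if self.labels else tuple(
            desikan_killiany_labels() if n == 68 else generic_labels(n)
        )
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n} regions")
        object.__setattr__(self, "labels", labels)
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome weights must be finite")
        if not np.array_equal(w, w.T):
            raise ValueError("connectome must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("connectome diagonal must be zero (no self-coupling)")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("connectome entries must lie in [0, 1]")
        if w.max() > 0 and not np.isclose(w.max(), 1.0):
            raise ValueError("nonzero connectome must be max-normalized (max == 1)")

    @classmethod
    def from_raw_counts(
        cls, counts: npt.NDArray[np.float64], labels: tuple[str, ...] | list[str] = ()
    ) -> "ConnectomeMatrix":
        """Build from raw nonnegative pair counts: symmetrize, zero the
        diagonal, divide by the global maximum."""
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got shape {c.shape}")
        if np.any(c < 0):
            raise ValueError("raw counts must be nonnegative")
        w = (c + c.T) / 2.0
        np.fill_diagonal(w, 0.0)
        m = w.max()
        if m > 0:
            w = w / m
        return cls(w, tuple(labels))

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def hemispheres(self) -> npt.NDArray[np.str_]:
        """Per-region hemisphere code ('L' or 'R') parsed from labels."""
        return np.array([lab.split(".")[0][-1] for lab in self.labels])
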