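"""Node-level parameters of the Wendling neural mass model.

The Wendling model describes one cortical region as four interacting
neuronal populations: pyramidal cells, excitatory interneurons, slow
(GABA_B-like) inhibitory interneurons and fast (GABA_A-like) inhibitory
interneurons.  Each synaptic pathway is a second-order linear kernel
``h(t) = W w t exp(-w t)`` with gain ``W`` (mV) and inverse time constant
``w`` (1/s); potentials are converted to firing rates by a sigmoid.

The defaults below are the standard parameter set for resting
("background") cortical activity and are shared by every region of a
coupled network.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["WendlingParams"]


@dataclass(frozen=True)
class WendlingParams:
    """Constants of a single Wendling neural-mass node.

    Parameters
    ----------
    A, B, G:
        Average excitatory, slow-inhibitory and fast-inhibitory synaptic
        gains (mV).
    a, b, g:
        Reciprocal average time constants of the corresponding synaptic
        kernels (1/s).
    C1 ... C7:
        Dimensionless average numbers of synaptic contacts: C1/C2 in the
        excitatory feedback loop, C3/C4 in the slow inhibitory loop and
        C5/C6/C7 in the fast inhibitory loop.
    v0, e0, r:
        Sigmoid parameters: half-activation potential (mV), half of the
        maximum firing rate (1/s) and slope (1/mV).
    mu, sigma2:
        Mean and variance of the Gaussian external pulse density p(t)
        driving the pyramidal population (1/s).
    """

    A: float = 3.25
    B: float = 22.0
    G: float = 10.0
    a: float = 100.0
    b: float = 50.0
    g: float = 500.0
    C1: float = 135.0
    C2: float = 108.0
    C3: float = 33.75
    C4: float = 33.75
    C5: float = 40.5
    C6: float = 13.5
    C7: float = 108.0
    v0: float = 6.0
    e0: float = 2.5
    r: float = 0.56
    mu: float = 90.0
    sigma2: float = 30.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not (value > 0):
                raise ValueError(
                    f"WendlingParams.{f.name} must be strictly positive, got {value!r}"
                )

    def replace(self, **changes: float) -> "WendlingParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)
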