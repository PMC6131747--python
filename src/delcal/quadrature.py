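"""Fixed quadrature over the latent trait.

The latent delirium intensity has a standard-normal population distribution,
so every marginal integral is taken against phi(theta) on a symmetric grid.
Equally spaced nodes with normal-density weights are used throughout: for
analytic integrands that vanish smoothly at the grid ends the rectangle rule
converges super-algebraically, and a fixed grid keeps E-step bookkeeping
trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["Quadrature", "normal_quadrature"]


@dataclass(frozen=True)
class Quadrature:
    nodes: np.ndarray
    weights: np.ndarray  # sum to 1 (truncated standard-normal prior)

    def __post_init__(self) -> None:
        if self.nodes.shape != self.weights.shape:
            raise ValueError("nodes and weights must have the same shape")

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


def normal_quadrature(n_nodes: int = 61, bound: float = 6.0) -> Quadrature:
    """Equally spaced nodes on [-bound, bound], normalized phi weights."""
    nodes = np.linspace(-bound, bound, n_nodes)
    w = norm.pdf(nodes)
    return Quadrature(nodes=nodes, weights=w / w.sum())
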