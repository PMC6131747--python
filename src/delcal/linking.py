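"""Haebara characteristic-curve linking between separate calibrations.

Two calibrations of the same construct define latent metrics related by an
affine map theta_ref = A * theta_target + B. Haebara linking chooses (A, B)
to minimize the weighted squared distance between the anchor items'
characteristic curves computed on the reference metric:

    L(A, B) = sum_q w_q sum_{anchor pairs} sum_k
              [ P_ref(y >= k | theta_q) - P'_target(y >= k | theta_q) ]^2,

where the target item's parameters transform as loading' = loading / A and
tau'_k = tau_k + loading' * B. The loss is evaluated on the reference metric
only (non-symmetric Haebara, the common default); a symmetric variant adds
the mirrored term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .instruments import AnchorMap
from .irt import ItemParams, cumulative_probs
from .quadrature import Quadrature, normal_quadrature

__all__ = [
    "LinkingTransform",
    "haebara_link",
    "transform_params",
    "transform_scores",
]


@dataclass(frozen=True)
class LinkingTransform:
    """Affine map theta_ref = A * theta_target + B onto the reference metric."""

    A: float
    B: float
    direction: tuple[str, str]  # (target label, reference label)
    criterion_value: float
    converged: bool = True
    n_anchors: int = 0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"linking slope A must be positive, got {self.A}")

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "B": self.B,
            "direction": list(self.direction),
            "criterion": self.criterion_value,
            "converged": self.converged,
            "anchors_used": self.n_anchors,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinkingTransform":
        return cls(
            A=float(d["A"]),
            B=float(d["B"]),
            direction=tuple(d["direction"]),
            criterion_value=float(d["criterion"]),
            converged=bool(d.get("converged", True)),
            n_anchors=int(d.get("anchors_used", 0)),
        )


def _transformed_item(p: ItemParams, A: float, B: float) -> ItemParams:
    loading = p.loading / A
    return replace(
        p,
        loading=loading,
        thresholds=tuple(np.asarray(p.thresholds) + loading * B),
    )


def transform_params(
    params_list: Sequence[ItemParams], t: LinkingTransform
) -> list[ItemParams]:
    """Re-express item parameters on the reference metric.

    loading' = loading / A and tau'_k = tau_k + loading' * B, so that
    P(y >= k | theta_target) under the original parameters equals
    P(y >= k | A * theta_target + B) under the transformed ones. Threshold
    ordering is preserved (a common shift); IRT locations move as
    b' = A * b + B.
    """
    return [_transformed_item(p, t.A, t.B) for p in params_list]


def transform_scores(theta, t: LinkingTransform):
    """Map latent scores onto the reference metric: theta' = A*theta + B."""
    return t.A * np.asarray(theta, dtype=float) + t.B


def _criterion(
    logA: float,
    B: float,
    pairs: list[tuple[ItemParams, ItemParams]],
    quad: Quadrature,
) -> float:
    A = np.exp(logA)
    total = 0.0
    for ref, tgt in pairs:
        p_ref = cumulative_probs(ref.loading, ref.tau, quad.nodes)
        t = _transformed_item(tgt, A, B)
        p_tgt = cumulative_probs(t.loading, t.tau, quad.nodes)
        total += float(
            np.sum(quad.weights[:, None] * (p_ref - p_tgt) ** 2)
        )
    return total


def haebara_link(
    anchors_ref: Sequence[ItemParams],
    anchors_target: Sequence[ItemParams],
    anchor_map: AnchorMap | None = None,
    quadrature: Quadrature | None = None,
    symmetric: bool = False,
    tol: float = 1e-8,
) -> LinkingTransform:
    """Estimate the Haebara linking constants from anchor item parameters.

    ``anchors_ref`` and ``anchors_target`` hold the anchor items' parameters
    from the reference and target calibrations. When ``anchor_map`` is given
    the lists are aligned through its (reference_item_id, target_item_id)
    pairs; otherwise they must be parallel lists.

    The search runs over (log A, B) with Nelder-Mead from the identity
    (A, B) = (1, 0); A is log-parameterized to enforce positivity.
    """
    quad = quadrature or normal_quadrature()
    ref_by_id = {p.item_id: p for p in anchors_ref}
    tgt_by_id = {p.item_id: p for p in anchors_target}
    if anchor_map is not None:
        pairs = [
            (ref_by_id[r], tgt_by_id[t]) for r, t in anchor_map.pairs
        ]
        direction = (anchor_map.target, anchor_map.reference)
    else:
        if len(anchors_ref) != len(anchors_target):
            raise ValueError("anchor lists must be parallel without a map")
        pairs = list(zip(anchors_ref, anchors_target))
        direction = ("target", "reference")
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 anchor pairs, got {len(pairs)}")

    def loss(x: np.ndarray) -> float:
        val = _criterion(x[0], x[1], pairs, quad)
        if symmetric:
            # mirrored term: reference items carried onto the target metric
            # with the inverse transform theta_t = (theta_ref - B)/A
            A = np.exp(x[0])
            inv_pairs = [(t, r) for r, t in pairs]
            val += _criterion(np.log(1.0 / A), -x[1] / A, inv_pairs, quad)
        return val

    res = minimize(
        loss,
        np.array([0.0, 0.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": tol, "maxiter": 2000},
    )
    A = float(np.exp(res.x[0]))
    return LinkingTransform(
        A=A,
        B=float(res.x[1]),
        direction=direction,
        criterion_value=float(res.fun),
        converged=bool(res.success),
        n_anchors=len(pairs),
    )
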