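"""Graded response model estimation by marginal maximum likelihood EM.

The measurement model for an item with K ordered categories is

    P(y >= k | theta) = logistic(lambda * theta - tau_k),   k = 1..K-1,

with a standard-normal latent trait. For K = 2 this is the two-parameter
logistic model. Everything lives on the logit metric: no 1.7 scaling
constant anywhere, so external probit-metric parameters must be rescaled
before comparison.

Estimation is EM with a fixed rectangular-weighted quadrature grid.
Threshold ordering is maintained by optimizing log-gap reparameterizations
in the M-step, anchored at a fixed threshold when one is constrained.
Per-parameter constraints (fixed loading, fixed threshold indices) are
honoured exactly: a fixed value is returned bit-identical to its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .instruments import InstrumentSpec, ResponseTable, ValidationError
from .quadrature import Quadrature, normal_quadrature

__all__ = [
    "ItemParams",
    "CalibrationResult",
    "icc",
    "cumulative_probs",
    "category_probs",
    "loglik",
    "fit_grm",
    "eap_scores",
    "item_information",
    "test_information",
    "reliability",
    "fa_to_irt",
    "irt_to_fa",
    "param_se",
]

_TINY = 1e-300


@dataclass(frozen=True)
class ItemParams:
    """Slope and ordered thresholds of one item on the logit latent metric.

    ``thresholds`` has length K-1 and may contain +/-inf sentinels marking
    boundary categories with no observed responses. ``fixed_thresholds``
    holds 0-based indices of thresholds constrained during estimation.
    """

    item_id: str
    loading: float
    thresholds: tuple[float, ...]
    fixed_loading: bool = False
    fixed_thresholds: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        tau = np.asarray(self.thresholds, dtype=float)
        object.__setattr__(self, "thresholds", tuple(tau.tolist()))
        finite = tau[np.isfinite(tau)]
        if finite.size > 1 and not np.all(np.diff(finite) > 0):
            raise ValidationError(
                f"item {self.item_id!r}: thresholds must be strictly "
                f"increasing, got {tau.tolist()}"
            )
        if not np.isfinite(self.loading):
            raise ValidationError(f"item {self.item_id!r}: non-finite loading")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    @property
    def tau(self) -> np.ndarray:
        return np.asarray(self.thresholds, dtype=float)

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "lambda": self.loading,
            "tau": list(self.thresholds),
            "fixed_lambda": self.fixed_loading,
            "fixed_tau_indices": sorted(self.fixed_thresholds),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ItemParams":
        return cls(
            item_id=d["item_id"],
            loading=float(d["lambda"]),
            thresholds=tuple(float(t) for t in d["tau"]),
            fixed_loading=bool(d.get("fixed_lambda", False)),
            fixed_thresholds=frozenset(d.get("fixed_tau_indices", ())),
        )


def cumulative_probs(
    loading: float, thresholds: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """P(y >= k | theta) for k = 1..K-1; shape (len(theta), K-1)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    z = loading * theta[:, None] - np.asarray(thresholds, dtype=float)[None, :]
    return expit(z)


def category_probs(
    loading: float, thresholds: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """P(y = k | theta) for k = 0..K-1; shape (len(theta), K)."""
    cum = cumulative_probs(loading, thresholds, theta)
    n = cum.shape[0]
    full = np.hstack([np.ones((n, 1)), cum, np.zeros((n, 1))])
    return full[:, :-1] - full[:, 1:]


def icc(params: ItemParams, theta: float | np.ndarray) -> np.ndarray:
    """Item characteristic curve: category probabilities at theta."""
    probs = category_probs(params.loading, params.tau, np.atleast_1d(theta))
    return probs[0] if np.isscalar(theta) else probs


def _prob_tables(
    params_list: Sequence[ItemParams], quad: Quadrature
) -> list[np.ndarray]:
    return [
        category_probs(p.loading, p.tau, quad.nodes) for p in params_list
    ]


def _response_loglik_matrix(
    resp: np.ndarray, tables: Sequence[np.ndarray]
) -> np.ndarray:
    """log prod_items P(y | theta_q); shape (n_assessments, Q)."""
    n, n_items = resp.shape
    out = np.zeros((n, tables[0].shape[0]))
    for i in range(n_items):
        y = resp[:, i]
        obs = y >= 0
        if obs.any():
            out[obs] += np.log(np.maximum(tables[i][:, y[obs]].T, _TINY))
    return out


def _posterior(
    resp: np.ndarray, tables: Sequence[np.ndarray], quad: Quadrature
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior node weights per assessment and per-assessment log-marginal."""
    ll = _response_loglik_matrix(resp, tables)
    logw = np.log(quad.weights)
    a = ll + logw[None, :]
    amax = a.max(axis=1, keepdims=True)
    ex = np.exp(a - amax)
    s = ex.sum(axis=1, keepdims=True)
    post = ex / s
    logmarg = amax[:, 0] + np.log(s[:, 0])
    return post, logmarg


def _responses_from_table(
    table: ResponseTable, params_list: Sequence[ItemParams]
) -> np.ndarray:
    return table.responses([p.item_id for p in params_list])


def loglik(
    table: ResponseTable,
    params_list: Sequence[ItemParams],
    quad: Quadrature | None = None,
) -> float:
    """Marginal log-likelihood of the table under fixed item parameters."""
    quad = quad or normal_quadrature()
    resp = _responses_from_table(table, params_list)
    _, logmarg = _posterior(resp, _prob_tables(params_list, quad), quad)
    return float(logmarg.sum())


def eap_scores(
    table: ResponseTable,
    params_list: Sequence[ItemParams],
    quad: Quadrature | None = None,
):
    """Per-assessment EAP score (posterior mean, SD) under a N(0,1) prior.

    Assessments with no observed items return exactly (0, 1), the prior.
    """
    quad = quad or normal_quadrature()
    resp = _responses_from_table(table, params_list)
    post, _ = _posterior(resp, _prob_tables(params_list, quad), quad)
    mean = post @ quad.nodes
    var = post @ (quad.nodes**2) - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    all_missing = (resp < 0).all(axis=1)
    mean[all_missing] = 0.0
    sd[all_missing] = 1.0
    out = table.data[["person_id", "day"]].copy()
    out["theta"] = mean
    out["theta_sd"] = sd
    return pd.DataFrame(out)


def item_information(params: ItemParams, theta: float | np.ndarray) -> np.ndarray:
    """Fisher information of one graded item at theta.

    I(theta) = lambda^2 * sum_k (f_k - f_{k+1})^2 / P_k with
    f_k = P*_k (1 - P*_k), P*_k = P(y >= k), f_0 = f_K = 0.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    cum = cumulative_probs(params.loading, params.tau, th)
    n = th.size
    f = np.hstack([np.zeros((n, 1)), cum * (1 - cum), np.zeros((n, 1))])
    probs = category_probs(params.loading, params.tau, th)
    num = (f[:, :-1] - f[:, 1:]) ** 2
    terms = np.where(probs > 1e-12, num / np.maximum(probs, 1e-12), 0.0)
    info = params.loading**2 * terms.sum(axis=1)
    return info[0] if np.isscalar(theta) else info


def test_information(
    params_list: Sequence[ItemParams], theta: np.ndarray
) -> np.ndarray:
    """Test information: sum of item informations at each theta."""
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    return np.sum([item_information(p, th) for p in params_list], axis=0)


def reliability(info: np.ndarray) -> np.ndarray:
    """Marginal-reliability transform I / (I + 1)."""
    info = np.asarray(info, dtype=float)
    return info / (info + 1.0)


def fa_to_irt(params: ItemParams) -> tuple[float, np.ndarray]:
    """Factor-analysis (lambda, tau) -> IRT (a, b_k) with b_k = tau_k/lambda."""
    if params.loading <= 0:
        raise ValueError(
            f"item {params.item_id!r}: location undefined for loading <= 0"
        )
    return params.loading, params.tau / params.loading


def irt_to_fa(item_id: str, a: float, b: np.ndarray, **kw) -> ItemParams:
    """Inverse of :func:`fa_to_irt`: (a, b_k) -> ItemParams."""
    return ItemParams(
        item_id=item_id,
        loading=a,
        thresholds=tuple(a * np.asarray(b, dtype=float)),
        **kw,
    )


@dataclass
class CalibrationResult:
    params: list[ItemParams]
    loglik: float
    n_iter: int
    converged: bool
    quadrature: Quadrature
    loglik_trace: list[float] = field(default_factory=list)
    flags: dict[str, str] = field(default_factory=dict)

    def params_by_id(self) -> dict[str, ItemParams]:
        return {p.item_id: p for p in self.params}

    def to_dict(self) -> dict:
        return {
            "params": [p.to_dict() for p in self.params],
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "flags": dict(self.flags),
        }


class _ItemUpdater:
    """M-step bookkeeping for one item.

    Maintains the ordered log-gap reparameterization of the free finite
    thresholds, anchored at the fixed threshold when one exists.
    """

    def __init__(self, params: ItemParams, free_thr: list[int]):
        self.params = params
        self.free_thr = free_thr  # 0-based indices of free finite thresholds
        self.free_loading = not params.fixed_loading
        fixed_finite = [
            j
            for j in sorted(params.fixed_thresholds)
            if np.isfinite(params.thresholds[j])
        ]
        if len(fixed_finite) > 1 and free_thr:
            raise ValidationError(
                f"item {params.item_id!r}: at most one fixed threshold is "
                "supported when other thresholds are free"
            )
        self.anchor = fixed_finite[0] if fixed_finite else None
        self.n_free = int(self.free_loading) + len(free_thr)

    # --- packing -------------------------------------------------------
    def pack(self, loading: float, tau: np.ndarray) -> np.ndarray:
        x = []
        if self.free_loading:
            x.append(np.log(max(loading, 1e-6)))
        if self.free_thr:
            if self.anchor is None:
                prev = None
                for j in self.free_thr:
                    if prev is None:
                        x.append(tau[j])
                    else:
                        x.append(np.log(max(tau[j] - tau[prev], 1e-4)))
                    prev = j
            else:
                below = sorted([j for j in self.free_thr if j < self.anchor],
                               reverse=True)
                above = sorted([j for j in self.free_thr if j > self.anchor])
                prev = self.anchor
                for j in below:
                    x.append(np.log(max(tau[prev] - tau[j], 1e-4)))
                    prev = j
                prev = self.anchor
                for j in above:
                    x.append(np.log(max(tau[j] - tau[prev], 1e-4)))
                    prev = j
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        tau = self.params.tau.copy()
        k = 0
        loading = self.params.loading
        if self.free_loading:
            loading = float(np.exp(x[0]))
            k = 1
        if self.free_thr:
            if self.anchor is None:
                prev_val = None
                for j in self.free_thr:
                    if prev_val is None:
                        tau[j] = x[k]
                    else:
                        tau[j] = prev_val + np.exp(x[k])
                    prev_val = tau[j]
                    k += 1
            else:
                below = sorted([j for j in self.free_thr if j < self.anchor],
                               reverse=True)
                above = sorted([j for j in self.free_thr if j > self.anchor])
                prev_val = tau[self.anchor]
                for j in below:
                    tau[j] = prev_val - np.exp(x[k])
                    prev_val = tau[j]
                    k += 1
                prev_val = tau[self.anchor]
                for j in above:
                    tau[j] = prev_val + np.exp(x[k])
                    prev_val = tau[j]
                    k += 1
        return loading, tau

    def tau_jacobian(self, x: np.ndarray) -> np.ndarray:
        """d tau[free_thr] / d x_threshold-part; shape (n_free_thr, n_thr_x)."""
        m = len(self.free_thr)
        off = 1 if self.free_loading else 0
        J = np.zeros((m, m))
        if m == 0:
            return J
        xs = x[off:]
        if self.anchor is None:
            # tau_0 = x0; tau_m = tau_{m-1} + exp(x_m)
            for row in range(m):
                J[row, 0] = 1.0
                for i in range(1, row + 1):
                    J[row, i] = np.exp(xs[i])
        else:
            below = sorted([j for j in self.free_thr if j < self.anchor],
                           reverse=True)
            above = sorted([j for j in self.free_thr if j > self.anchor])
            order = below + above  # order in which x entries were packed
            pos = {j: self.free_thr.index(j) for j in self.free_thr}
            # below chain: tau = anchor - cumsum(exp)
            for bi, j in enumerate(below):
                for i in range(bi + 1):
                    J[pos[j], i] = -np.exp(xs[i])
            nb = len(below)
            for ai, j in enumerate(above):
                for i in range(ai + 1):
                    J[pos[j], nb + i] = np.exp(xs[nb + i])
        return J


def _neg_q(loading, tau, theta, r):
    """Expected complete-data negative loglik and its gradients for one item.

    r has shape (Q, K): expected response counts per quadrature node and
    category from the E-step. Returns (negQ, dnegQ/dloading, dnegQ/dtau).
    """
    Q = theta.size
    cum = cumulative_probs(loading, tau, theta)
    full = np.hstack([np.ones((Q, 1)), cum, np.zeros((Q, 1))])
    P = full[:, :-1] - full[:, 1:]
    logP = np.log(np.maximum(P, _TINY))
    negQ = -float(np.sum(r * logP))
    D = np.where(r > 0, r / np.maximum(P, _TINY), 0.0)
    f = cum * (1 - cum)
    diff = D[:, :-1] - D[:, 1:]
    # gradients of Q (not negQ)
    g_tau = np.sum(f * diff, axis=0)          # dQ/dtau_j
    g_load = -float(np.sum(theta[:, None] * f * diff))  # dQ/dloading
    return negQ, -g_load, -g_tau


def fit_grm(
    table: ResponseTable,
    spec: InstrumentSpec | None = None,
    constraints: Iterable[ItemParams] | None = None,
    quadrature: Quadrature | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> CalibrationResult:
    """Fit a graded response model by marginal maximum likelihood EM.

    Parameters
    ----------
    table
        Validated response table (binary or polytomous items).
    spec
        Instrument definition fixing item order and category counts; when
        omitted both are inferred from the data.
    constraints
        ItemParams carrying starting values and fixed flags. Items whose
        ``fixed_loading`` / ``fixed_thresholds`` flags are set keep those
        values bit-identically; everything else is estimated.
    tol
        Convergence: maximum absolute change of any free parameter.

    Missing responses contribute nothing to an assessment's likelihood term.
    Items with observed responses confined to a single category are flagged,
    given +/-inf sentinel thresholds, and excluded from estimation.
    Non-convergence is flagged on the result, never raised.
    """
    quad = quadrature or normal_quadrature()
    if spec is not None:
        item_ids = spec.item_ids
        n_cats = {it.item_id: it.n_categories for it in spec.items}
    else:
        item_ids = table.item_columns
        n_cats = {}
    if len(item_ids) < 2:
        raise ValidationError("fit_grm needs at least 2 items")
    resp = table.responses(item_ids)
    n = resp.shape[0]
    if n == 0:
        raise ValidationError("empty response table")
    cmap = {p.item_id: p for p in (constraints or [])}

    params: list[ItemParams] = []
    updaters: list[_ItemUpdater | None] = []
    flags: dict[str, str] = {}
    for i, item_id in enumerate(item_ids):
        y = resp[:, i]
        obs = y[y >= 0]
        K = n_cats.get(item_id)
        if K is None:
            K = max(int(obs.max()) + 1 if obs.size else 2,
                    cmap[item_id].n_categories if item_id in cmap else 2)
        counts = np.bincount(obs, minlength=K) if obs.size else np.zeros(K, int)
        init = cmap.get(item_id)
        fixed_loading = init.fixed_loading if init else False
        fixed_thr = frozenset(init.fixed_thresholds) if init else frozenset()
        loading = init.loading if init else 1.0
        tau = np.asarray(init.thresholds, dtype=float) if init else np.full(
            K - 1, np.nan
        )
        if init and len(init.thresholds) != K - 1:
            raise ValidationError(
                f"item {item_id!r}: constraint has {len(init.thresholds)} "
                f"thresholds, expected {K - 1}"
            )
        nonzero = np.nonzero(counts)[0]
        fully_fixed = fixed_loading and len(fixed_thr) == K - 1
        if nonzero.size <= 1 and not fully_fixed:
            # degenerate item: all observed responses in one category
            k0 = int(nonzero[0]) if nonzero.size else 0
            tau = np.where(np.arange(1, K) <= k0, -np.inf, np.inf)
            params.append(
                ItemParams(item_id, 0.0, tuple(tau),
                           fixed_loading=fixed_loading,
                           fixed_thresholds=fixed_thr)
            )
            updaters.append(None)
            flags[item_id] = "degenerate: all responses in one category"
            continue
        k_lo, k_hi = (int(nonzero[0]), int(nonzero[-1])) if nonzero.size else (0, K - 1)
        # initialize free thresholds from marginal cumulative proportions
        if np.isnan(tau).any():
            phat = np.array(
                [max(min((obs >= k).mean(), 1 - 1e-3), 1e-3)
                 for k in range(1, K)]
            )
            tau_init = -np.log(phat / (1 - phat))
            tau = np.where(np.isnan(tau), np.clip(tau_init, -4, 4), tau)
        free_thr = []
        for j in range(K - 1):  # threshold index j is the event y >= j+1
            if j in fixed_thr:
                continue
            if j + 1 <= k_lo:
                tau[j] = -np.inf
            elif j + 1 > k_hi:
                tau[j] = np.inf
                flags.setdefault(
                    item_id, f"empty boundary categories above {k_hi}"
                )
            else:
                free_thr.append(j)
        # enforce strict initial ordering among finite thresholds
        fin = [j for j in range(K - 1) if np.isfinite(tau[j])]
        for a, b in zip(fin, fin[1:]):
            if tau[b] <= tau[a]:
                if b in free_thr:
                    tau[b] = tau[a] + 0.1
                elif a in free_thr:
                    tau[a] = tau[b] - 0.1
        for a, b in zip(reversed(fin[:-1]), reversed(fin[1:])):
            if tau[b] <= tau[a] and a in free_thr:
                tau[a] = tau[b] - 0.1
        p = ItemParams(item_id, float(loading), tuple(tau),
                       fixed_loading=fixed_loading, fixed_thresholds=fixed_thr)
        upd = _ItemUpdater(p, free_thr)
        params.append(p)
        updaters.append(upd if upd.n_free else None)

    theta = quad.nodes
    prev_ll = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tables = _prob_tables(params, quad)
        post, logmarg = _posterior(resp, tables, quad)
        ll = float(logmarg.sum())
        trace.append(ll)
        max_change = 0.0
        new_params = list(params)
        for i, upd in enumerate(updaters):
            if upd is None:
                continue
            y = resp[:, i]
            K = params[i].n_categories
            r = np.zeros((quad.n_nodes, K))
            for k in range(K):
                mask = y == k
                if mask.any():
                    r[:, k] = post[mask].sum(axis=0)
            upd.params = params[i]
            x0 = upd.pack(params[i].loading, params[i].tau)

            def fun(x, upd=upd, r=r):
                loading, tau = upd.unpack(x)
                negQ, gL, gT = _neg_q(loading, tau, theta, r)
                g = np.zeros_like(x)
                k = 0
                if upd.free_loading:
                    g[0] = gL * loading  # chain rule through log
                    k = 1
                if upd.free_thr:
                    J = upd.tau_jacobian(x)
                    g[k:] = J.T @ gT[upd.free_thr]
                return negQ, g

            f0, _ = fun(x0)
            res = minimize(fun, x0, jac=True, method="BFGS",
                           options={"maxiter": 50, "gtol": 1e-7})
            if res.fun <= f0:  # monotone safeguard
                loading, tau = upd.unpack(res.x)
                old = params[i]
                delta = abs(loading - old.loading)
                fin = np.isfinite(tau)
                if fin.any():
                    delta = max(
                        delta, float(np.max(np.abs(tau[fin] - old.tau[fin])))
                    )
                max_change = max(max_change, delta)
                new_params[i] = replace(
                    old, loading=float(loading), thresholds=tuple(tau)
                )
        params = new_params
        if it > 1 and max_change < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    # final loglik at the returned parameters
    _, logmarg = _posterior(resp, _prob_tables(params, quad), quad)
    final_ll = float(logmarg.sum())
    trace.append(final_ll)
    return CalibrationResult(
        params=params,
        loglik=final_ll,
        n_iter=it,
        converged=converged,
        quadrature=quad,
        loglik_trace=trace,
        flags=flags,
    )


def param_se(
    table: ResponseTable,
    params_list: Sequence[ItemParams],
    quad: Quadrature | None = None,
    step: float = 1e-3,
) -> dict[str, dict]:
    """Observed-information standard errors for the free, finite parameters.

    Central finite differences of the marginal log-likelihood; clustering is
    ignored (independent-assessment information), so these are model-based
    SEs for the point estimates only.
    """
    quad = quad or normal_quadrature()
    resp = _responses_from_table(table, params_list)

    entries: list[tuple[int, str, int]] = []  # (item index, kind, thr index)
    x0 = []
    for i, p in enumerate(params_list):
        if not p.fixed_loading and p.loading != 0.0:
            entries.append((i, "loading", -1))
            x0.append(p.loading)
        for j, t in enumerate(p.thresholds):
            if j not in p.fixed_thresholds and np.isfinite(t):
                entries.append((i, "tau", j))
                x0.append(t)
    x0 = np.asarray(x0)

    def ll_at(x: np.ndarray) -> float:
        plist = list(params_list)
        for (i, kind, j), v in zip(entries, x):
            p = plist[i]
            if kind == "loading":
                plist[i] = replace(p, loading=float(v))
            else:
                tau = p.tau.copy()
                tau[j] = v
                fin = tau[np.isfinite(tau)]
                if not np.all(np.diff(fin) > 0):
                    return -np.inf
                plist[i] = replace(p, thresholds=tuple(tau))
        _, lm = _posterior(resp, _prob_tables(plist, quad), quad)
        return float(lm.sum())

    m = x0.size
    H = np.zeros((m, m))
    h = np.maximum(np.abs(x0), 1.0) * step
    f0 = ll_at(x0)
    fp = np.zeros(m)
    fm = np.zeros(m)
    for a in range(m):
        e = np.zeros(m)
        e[a] = h[a]
        fp[a] = ll_at(x0 + e)
        fm[a] = ll_at(x0 - e)
        H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h[a] ** 2
    for a in range(m):
        for b in range(a + 1, m):
            ea = np.zeros(m); ea[a] = h[a]
            eb = np.zeros(m); eb[b] = h[b]
            fpp = ll_at(x0 + ea + eb)
            H[a, b] = H[b, a] = (
                fpp - fp[a] - fp[b] + f0
            ) / (h[a] * h[b])
    cov = np.linalg.pinv(-H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    out: dict[str, dict] = {}
    for (i, kind, j), s in zip(entries, se):
        d = out.setdefault(params_list[i].item_id, {"loading": None, "tau": {}})
        if kind == "loading":
            d["loading"] = float(s)
        else:
            d["tau"][j] = float(s)
    return out
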