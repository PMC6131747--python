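"""Downstream outputs of the harmonized model.

Test characteristic curves (expected sum score against latent intensity),
their inverses, integer-score crosswalk tables between instruments,
information/reliability curves, item-person maps, factor-score correlation
matrices, and residual diagnostics against observed polychoric correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import multivariate_normal, norm

from .instruments import InstrumentSpec, ResponseTable
from .irt import (
    ItemParams,
    category_probs,
    cumulative_probs,
    fa_to_irt,
    test_information,
    reliability,
)
from .pipeline import HarmonizedModel

__all__ = [
    "tcc",
    "invert_tcc",
    "CrosswalkTable",
    "crosswalk",
    "reliability_report",
    "item_person_map",
    "score_correlations",
    "polychoric_corr",
    "residual_diagnostics",
]

#: Default curve grid: severity skews high relative to the sample mean.
DEFAULT_GRID = np.arange(-3.0, 6.0 + 1e-9, 0.01)

THETA_MAX = 6.0


def tcc(params_list: Sequence[ItemParams], theta) -> np.ndarray:
    """Test characteristic curve: expected total score at each theta.

    E[X | theta] = sum_i sum_k k P_ik(theta)
                 = sum_i sum_{k>=1} P(y_i >= k | theta); non-decreasing.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    total = np.zeros(th.size)
    for p in params_list:
        total += cumulative_probs(p.loading, p.tau, th).sum(axis=1)
    return total[0] if np.isscalar(theta) else total


def invert_tcc(
    params_list: Sequence[ItemParams],
    score: float,
    theta_max: float = THETA_MAX,
) -> tuple[float, bool]:
    """Latent intensity at which the expected score equals ``score``.

    Returns (theta, truncated). Scores at or beyond the curve's value at
    +/-theta_max are truncated to the boundary with the flag set. Scores
    outside [0, max attainable] raise.
    """
    max_score = sum(p.n_categories - 1 for p in params_list)
    if not 0 <= score <= max_score:
        raise ValueError(f"score {score} outside [0, {max_score}]")
    lo, hi = -theta_max, theta_max
    f = lambda t: tcc(params_list, t) - score
    if f(lo) >= 0:
        return lo, True
    if f(hi) <= 0:
        return hi, True
    root = brentq(f, lo, hi, xtol=1e-6)
    return float(root), False


@dataclass
class CrosswalkTable:
    """Integer source score -> equated theta -> expected target scores."""

    source: str
    table: pd.DataFrame  # columns: source score, theta, truncated, per-target

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def crosswalk(
    model: HarmonizedModel,
    source: str,
    targets: Sequence[str] | None = None,
) -> CrosswalkTable:
    """Crosswalk each integer source score to expected scores on the targets.

    For each source score s: theta = TCC_source^{-1}(s), then for each target
    the raw expected score TCC_target(theta) and its half-up rounding are
    reported. Composition of non-decreasing maps, hence monotone.
    """
    if targets is None:
        targets = [n for n in model.instruments if n != source]
    src_params = model.instruments[source]
    max_score = sum(p.n_categories - 1 for p in src_params)
    rows = []
    for s in range(max_score + 1):
        theta, truncated = invert_tcc(src_params, s)
        row = {f"{source}_score": s, "theta": theta, "truncated": truncated}
        for t in targets:
            raw = float(tcc(model.instruments[t], theta))
            row[f"{t}_expected"] = raw
            row[f"{t}_rounded"] = int(np.floor(raw + 0.5))
        rows.append(row)
    return CrosswalkTable(source=source, table=pd.DataFrame(rows))


def reliability_report(
    model: HarmonizedModel,
    theta_grid: np.ndarray | None = None,
    threshold: float = 0.70,
) -> tuple[dict[str, pd.DataFrame], dict[str, float]]:
    """Information and reliability curves per instrument.

    Returns the per-instrument curve tables (theta, information, reliability)
    and the width of the theta region where reliability >= ``threshold``.
    """
    grid = DEFAULT_GRID if theta_grid is None else np.asarray(theta_grid)
    step = np.diff(grid).mean()
    curves: dict[str, pd.DataFrame] = {}
    widths: dict[str, float] = {}
    for name, params in model.instruments.items():
        info = test_information(params, grid)
        rel = reliability(info)
        curves[name] = pd.DataFrame(
            {"theta": grid, "information": info, "reliability": rel}
        )
        widths[name] = float((rel >= threshold).sum() * step)
    return curves, widths


def item_person_map(
    model: HarmonizedModel,
    flag_threshold: float = 4.0,
) -> pd.DataFrame:
    """Item category locations on the common metric, with extremity flags.

    One row per item and category boundary: b_k = tau_k / loading. Categories
    located more than ``flag_threshold`` SD above the latent mean are flagged
    (they are only reached in the most severe assessments). Items with
    non-positive loadings have no defined location and are excluded.
    """
    rows = []
    for name, params in model.instruments.items():
        for p in params:
            if p.loading <= 0:
                continue
            _, b = fa_to_irt(p)
            for k, bk in enumerate(b, start=1):
                rows.append(
                    {
                        "instrument": name,
                        "item_id": p.item_id,
                        "category": k,
                        "location": float(bk),
                        "flagged": bool(np.isfinite(bk) and bk > flag_threshold),
                    }
                )
    return pd.DataFrame(rows)


def score_correlations(model: HarmonizedModel) -> pd.DataFrame:
    """Pearson correlations of per-assessment EAP scores across instruments.

    Each pair is computed over the assessments scored on both instruments;
    fewer than 3 common assessments is an error.
    """
    names = list(model.instruments)
    cols = {n: model.scores[f"theta_{n}"] for n in names}
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            both = cols[a].notna() & cols[b].notna()
            if both.sum() < 3:
                raise ValueError(
                    f"fewer than 3 common assessments for {a} and {b}"
                )
            mat.loc[a, b] = float(np.corrcoef(cols[a][both], cols[b][both])[0, 1])
    return mat


# ---------------------------------------------------------------------------
# residual diagnostics: observed vs model-implied polychoric correlations

_LOGISTIC_VAR = np.pi**2 / 3.0


def polychoric_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation of two ordinal variables.

    Thresholds come from the marginal cumulative proportions (probit scale);
    the correlation maximizes the bivariate-normal rectangle likelihood of
    the cross-table. Raises if the cross-table is degenerate (a variable
    with a single observed category).
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    x = x[ok].astype(int)
    y = y[ok].astype(int)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("polychoric needs >= 2 observed categories per variable")

    def cuts(v: np.ndarray) -> np.ndarray:
        cats = np.arange(v.min(), v.max() + 1)
        cum = np.array([(v <= c).mean() for c in cats[:-1]])
        return norm.ppf(np.clip(cum, 1e-6, 1 - 1e-6))

    cx, cy = cuts(x), cuts(y)
    ax = np.concatenate([[-np.inf], cx, [np.inf]])
    ay = np.concatenate([[-np.inf], cy, [np.inf]])
    counts = np.zeros((ax.size - 1, ay.size - 1))
    xs = x - x.min()
    ys = y - y.min()
    for i, j in zip(xs, ys):
        counts[i, j] += 1

    def rect_probs(rho: float) -> np.ndarray:
        mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

        def cdf(a, b):
            if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
                return 0.0
            aa = min(a, 8.0)
            bb = min(b, 8.0)
            return float(mvn.cdf([aa, bb]))

        F = np.array([[cdf(a, b) for b in ay] for a in ax])
        return np.maximum(
            F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1], 1e-12
        )

    def negll(rho: float) -> float:
        return -float(np.sum(counts * np.log(rect_probs(rho))))

    res = minimize_scalar(
        negll, bounds=(-0.995, 0.995), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)


def implied_latent_corr(p_i: ItemParams, p_j: ItemParams) -> float:
    """Model-implied correlation of two items' latent responses.

    Under the graded model the latent response is loading*theta + e with
    logistic residual variance pi^2/3, giving
    rho_ij = l_i l_j / sqrt((l_i^2 + pi^2/3)(l_j^2 + pi^2/3)).
    """
    s = _LOGISTIC_VAR
    return float(
        p_i.loading * p_j.loading
        / np.sqrt((p_i.loading**2 + s) * (p_j.loading**2 + s))
    )


def residual_diagnostics(
    table: ResponseTable,
    params_list: Sequence[ItemParams],
) -> tuple[pd.DataFrame, float]:
    """Observed vs model-implied pairwise latent correlations and their RMSR.

    Serves as an estimator-agnostic unidimensionality diagnostic: under a
    well-fitting one-factor model the observed polychoric correlations track
    the implied ones and the root-mean-square residual is small. Item pairs
    with degenerate cross-tables are skipped.
    """
    by_id = {p.item_id: p for p in params_list}
    ids = [p.item_id for p in params_list if p.item_id in table.data.columns]
    rows = []
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            a, b = ids[a_idx], ids[b_idx]
            try:
                obs = polychoric_corr(
                    table.data[a].to_numpy(), table.data[b].to_numpy()
                )
            except ValueError:
                continue
            imp = implied_latent_corr(by_id[a], by_id[b])
            rows.append(
                {
                    "item_i": a,
                    "item_j": b,
                    "observed": obs,
                    "implied": imp,
                    "residual": obs - imp,
                }
            )
    df = pd.DataFrame(rows)
    rmsr = float(np.sqrt(np.mean(df["residual"] ** 2))) if len(df) else np.nan
    return df, rmsr
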