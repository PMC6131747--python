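"""Graded-model engine: closed forms, dense-grid oracles, EM behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import simpson
from scipy.special import expit

from delcal.instruments import InstrumentSpec, Item
from delcal.irt import (
    ItemParams,
    category_probs,
    eap_scores,
    fa_to_irt,
    fit_grm,
    icc,
    irt_to_fa,
    item_information,
    loglik,
    param_se,
)
from delcal.irt import test_information as total_information
from delcal.quadrature import normal_quadrature
from delcal.simulate import simulate_responses

from conftest import make_table

GRID = np.linspace(-6, 6, 2001)
PHI = np.exp(-GRID**2 / 2) / np.sqrt(2 * np.pi)


def dense_loglik(resp, params_list):
    """Independent oracle: simpson integration of prod P over a 2001-pt grid."""
    total = 0.0
    tables = [category_probs(p.loading, p.tau, GRID) for p in params_list]
    for row in resp:
        like = np.ones_like(GRID)
        for i, y in enumerate(row):
            if y >= 0:
                like = like * tables[i][:, y]
        total += np.log(
            simpson(like * PHI, x=GRID) / simpson(PHI, x=GRID)
        )
    return total


def dense_eap(resp, params_list):
    tables = [category_probs(p.loading, p.tau, GRID) for p in params_list]
    out = []
    for row in resp:
        like = PHI.copy()
        for i, y in enumerate(row):
            if y >= 0:
                like = like * tables[i][:, y]
        m = simpson(GRID * like, x=GRID) / simpson(like, x=GRID)
        out.append(m)
    return np.array(out)


def small_instance(seed=0, n=50):
    spec = InstrumentSpec(
        "small",
        (
            Item("a", "d1", 4, 1),
            Item("b", "d2", 3, 1),
            Item("c", "d3", 2, 1),
            Item("d", "d4", 4, 2),
        ),
    )
    params = [
        ItemParams("a", 1.4, (-1.0, 0.3, 1.8)),
        ItemParams("b", 0.9, (0.0, 1.2)),
        ItemParams("c", 2.0, (0.5,)),
        ItemParams("d", 1.1, (-0.4, 0.9, 2.2)),
    ]
    rng = np.random.default_rng(seed)
    th = pd.DataFrame(
        {"person_id": np.arange(n), "day": 1, "theta": rng.normal(size=n)}
    )
    table = simulate_responses(th, params, spec, missing_rate=0.1, seed=seed + 1)
    return spec, params, table


class TestICC:
    def test_binary_midpoint(self):
        p = ItemParams("x", 1.0, (0.0,))
        assert np.allclose(icc(p, 0.0), [0.5, 0.5])

    def test_closed_form_cumulative(self):
        p = ItemParams("x", 2.0, (-1.0, 1.0))
        probs = icc(p, 0.0)
        p_ge1, p_ge2 = expit(1.0), expit(-1.0)
        assert p_ge1 == pytest.approx(0.7311, abs=1e-4)
        assert p_ge2 == pytest.approx(0.2689, abs=1e-4)
        assert np.allclose(probs, [1 - p_ge1, p_ge1 - p_ge2, p_ge2])

    def test_limits_and_normalization(self):
        p = ItemParams("x", 1.5, (-0.5, 0.8, 2.0))
        assert np.allclose(icc(p, -40.0), [1, 0, 0, 0], atol=1e-12)
        assert np.allclose(icc(p, 40.0), [0, 0, 0, 1], atol=1e-12)
        th = np.linspace(-4, 4, 17)
        assert np.allclose(icc(p, th).sum(axis=1), 1.0)


class TestLoglik:
    def test_theta_independent_item(self):
        spec = InstrumentSpec("s", (Item("a", "d", 2), Item("b", "d2", 2)))
        t = make_table("s", {"a": [0, 1, 0, 1], "b": [np.nan] * 4})
        params = [ItemParams("a", 0.0, (0.0,)), ItemParams("b", 0.0, (0.0,))]
        assert loglik(t, params) == pytest.approx(4 * np.log(0.5), abs=1e-9)

    def test_matches_dense_grid_oracle(self):
        spec, params, table = small_instance(seed=3)
        resp = table.responses([p.item_id for p in params])
        ours = loglik(table, params)
        oracle = dense_loglik(resp, params)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_all_missing_assessment_contributes_zero(self):
        spec, params, table = small_instance(seed=4, n=20)
        extra = table.data.iloc[:1].copy()
        extra[["a", "b", "c", "d"]] = np.nan
        extra["person_id"] = 9999
        from delcal.instruments import ResponseTable

        bigger = ResponseTable(
            "small", pd.concat([table.data, extra], ignore_index=True)
        )
        assert loglik(bigger, params) == pytest.approx(
            loglik(table, params), abs=1e-12
        )


class TestEAP:
    def test_matches_dense_grid_oracle(self):
        spec, params, table = small_instance(seed=5)
        resp = table.responses([p.item_id for p in params])
        ours = eap_scores(table, params)["theta"].to_numpy()
        oracle = dense_eap(resp, params)
        assert np.max(np.abs(ours - oracle)) < 1e-4

    def test_all_missing_returns_prior(self):
        spec = InstrumentSpec("s", (Item("a", "d", 2), Item("b", "d2", 2)))
        t = make_table("s", {"a": [np.nan, 1], "b": [np.nan, 1]})
        params = [ItemParams("a", 1.5, (0.0,)), ItemParams("b", 1.5, (0.5,))]
        sc = eap_scores(t, params)
        assert sc["theta"].iloc[0] == 0.0
        assert sc["theta_sd"].iloc[0] == 1.0
        assert sc["theta"].iloc[1] > 0  # all items endorsed -> above the mean


class TestInformation:
    def test_binary_item_at_location(self):
        lam, b = 1.8, 0.7
        p = ItemParams("x", lam, (lam * b,))
        assert item_information(p, b) == pytest.approx(0.25 * lam**2, abs=1e-10)

    def test_additivity(self):
        p1 = ItemParams("x", 1.2, (-0.5, 1.0))
        p2 = ItemParams("y", 0.8, (0.3,))
        th = np.linspace(-3, 3, 7)
        total = total_information([p1, p2], th)
        assert np.allclose(
            total, item_information(p1, th) + item_information(p2, th)
        )

    def test_matches_curvature_of_expected_loglik(self):
        # I(theta) = -E_y[d^2/dtheta^2 log P(y|theta)] via central differences
        p = ItemParams("x", 1.6, (-0.8, 0.4, 1.9))
        h = 1e-4
        for theta0 in (-2.0, -0.5, 0.0, 1.0, 2.5):
            probs0 = icc(p, theta0)
            lp = lambda t: np.log(icc(p, t))
            d2 = (lp(theta0 + h) - 2 * lp(theta0) + lp(theta0 - h)) / h**2
            oracle = -np.sum(probs0 * d2)
            assert item_information(p, theta0) == pytest.approx(
                oracle, abs=1e-4
            )


class TestConversions:
    def test_fa_to_irt_and_back(self):
        p = ItemParams("x", 2.0, (1.0, 3.0))
        a, b = fa_to_irt(p)
        assert a == 2.0 and np.allclose(b, [0.5, 1.5])
        back = irt_to_fa("x", a, b)
        assert np.allclose(back.tau, p.tau, atol=1e-12)

    def test_zero_loading_has_no_location(self):
        with pytest.raises(ValueError, match="undefined"):
            fa_to_irt(ItemParams("x", 0.0, (0.5,)))


class TestFit:
    def test_loglik_at_fixed_truth_matches_oracle(self):
        spec, params, table = small_instance(seed=6)
        fixed = [
            ItemParams(
                p.item_id, p.loading, p.thresholds,
                fixed_loading=True,
                fixed_thresholds=frozenset(range(len(p.thresholds))),
            )
            for p in params
        ]
        res = fit_grm(table, spec, constraints=fixed, max_iter=5)
        resp = table.responses([p.item_id for p in params])
        assert res.loglik == pytest.approx(dense_loglik(resp, params), abs=1e-6)
        # fixed parameters pass through bit-identically
        for got, want in zip(res.params, fixed):
            assert got.loading == want.loading
            assert got.thresholds == want.thresholds

    def test_em_loglik_monotone(self, study):
        from delcal.instruments import dichotomize

        spec = study.specs["CAM-S-long"]
        res = fit_grm(
            dichotomize(study.tables["CAM-S-long"], spec), spec.dichotomized()
        )
        trace = np.array(res.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert res.converged

    def test_quadrature_stability(self, study):
        spec = study.specs["MDAS"]
        table = study.tables["MDAS"]
        params = study.true_params["MDAS"]
        l49 = loglik(table, params, normal_quadrature(49))
        l101 = loglik(table, params, normal_quadrature(101))
        assert abs(l49 - l101) < 1e-6

    def test_parameter_recovery_within_3se(self):
        lam, tau = 1.5, (-1.0, 0.0, 2.0)
        spec = InstrumentSpec(
            "r", tuple(Item(f"i{k}", f"d{k}", 4) for k in range(3))
        )
        params = [ItemParams(f"i{k}", lam, tau) for k in range(3)]
        n = 2000
        rng = np.random.default_rng(17)
        th = pd.DataFrame(
            {"person_id": np.arange(n), "day": 1, "theta": rng.normal(size=n)}
        )
        table = simulate_responses(th, params, spec, seed=18)
        res = fit_grm(table, spec)
        se = param_se(table, res.params)
        for p in res.params:
            s = se[p.item_id]
            assert abs(p.loading - lam) < 3 * s["loading"]
            for j, t in enumerate(tau):
                assert abs(p.thresholds[j] - t) < 3 * s["tau"][j]
        # IRT locations recovered on the b metric as well
        for p in res.params:
            _, b = fa_to_irt(p)
            b_true = np.asarray(tau) / lam
            assert np.max(np.abs(b - b_true)) < 0.25

    def test_degenerate_item_flagged_with_sentinels(self):
        spec = InstrumentSpec("s", (Item("a", "d", 3), Item("b", "d2", 3)))
        t = make_table("s", {"a": [1] * 30, "b": [0, 1, 2] * 10})
        res = fit_grm(t, spec, max_iter=50)
        assert "a" in res.flags
        pa = res.params_by_id()["a"]
        assert pa.thresholds[0] == -np.inf and pa.thresholds[1] == np.inf
        # the flagged item drops out of scoring: its icc is constant
        assert np.allclose(icc(pa, -3.0), icc(pa, 3.0))

    def test_binary_grm_is_2pl(self):
        # K=2 graded model: P(y=1) = logistic(lam*theta - tau), the 2PL
        p = ItemParams("x", 1.7, (0.6,))
        th = np.linspace(-3, 3, 13)
        assert np.allclose(
            category_probs(p.loading, p.tau, th)[:, 1],
            expit(1.7 * th - 0.6),
        )

    def test_nonconvergence_flagged_not_raised(self):
        spec, params, table = small_instance(seed=8, n=40)
        res = fit_grm(table, spec, max_iter=3)
        assert res.converged is False
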