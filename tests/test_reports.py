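"""Crosswalks, curves, correlation matrices, and residual diagnostics."""

import numpy as np
import pandas as pd
import pytest

from delcal.instruments import InstrumentSpec, Item, dichotomize
from delcal.irt import ItemParams
from delcal.pipeline import HarmonizedModel
from delcal.reports import (
    crosswalk,
    implied_latent_corr,
    invert_tcc,
    item_person_map,
    polychoric_corr,
    reliability_report,
    residual_diagnostics,
    score_correlations,
    tcc,
)
from delcal.simulate import simulate_responses

PARAMS = [
    ItemParams("a", 1.5, (-0.8, 0.5, 1.9)),
    ItemParams("b", 1.0, (0.2, 1.4)),
    ItemParams("c", 2.0, (0.9,)),
]


class TestTCC:
    def test_limits(self):
        assert tcc(PARAMS, -40.0) == pytest.approx(0.0, abs=1e-10)
        assert tcc(PARAMS, 40.0) == pytest.approx(6.0, abs=1e-10)

    def test_single_binary_item_midpoint(self):
        assert tcc([ItemParams("x", 1.0, (0.0,))], 0.0) == pytest.approx(0.5)

    def test_monotone(self):
        grid = np.linspace(-6, 6, 241)
        assert np.all(np.diff(tcc(PARAMS, grid)) > 0)

    def test_matches_monte_carlo_mean_sum_score(self):
        spec = InstrumentSpec(
            "s", (Item("a", "d1", 4), Item("b", "d2", 3), Item("c", "d3", 2))
        )
        n = 20000
        for theta0 in (-1.5, -0.5, 0.5, 1.5, 3.0):
            th = pd.DataFrame(
                {"person_id": np.arange(n), "day": 1,
                 "theta": np.full(n, theta0)}
            )
            t = simulate_responses(th, PARAMS, spec, seed=int(10 * theta0) + 60)
            sums = t.data[["a", "b", "c"]].sum(axis=1)
            mc_se = sums.std(ddof=1) / np.sqrt(n)
            assert abs(tcc(PARAMS, theta0) - sums.mean()) < 3 * mc_se

    def test_inversion_round_trip(self):
        theta0 = 1.7
        s = tcc(PARAMS, theta0)
        theta, truncated = invert_tcc(PARAMS, float(s))
        assert not truncated
        assert theta == pytest.approx(theta0, abs=1e-5)

    def test_boundary_truncation(self):
        theta, truncated = invert_tcc(PARAMS, 0.0)
        assert truncated and theta == -6.0
        theta, truncated = invert_tcc(PARAMS, 6.0)
        assert truncated and theta == 6.0
        with pytest.raises(ValueError, match="outside"):
            invert_tcc(PARAMS, 7.0)


class TestCrosswalk:
    def test_self_crosswalk_is_identity(self, model):
        cw = crosswalk(model, "MDAS", ["MDAS"])
        t = cw.table
        inner = t[~t["truncated"]]
        assert (inner["MDAS_rounded"] == inner["MDAS_score"]).all()

    def test_columns_monotone_and_in_range(self, model):
        cw = crosswalk(model, "CAM-S-long", ["DRS-R-98", "MDAS"])
        t = cw.table
        assert (t["theta"].diff().dropna() >= 0).all()
        for tgt, mx in (("DRS-R-98", 39), ("MDAS", 30)):
            col = t[f"{tgt}_rounded"]
            assert (col.diff().dropna() >= 0).all()
            assert col.between(0, mx).all()

    def test_regenerates_identically_from_serialized_model(self, model):
        back = HarmonizedModel.from_dict(model.to_dict())
        for source in ("DRS-R-98", "CAM-S-short"):
            a = crosswalk(model, source).table
            b = crosswalk(back, source).table
            pd.testing.assert_frame_equal(a, b)


class TestReliability:
    def test_more_items_give_more_information(self, model):
        curves, _ = reliability_report(model)
        long_i = curves["CAM-S-long"]["information"]
        short_i = curves["CAM-S-short"]["information"]
        assert (long_i >= short_i - 1e-12).all()

    def test_reliability_vanishes_in_the_tails(self):
        grid = np.array([-30.0, 30.0])
        from delcal.irt import test_information as tinfo
        from delcal.irt import reliability as rel

        assert np.all(rel(tinfo(PARAMS, grid)) < 1e-6)

    def test_widths_positive_and_reported_per_instrument(self, model):
        _, widths = reliability_report(model)
        assert set(widths) == set(model.instruments)
        assert all(w > 0 for w in widths.values())


class TestItemPersonMap:
    def test_location_arithmetic_and_flag_rule(self):
        model = _tiny_model([ItemParams("x", 2.0, (2.0, 8.0)),
                             ItemParams("y", 1.0, (0.5,))])
        ipm = item_person_map(model)
        x = ipm[ipm.item_id == "x"].set_index("category")
        assert x.loc[1, "location"] == pytest.approx(1.0)
        assert x.loc[2, "location"] == pytest.approx(4.0)
        assert not x.loc[1, "flagged"]
        assert not x.loc[2, "flagged"]  # boundary: rule is strictly above 4
        y = item_person_map(_tiny_model([ItemParams("x", 2.0, (2.0, 8.2)),
                                         ItemParams("y", 1.0, (0.5,))]))
        assert y[y.item_id == "x"].set_index("category").loc[2, "flagged"]

    def test_flags_match_serialized_recomputation(self, model):
        ipm = item_person_map(model)
        back = item_person_map(HarmonizedModel.from_dict(model.to_dict()))
        pd.testing.assert_frame_equal(ipm, back)
        recomputed = ipm["location"] > 4.0
        finite = np.isfinite(ipm["location"])
        assert (ipm["flagged"] == (recomputed & finite)).all()


class TestScoreCorrelations:
    def test_diagonal_is_one(self, model):
        corr = score_correlations(model)
        assert np.allclose(np.diag(corr.to_numpy(dtype=float)), 1.0)

    def test_independent_latents_destroy_correlation(self, bundled_specs):
        """Negative control: independent thetas per instrument -> r near 0."""
        from delcal.simulate import GeneratorConfig, simulate_theta, default_true_params
        from delcal.pipeline import run_pipeline, PipelineConfig

        specs = {k: bundled_specs[k] for k in ("DRS-R-98", "MDAS", "CAM-S-long")}
        true = default_true_params(specs)
        tables = {}
        for i, (name, spec) in enumerate(specs.items()):
            th = simulate_theta(GeneratorConfig(seed=500 + i))
            tables[name] = simulate_responses(th, true[name], spec, seed=600 + i)
        model = run_pipeline(tables, specs, PipelineConfig())
        corr = score_correlations(model).to_numpy(dtype=float)
        main = corr[:3, :3]
        off = main[np.triu_indices(3, 1)]
        assert np.max(np.abs(off)) < 0.15


def _tiny_model(params):
    scores = pd.DataFrame(
        {"person_id": [1, 2, 3], "day": [1, 1, 1],
         "theta_T": [0.0, 0.1, 0.2], "sd_T": [1.0, 1.0, 1.0]}
    )
    spec = InstrumentSpec(
        "T", tuple(Item(p.item_id, f"d{i}", p.n_categories)
                   for i, p in enumerate(params))
    )
    return HarmonizedModel(
        reference="T", specs={"T": spec}, instruments={"T": list(params)},
        step1=None, step2=None, transforms={}, scores=scores,
    )


class TestResidualDiagnostics:
    def test_zero_loading_implies_zero_correlation(self):
        assert implied_latent_corr(
            ItemParams("x", 0.0, (0.0,)), ItemParams("y", 1.5, (0.0,))
        ) == 0.0

    def test_polychoric_recovers_known_correlation(self):
        rng = np.random.default_rng(3)
        n, rho = 4000, 0.6
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        x = np.digitize(z[:, 0], [-0.5, 0.8])
        y = np.digitize(z[:, 1], [0.0, 1.0])
        est = polychoric_corr(x.astype(float), y.astype(float))
        assert est == pytest.approx(rho, abs=0.05)

    def test_small_rmsr_under_the_generating_model(self, study, model):
        table = study.tables["CAM-S-long"]
        df, rmsr = residual_diagnostics(
            table, model.instruments["CAM-S-long"]
        )
        assert len(df) > 30
        assert rmsr < 0.07

    def test_two_factor_data_inflate_rmsr(self):
        """Misfit sensitivity: two independent factors forced into one."""
        from delcal.instruments import ResponseTable
        from delcal.irt import fit_grm

        rng = np.random.default_rng(8)
        n = 1500
        th1 = rng.normal(size=n)
        th2 = rng.normal(size=n)  # independent second factor
        spec = InstrumentSpec(
            "two", tuple(Item(f"i{k}", f"d{k}", 3) for k in range(6))
        )
        params = [ItemParams(f"i{k}", 1.6, (-0.3, 1.0)) for k in range(6)]
        data = {"person_id": np.arange(n), "day": np.ones(n, int)}
        for k in range(6):
            th = th1 if k < 3 else th2
            cum = 1 / (1 + np.exp(-(1.6 * th[:, None] - np.array([-0.3, 1.0]))))
            u = rng.uniform(size=(n, 1))
            data[f"i{k}"] = (u < cum).sum(axis=1).astype(float)
        table = ResponseTable("two", pd.DataFrame(data))
        res = fit_grm(table, spec)
        _, rmsr = residual_diagnostics(table, res.params)
        assert rmsr > 0.15
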