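import numpy as np
import pandas as pd
import pytest

from dropletomics import oplsda as op
from conftest import build_table


def _two_group(rng, n_species=8, n_per=5, effect_on=(), effect=3.0,
               sigma=0.15):
    samples = ([f"a{i}" for i in range(n_per)]
               + [f"b{i}" for i in range(n_per)])
    design = {s: ("GA" if s[0] == "a" else "GB") for s in samples}
    values = {}
    for i in range(n_species):
        name = f"TG {40 + 2 * i}:{i % 4}"
        row = rng.lognormal(3, sigma, 2 * n_per)
        if name in effect_on:
            row[:n_per] *= effect
        values[name] = row.tolist()
    return build_table(values, samples, design=design), design


class TestFit:
    def test_perfect_discriminator_has_top_correlation(self, make_table):
        rng = np.random.default_rng(1)
        t, _ = _two_group(rng, effect_on=("TG 40:0",), effect=50.0,
                          sigma=0.05)
        model = op.fit_opls_da(t, ("GA", "GB"), n_orthogonal=1)
        assert model.corr.abs().idxmax() == "TG 40:0"
        # the S-plot correlation relates the *filtered* score to the
        # *unfiltered* variable, so even a perfect discriminator sits
        # slightly below 1
        assert abs(model.corr["TG 40:0"]) > 0.9

    def test_zero_orthogonal_equals_plain_pls(self):
        """Oracle: with no orthogonal rounds the score is the direct
        X'y projection."""
        rng = np.random.default_rng(2)
        t, design = _two_group(rng, effect_on=("TG 42:1",))
        model = op.fit_opls_da(t, ("GA", "GB"), n_orthogonal=0, scale="uv")
        X = t.data.T.reindex(model.samples).to_numpy()
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.array([1.0 if design[s] == "GA" else -1.0
                      for s in model.samples])
        w_ref = X.T @ y
        w_ref /= np.linalg.norm(w_ref)
        np.testing.assert_allclose(model.w, w_ref, atol=1e-10)
        np.testing.assert_allclose(model.t, X @ w_ref, atol=1e-10)

    def test_toy_matrix_matches_hand_executed_steps(self, make_table):
        """4x3 toy: every intermediate of the single orthogonal round is
        recomputed step by step with plain numpy."""
        t = make_table({"TG 40:0": [1.0, 2.0, 6.0, 5.0],
                        "TG 42:1": [2.0, 1.0, 4.0, 6.0],
                        "TG 44:2": [9.0, 7.0, 2.0, 1.0]},
                       ["a1", "a2", "b1", "b2"],
                       design={"a1": "GA", "a2": "GA",
                               "b1": "GB", "b2": "GB"})
        model = op.fit_opls_da(t, ("GA", "GB"), n_orthogonal=1, scale="uv")
        X = t.data.T.to_numpy()
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.array([1.0, 1.0, -1.0, -1.0])
        w = X.T @ y
        w /= np.linalg.norm(w)
        tt = X @ w
        p = X.T @ tt / (tt @ tt)
        w_o = p - (w @ p) * w
        w_o /= np.linalg.norm(w_o)
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        Xf = X - np.outer(t_o, p_o)
        t_pred = Xf @ w
        np.testing.assert_allclose(model.t, t_pred, atol=1e-12)
        np.testing.assert_allclose(model.orthogonal[0][1], t_o, atol=1e-12)
        np.testing.assert_allclose(model.p, Xf.T @ t_pred / (t_pred @ t_pred),
                                   atol=1e-12)

    def test_class_coding_is_alphabetical(self):
        rng = np.random.default_rng(3)
        t, _ = _two_group(rng, effect_on=("TG 42:1",))
        model = op.fit_opls_da(t, ("GB", "GA"))
        assert model.positive_group == "GA"
        assert set(model.y[[s for s in model.samples
                            if s.startswith("a")]]) == {1.0}

    def test_one_class_errors(self):
        rng = np.random.default_rng(4)
        t, _ = _two_group(rng)
        with pytest.raises(op.OplsError):
            op.fit_opls_da(t, ("GA", "GA"))


class TestInvariants:
    @pytest.mark.parametrize("n_orth", [1, 2])
    def test_orthogonal_scores_perpendicular_to_predictive(self, n_orth):
        rng = np.random.default_rng(5)
        t, _ = _two_group(rng, n_species=10, effect_on=("TG 42:1",))
        model = op.fit_opls_da(t, ("GA", "GB"), n_orthogonal=n_orth)
        for _, t_o, _ in model.orthogonal:
            assert abs(t_o @ model.t) < 1e-8 * np.linalg.norm(t_o) \
                * np.linalg.norm(model.t) + 1e-8

    def test_frobenius_variance_accounting(self):
        rng = np.random.default_rng(6)
        t, design = _two_group(rng, n_species=10, effect_on=("TG 42:1",))
        model = op.fit_opls_da(t, ("GA", "GB"), n_orthogonal=2)
        X0 = t.data.T.reindex(model.samples).to_numpy()
        X0 = (X0 - X0.mean(0)) / X0.std(0, ddof=1)
        removed = sum(np.linalg.norm(np.outer(t_o, p_o), "fro") ** 2
                      for _, t_o, p_o in model.orthogonal)
        Xf = X0.copy()
        for _, t_o, p_o in model.orthogonal:
            Xf = Xf - np.outer(t_o, p_o)
        lhs = np.linalg.norm(X0, "fro") ** 2
        rhs = np.linalg.norm(Xf, "fro") ** 2 + removed
        assert rhs == pytest.approx(lhs, rel=1e-6)

    def test_filtering_never_hurts_predictive_correlation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t, design = _two_group(rng, n_species=12,
                                   effect_on=("TG 42:1", "TG 46:3"),
                                   effect=rng.uniform(1.5, 4))
            y = None
            m0 = op.fit_opls_da(t, ("GA", "GB"), n_orthogonal=0)
            m1 = op.fit_opls_da(t, ("GA", "GB"), n_orthogonal=1)
            y = m0.y.to_numpy()
            c0 = abs(np.corrcoef(m0.t, y)[0, 1])
            c1 = abs(np.corrcoef(m1.t, y)[0, 1])
            assert c1 >= c0 - 1e-8


class TestSPlot:
    def test_splot_axes(self):
        rng = np.random.default_rng(8)
        t, _ = _two_group(rng, effect_on=("TG 40:0",), effect=10.0)
        model = op.fit_opls_da(t, ("GA", "GB"))
        sp = op.s_plot(model)
        assert set(sp.columns) == {"loading", "correlation"}
        assert sp["correlation"].dropna().between(-1, 1).all()

    def test_correlations_match_direct_pearson(self):
        """Brute-force oracle on 100 random instances."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            t, _ = _two_group(rng, n_species=6,
                              effect_on=("TG 42:1",),
                              effect=rng.uniform(1.2, 5))
            model = op.fit_opls_da(t, ("GA", "GB"))
            X = t.data.T.reindex(model.samples).to_numpy()
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            for i, sp_name in enumerate(model.species):
                ref = np.corrcoef(model.t, X[:, i])[0, 1]
                assert model.corr[sp_name] == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_species_gets_missing_correlation(self, make_table):
        t = make_table({"TG 40:0": [1, 2, 6, 5], "TG 42:1": [2, 1, 4, 6],
                        "TG 44:2": [3, 3, 3, 3]},
                       ["a1", "a2", "b1", "b2"],
                       design={"a1": "GA", "a2": "GA",
                               "b1": "GB", "b2": "GB"})
        model = op.fit_opls_da(t, ("GA", "GB"))
        assert np.isnan(model.corr["TG 44:2"])


class TestWeightedLoadingsAndSelection:
    def test_zero_corr_gives_zero_weighted_loading(self, make_table):
        t = make_table({"TG 40:0": [1, 2, 6, 5], "TG 42:1": [2, 1, 4, 6],
                        "TG 44:2": [3, 3, 3, 3]},
                       ["a1", "a2", "b1", "b2"],
                       design={"a1": "GA", "a2": "GA",
                               "b1": "GB", "b2": "GB"})
        model = op.fit_opls_da(t, ("GA", "GB"))
        assert op.weighted_loadings(model)["TG 44:2"] == 0.0

    def test_unit_corr_keeps_loading(self):
        rng = np.random.default_rng(10)
        t, _ = _two_group(rng, effect_on=("TG 40:0",), effect=100.0,
                          sigma=0.01)
        model = op.fit_opls_da(t, ("GA", "GB"))
        wl = op.weighted_loadings(model)
        p = pd.Series(model.p, index=model.species)
        sp = "TG 40:0"
        assert wl[sp] == pytest.approx(
            p[sp] * abs(model.corr[sp]))
        assert abs(model.corr[sp]) > 0.9

    def test_empty_selection_is_not_an_error(self):
        rng = np.random.default_rng(11)
        t, _ = _two_group(rng, effect_on=(), sigma=0.4)
        model = op.fit_opls_da(t, ("GA", "GB"))
        sel = op.select_discriminants(model, corr_threshold=0.999999,
                                      loading_quantile=1.0)
        assert sel.positive == [] or sel.negative == []

    def test_lowering_corr_threshold_never_shrinks(self):
        rng = np.random.default_rng(12)
        t, _ = _two_group(rng, n_species=12,
                          effect_on=("TG 42:1", "TG 46:3"), effect=3.0)
        model = op.fit_opls_da(t, ("GA", "GB"))
        prev_pos, prev_neg = set(), set()
        for thr in (0.95, 0.8, 0.5, 0.2, 0.05):
            sel = op.select_discriminants(model, corr_threshold=thr,
                                          loading_quantile=0.5)
            assert set(sel.positive) >= prev_pos
            assert set(sel.negative) >= prev_neg
            prev_pos, prev_neg = set(sel.positive), set(sel.negative)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.2])
    def test_threshold_validation(self, bad):
        rng = np.random.default_rng(13)
        t, _ = _two_group(rng, effect_on=("TG 42:1",))
        model = op.fit_opls_da(t, ("GA", "GB"))
        with pytest.raises(op.OplsError):
            op.select_discriminants(model, corr_threshold=bad)

    def test_planted_discriminators_recovered_by_sign(self):
        """Species raised in the +1-coded group land in the positive
        subset and vice versa, over 50 random instances."""
        recovered = 0
        planted_total = 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            up_in_a = ("TG 40:0", "TG 44:2")    # GA is coded +1
            t, _ = _two_group(rng, n_species=10, effect_on=up_in_a,
                              effect=3.0)
            down = "TG 46:3"
            t.data.loc[down, [s for s in t.samples if s[0] == "a"]] *= 0.3
            model = op.fit_opls_da(t, ("GA", "GB"))
            sel = op.select_discriminants(model, corr_threshold=0.7,
                                          loading_quantile=0.7)
            planted_total += 3
            recovered += sum(sp in sel.positive for sp in up_in_a)
            recovered += int(down in sel.negative)
        assert recovered / planted_total >= 0.8


class TestEvaluateSubsets:
    def test_full_subset_matches_full_pca(self):
        rng = np.random.default_rng(14)
        t, _ = _two_group(rng, n_species=6, effect_on=("TG 42:1",),
                          effect=4.0)
        all_species = t.species_names
        sel = op.SPlotSelection(positive=all_species, negative=[],
                                corr_threshold=0.8, loading_quantile=0.9)
        report = op.evaluate_subsets(sel, t, ("GA", "GB"))
        from dropletomics.pca_phenotyping import fit_pca
        model = fit_pca(t)
        cents = {g: model.scores.loc[[s for s in model.scores.index
                                      if model.design[s] == g]].mean()
                 for g in ("GA", "GB")}
        ref = abs((cents["GA"] - cents["GB"]).iloc[0])
        assert report.loc["positive", "pc1_centroid_distance"] == \
            pytest.approx(ref, rel=1e-9)

    def test_stronger_negative_side_wins_pc1_distance(self):
        rng = np.random.default_rng(15)
        t, _ = _two_group(rng, n_species=12, sigma=0.1)
        # weak positive-side effect, strong negative-side effect
        a_cols = [s for s in t.samples if s[0] == "a"]
        t.data.loc["TG 40:0", a_cols] *= 1.6
        t.data.loc["TG 42:1", a_cols] *= 0.2
        t.data.loc["TG 44:2", a_cols] *= 0.2
        model = op.fit_opls_da(t, ("GA", "GB"))
        sel = op.SPlotSelection(positive=["TG 40:0"],
                                negative=["TG 42:1", "TG 44:2"],
                                corr_threshold=0.8, loading_quantile=0.9)
        report = op.evaluate_subsets(sel, t, ("GA", "GB"))
        assert (report.loc["negative", "pc1_centroid_distance"]
                > report.loc["positive", "pc1_centroid_distance"])

    def test_singleton_subset_is_one_dimensional(self):
        rng = np.random.default_rng(16)
        t, _ = _two_group(rng, n_species=6, effect_on=("TG 42:1",),
                          effect=4.0)
        sel = op.SPlotSelection(positive=["TG 42:1"], negative=[],
                                corr_threshold=0.8, loading_quantile=0.9)
        report = op.evaluate_subsets(sel, t, ("GA", "GB"))
        assert report.loc["positive", "pc1_separation_share"] == \
            pytest.approx(1.0)
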