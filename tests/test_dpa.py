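"""Differential proportion analysis: tabulation, bootstrap, count
normalization, Poisson GLM oracles, Rubin pooling identities, max-|t|
adjustment envelope, and end-to-end recovery behaviour."""


import numpy as np
import pandas as pd
import pytest

from gliapipe import dpa, simulate


def _cell_table(counts: dict) -> pd.DataFrame:
    rows = []
    genotype = {"s1": "g1", "s2": "g2"}
    for (s, c), k in counts.items():
        for i in range(k):
            rows.append((f"{s}_{c}_{i}", s, genotype.get(s, "g1"), c))
    return pd.DataFrame(rows, columns=["cell_id", "sample_id", "genotype", "cluster"])


class TestTabulate:
    def test_counts_reproduced_exactly(self):
        cells = _cell_table({("s1", "A"): 90, ("s1", "B"): 10, ("s2", "A"): 60, ("s2", "B"): 40})
        comp = dpa.tabulate_composition(cells)
        lookup = comp.set_index(["sample_id", "cluster"])["cell_count"]
        assert lookup["s1", "A"] == 90 and lookup["s1", "B"] == 10
        assert lookup["s2", "A"] == 60 and lookup["s2", "B"] == 40

    def test_missing_combination_zero_filled(self):
        cells = _cell_table({("s1", "A"): 5, ("s1", "B"): 3, ("s2", "A"): 4})
        comp = dpa.tabulate_composition(cells)
        assert comp.set_index(["sample_id", "cluster"])["cell_count"]["s2", "B"] == 0

    def test_per_sample_conservation(self):
        cells = _cell_table({("s1", "A"): 7, ("s1", "B"): 5, ("s2", "A"): 2, ("s2", "B"): 9})
        comp = dpa.tabulate_composition(cells)
        sums = comp.groupby("sample_id")["cell_count"].sum()
        assert sums["s1"] == 12 and sums["s2"] == 11

    def test_unknown_cluster_rejected(self):
        cells = _cell_table({("s1", "A"): 2, ("s2", "Z"): 2})
        with pytest.raises(ValueError, match="not in roster"):
            dpa.tabulate_composition(cells, clusters=["A", "B"])


class TestBootstrap:
    def test_mean_replicate_proportion_unbiased(self):
        cells = _cell_table({("s1", "A"): 120, ("s1", "B"): 80})
        comp = dpa.tabulate_composition(cells)
        reps = dpa.stratified_bootstrap(comp, B=3000, seed=1)
        props = [
            r.set_index(["sample_id", "cluster"])["cell_count"]["s1", "A"] / 200 for r in reps
        ]
        p = 0.6
        mc_se = np.sqrt(p * (1 - p) / 200) / np.sqrt(len(reps))
        assert abs(np.mean(props) - p) < 3 * mc_se

    def test_totals_preserved_per_replicate(self):
        cells = _cell_table({("s1", "A"): 30, ("s1", "B"): 20, ("s2", "A"): 15, ("s2", "B"): 35})
        comp = dpa.tabulate_composition(cells)
        for rep in dpa.stratified_bootstrap(comp, B=20, seed=2):
            sums = rep.groupby("sample_id")["cell_count"].sum()
            assert sums["s1"] == 50 and sums["s2"] == 50

    def test_single_cell_stratum_degenerate(self):
        cells = _cell_table({("s1", "A"): 1, ("s2", "A"): 3, ("s2", "B"): 2})
        comp = dpa.tabulate_composition(cells)
        for rep in dpa.stratified_bootstrap(comp, B=10, seed=3):
            assert rep.set_index(["sample_id", "cluster"])["cell_count"]["s1", "A"] == 1

    def test_seed_reproducibility(self):
        cells = _cell_table({("s1", "A"): 30, ("s1", "B"): 20})
        comp = dpa.tabulate_composition(cells)
        a = dpa.stratified_bootstrap(comp, B=5, seed=42)
        b = dpa.stratified_bootstrap(comp, B=5, seed=42)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestNormalize:
    @pytest.mark.parametrize(
        "counts,target,expected",
        [((120, 80), 150, (90, 60)), ((50, 50), 150, (75, 75))],
    )
    def test_exact_proportional_scaling(self, counts, target, expected):
        comp = pd.DataFrame(
            [("s1", "g1", c, k) for c, k in zip("AB", counts)],
            columns=["sample_id", "genotype", "cluster", "cell_count"],
        )
        out = dpa.normalize_counts(comp, target)
        assert tuple(out["cell_count"]) == expected

    def test_largest_remainder_property(self):
        comp = pd.DataFrame(
            [("s1", "g1", c, 1) for c in "ABC"],
            columns=["sample_id", "genotype", "cluster", "cell_count"],
        )
        out = dpa.normalize_counts(comp, 100)
        counts = out["cell_count"].to_numpy()
        assert counts.sum() == 100
        assert counts.max() - counts.min() <= 1

    def test_equal_totals_across_samples(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in ["s1", "s2", "s3"]:
            for c in "ABCD":
                rows.append((s, "g1", c, int(rng.integers(1, 500))))
        comp = pd.DataFrame(rows, columns=["sample_id", "genotype", "cluster", "cell_count"])
        out = dpa.normalize_counts(comp, "mean")
        totals = out.groupby("sample_id")["cell_count"].sum()
        assert totals.nunique() == 1


class TestPoissonGLM:
    def test_saturated_fit_reproduces_counts(self):
        comp = pd.DataFrame(
            [("a", "g1", "A", 90), ("a", "g1", "B", 10), ("b", "g2", "A", 60), ("b", "g2", "B", 40)],
            columns=["sample_id", "genotype", "cluster", "cell_count"],
        )
        fit = dpa.fit_poisson_glm(comp, clusters=["A", "B"], genotypes=["g1", "g2"])
        assert fit.converged
        np.testing.assert_allclose(fit.fitted, [90, 10, 60, 40], atol=1e-8)

    def test_interaction_equals_log_odds_ratio(self):
        """Counts g1:(A 90, B 10), g2:(A 60, B 40): the (B, g2)
        interaction is log((40*90)/(60*10)) = log 6."""
        comp = pd.DataFrame(
            [("a", "g1", "A", 90), ("a", "g1", "B", 10), ("b", "g2", "A", 60), ("b", "g2", "B", 40)],
            columns=["sample_id", "genotype", "cluster", "cell_count"],
        )
        fit = dpa.fit_poisson_glm(comp, clusters=["A", "B"], genotypes=["g1", "g2"])
        coef = dict(zip(fit.colnames, fit.params))
        assert coef["cluster[T.B]:genotype[T.g2]"] == pytest.approx(np.log(6), abs=1e-8)

    def test_flat_table_has_zero_effects(self):
        comp = pd.DataFrame(
            [(g, g, c, 25) for g in ["g1", "g2"] for c in "AB"],
            columns=["sample_id", "genotype", "cluster", "cell_count"],
        )
        fit = dpa.fit_poisson_glm(comp, clusters=["A", "B"], genotypes=["g1", "g2"])
        coef = dict(zip(fit.colnames, fit.params))
        for name, val in coef.items():
            if name != "Intercept":
                assert val == pytest.approx(0.0, abs=1e-8)

    def test_missing_cell_rejected(self):
        comp = pd.DataFrame(
            [("a", "g1", "A", 5), ("b", "g2", "A", 5), ("b", "g2", "B", 5)],
            columns=["sample_id", "genotype", "cluster", "cell_count"],
        )
        with pytest.raises(ValueError, match="observation"):
            dpa.fit_poisson_glm(comp, clusters=["A", "B"], genotypes=["g1", "g2"])


class TestRubinPooling:
    def test_worked_example(self):
        """Estimates {1.0, 1.2, 0.8} with variance 0.04: q_bar = 1,
        B = 0.04, T = 0.04 + (4/3)(0.04) = 0.09333..., SE ~ 0.3055."""
        pc = dpa.pool_rubin([1.0, 1.2, 0.8], [0.04, 0.04, 0.04])
        assert pc.q_bar == pytest.approx(1.0, abs=1e-12)
        assert pc.B_between == pytest.approx(0.04, abs=1e-12)
        assert pc.T_total == pytest.approx(0.04 + (4 / 3) * 0.04, abs=1e-12)
        assert np.sqrt(pc.T_total) == pytest.approx(0.30550, abs=1e-4)

    def test_identical_estimates_collapse_to_within_variance(self):
        pc = dpa.pool_rubin([0.7, 0.7, 0.7, 0.7], [0.09] * 4)
        assert pc.B_between == 0.0
        assert pc.T_total == pytest.approx(0.09)

    def test_order_invariance(self):
        a = dpa.pool_rubin([1.0, 1.2, 0.8], [0.04, 0.05, 0.06])
        b = dpa.pool_rubin([0.8, 1.0, 1.2], [0.06, 0.04, 0.05])
        assert a.q_bar == pytest.approx(b.q_bar)
        assert a.T_total == pytest.approx(b.T_total)
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_pooled_estimate_is_mean_of_replicates(self):
        rng = np.random.default_rng(5)
        est = rng.normal(size=40)
        var = rng.uniform(0.01, 0.1, size=40)
        pc = dpa.pool_rubin(est, var)
        assert pc.q_bar == pytest.approx(est.mean(), abs=1e-14)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            dpa.pool_rubin([1.0], [0.1])


class TestMaxTAdjustment:
    def test_family_of_one_unchanged(self):
        comp = pd.DataFrame(
            [("a", "g1", "A", 90), ("a", "g1", "B", 10), ("b", "g2", "A", 60), ("b", "g2", "B", 40)],
            columns=["sample_id", "genotype", "cluster", "cell_count"],
        )
        res = dpa.run_dpa(composition=comp, clusters=["A", "B"], genotypes=["g1", "g2"], B=50, seed=0)
        assert np.allclose(res.contrasts["p_adj"], res.contrasts["p_raw"])

    def test_adjustment_monotone_over_six_pairs(self):
        cfg = simulate.SimConfig(cells_per_mouse=800.0, seed=43)
        comp = simulate.gen_composition(cfg)
        res = dpa.run_dpa(
            composition=comp.table, clusters=list(cfg.clusters), genotypes=list(cfg.genotypes), B=60, seed=0
        )
        assert len(res.contrasts) == 8 * 6
        assert (res.contrasts["p_adj"] >= res.contrasts["p_raw"] - 1e-12).all()

    def test_independent_contrasts_match_sidak_envelope(self):
        """For 6 independent contrasts the single-step max-|t| adjusted
        p equals the Sidak value 1 - (1 - p)^6."""
        from scipy import stats as st

        z = st.norm.isf(0.01)  # raw two-sided p = 0.02
        adj = dpa._maxt_adjust(np.full(6, z), np.full(6, np.inf), np.eye(6), seed=0)
        expected = 1 - 0.98**6
        assert np.allclose(adj, expected, atol=2e-3)


class TestRunDPA:
    def test_relabeling_clusters_preserves_pvalues(self):
        cfg = simulate.SimConfig(cells_per_mouse=600.0, seed=47)
        comp = simulate.gen_composition(cfg).table
        res_a = dpa.run_dpa(
            composition=comp, clusters=list(cfg.clusters), genotypes=list(cfg.genotypes), B=40, seed=9
        )
        mapping = {c: f"state_{i}" for i, c in enumerate(cfg.clusters)}
        comp_b = comp.assign(cluster=comp["cluster"].map(mapping))
        res_b = dpa.run_dpa(
            composition=comp_b,
            clusters=[mapping[c] for c in cfg.clusters],
            genotypes=list(cfg.genotypes),
            B=40,
            seed=9,
        )
        np.testing.assert_allclose(
            res_a.contrasts["p_raw"].to_numpy(), res_b.contrasts["p_raw"].to_numpy()
        )

    def test_power_monotone_in_fold_change(self):
        """Simulated detection of an enriched cluster never degrades as
        the injected fold grows 1x -> 2x -> 4x."""
        powers = []
        for fold in (1.0, 2.0, 4.0):
            hits = 0
            for r in range(12):
                cfg = simulate.SimConfig(
                    effect_matrix={"hPS-5X": {"IFN": fold}},
                    mice_per_genotype=2,
                    cells_per_mouse=2000.0,
                    seed=60_000 + r,
                )
                comp = simulate.gen_composition(cfg)
                res = dpa.run_dpa(
                    composition=comp.table,
                    clusters=list(cfg.clusters),
                    genotypes=list(cfg.genotypes),
                    B=60,
                    seed=r,
                )
                row = res.contrasts[
                    (res.contrasts["cluster"] == "IFN")
                    & (res.contrasts["genotype_a"] == "hWT")
                    & (res.contrasts["genotype_b"] == "hPS-5X")
                ].iloc[0]
                hits += row["p_adj"] < 0.05
            powers.append(hits)
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] >= 11  # 4-fold enrichment is essentially always seen

    def test_proportion_summary_matches_observed(self):
        cfg = simulate.SimConfig(cells_per_mouse=1500.0, seed=53, effect_matrix={})
        comp = simulate.gen_composition(cfg)
        res = dpa.run_dpa(
            composition=comp.table, clusters=list(cfg.clusters), genotypes=list(cfg.genotypes), B=80, seed=1
        )
        # bootstrap-mean proportions track the observed genotype proportions
        obs = (
            comp.table.groupby(["genotype", "cluster"], sort=False)["cell_count"].sum()
            / comp.table.groupby("genotype")["cell_count"].sum()
        )
        for _, row in res.proportions.iterrows():
            assert row["mean_prop"] == pytest.approx(obs[row["genotype"], row["cluster"]], abs=0.02)
        assert (res.proportions["sd_prop"] > 0).any()

    def test_manifest_records_run_conditions(self):
        cfg = simulate.SimConfig(cells_per_mouse=400.0, seed=59)
        comp = simulate.gen_composition(cfg)
        res = dpa.run_dpa(
            composition=comp.table, clusters=list(cfg.clusters), genotypes=list(cfg.genotypes), B=30, seed=2
        )
        assert res.manifest["B"] == 30
        assert res.manifest["observation_unit"] == "sample"
        assert res.manifest["dropped"] <= 0.01 * 30

    @pytest.mark.parametrize("kwargs", [{"observation_unit": "genotype"}, {"normalize": "before"}])
    def test_config_switches_run_and_are_recorded(self, kwargs):
        cfg = simulate.SimConfig(cells_per_mouse=500.0, seed=67)
        comp = simulate.gen_composition(cfg)
        res = dpa.run_dpa(
            composition=comp.table, clusters=list(cfg.clusters),
            genotypes=list(cfg.genotypes), B=30, seed=3, **kwargs
        )
        assert len(res.contrasts) == 8 * 6
        for k, v in kwargs.items():
            assert res.manifest[k] == v

    def test_requires_two_groups(self):
        comp = pd.DataFrame(
            [("a", "g1", "A", 5), ("a", "g1", "B", 5)],
            columns=["sample_id", "genotype", "cluster", "cell_count"],
        )
        with pytest.raises(ValueError, match="at least 2"):
            dpa.run_dpa(composition=comp, B=10)
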