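"""Cross-validation machinery, accuracy metrics and model comparison."""

import numpy as np
import pandas as pd
import pytest

import maizegp as mg
from maizegp.evaluate import pivot_accuracy_table, run_scenario_two


class TestSplits:
    def test_sizes_partition_and_determinism(self, small_phenotypes):
        records, _ = small_phenotypes
        splits = mg.make_random_splits(records, 0.8, 3, seed=1)
        lines = set(records["line"])
        for s in splits:
            assert len(s.train_lines) == round(0.8 * len(lines))
            assert set(s.train_lines) | set(s.val_lines) == lines
            assert set(s.train_lines) & set(s.val_lines) == set()
        again = mg.make_random_splits(records, 0.8, 3, seed=1)
        assert [s.train_lines for s in splits] == [s.train_lines for s in again]

    def test_too_few_validation_lines_raises(self, small_phenotypes):
        records, _ = small_phenotypes
        with pytest.raises(ValueError):
            mg.make_random_splits(records, 0.999, 1, seed=1)


class TestPearsonAccuracy:
    def test_perfect_and_inverted(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        assert mg.pearson_accuracy(y, y) == pytest.approx(1.0)
        assert mg.pearson_accuracy(y, -y) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 1, sd_x = 1, sd_y = sqrt(13/12): r = sqrt(12/13) = 0.961
        r = mg.pearson_accuracy([1, 2, 3], [2, 2.5, 4])
        assert round(r, 3) == 0.961

    def test_constant_vector_flagged_nan(self):
        assert np.isnan(mg.pearson_accuracy([1, 1, 1], [1, 2, 3]))


class TestRelativeImprovement:
    def _table(self):
        rows = []
        for env in ("E1", "E2"):
            for trait in ("FF", "MF"):
                for cyc in (1, 2):
                    rows.append(("m", "UTUE", env, trait, cyc, 0.40))
                    rows.append(("m", "MTUE", env, trait, cyc, 0.50))
        return pd.DataFrame(
            rows, columns=["model", "approach", "environment", "trait", "cycle", "pearson_r"]
        )

    def test_identical_selection_zero(self):
        t = self._table()
        assert mg.relative_improvement(t, {"approach": "UTUE"}, {"approach": "UTUE"}) == 0.0

    def test_arithmetic(self):
        t = self._table()
        gain = mg.relative_improvement(t, {"approach": "UTUE"}, {"approach": "MTUE"})
        assert gain == pytest.approx(25.0)

    def test_swapped_selectors_change_sign_of_numerator(self):
        t = self._table()
        fwd = mg.relative_improvement(t, {"approach": "UTUE"}, {"approach": "MTUE"})
        rev = mg.relative_improvement(t, {"approach": "MTUE"}, {"approach": "UTUE"})
        assert fwd > 0 > rev

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            mg.relative_improvement(self._table(), {"approach": "XX"}, {"approach": "MTUE"})


class TestCompareModels:
    def _table(self, shift=0.0, sd=0.01, n=8):
        rng = np.random.default_rng(0)
        rows = []
        for model, mu in (("a_model", 0.5), ("b_model", 0.5 + shift)):
            for cyc in range(n):
                rows.append((model, "UTUE", "E1", "FF", cyc, mu + sd * rng.standard_normal()))
        return pd.DataFrame(
            rows, columns=["model", "approach", "environment", "trait", "cycle", "pearson_r"]
        )

    def test_identical_distributions_share_letter(self):
        t = self._table(shift=0.0)
        # give both models the same multiset of cycle accuracies
        vals = t.loc[t.model == "a_model", "pearson_r"].to_numpy()
        t.loc[t.model == "b_model", "pearson_r"] = vals[::-1]
        letters = mg.compare_models(t, {"environment": "E1", "trait": "FF"}, alpha=0.01)
        assert letters["a_model"] == letters["b_model"]

    def test_separated_distributions_get_different_letters(self):
        t = self._table(shift=0.5)
        letters = mg.compare_models(t, {"environment": "E1", "trait": "FF"}, alpha=0.01)
        assert set(letters["a_model"]) & set(letters["b_model"]) == set()

    def test_letters_independent_of_input_order(self):
        t = self._table(shift=0.5)
        l1 = mg.compare_models(t, {"environment": "E1", "trait": "FF"})
        l2 = mg.compare_models(t.iloc[::-1].reset_index(drop=True), {"environment": "E1", "trait": "FF"})
        assert l1 == l2

    def test_identical_cycle_vectors_share_letter(self):
        t = self._table(shift=0.0, sd=0.0)
        letters = mg.compare_models(t, {"environment": "E1", "trait": "FF"})
        assert letters["a_model"] == letters["b_model"] == "a"


class TestScenarioOne:
    def test_unsupported_pair_raises(self, small_phenotypes, small_grm):
        records, _ = small_phenotypes
        with pytest.raises(ValueError, match="not supported"):
            mg.run_scenario_one(
                records, small_grm, ["bgge"], ["UTUE"], mg.CVScheme(n_cycles=1, seed=1)
            )

    def test_row_count_bookkeeping(self, small_phenotypes, small_grm, tiny_settings):
        records, _ = small_phenotypes
        table = mg.run_scenario_one(
            records,
            small_grm,
            ["mcmc_mixed"],
            ["UTUE", "MTUE"],
            mg.CVScheme(n_cycles=2, seed=3),
            settings=tiny_settings,
        )
        # 1 model x 2 approaches x 2 environments x 3 traits x 2 cycles
        assert len(table) == 2 * 2 * 3 * 2
        assert table["pearson_r"].between(-1, 1).all()

    def test_reproducible_under_seed(self, small_phenotypes, small_grm, tiny_settings):
        records, _ = small_phenotypes
        kw = dict(settings=tiny_settings, mlp_config=mg.MLPConfig(epochs=10))
        t1 = mg.run_scenario_one(
            records, small_grm, ["dl"], ["UTUE"], mg.CVScheme(n_cycles=1, seed=4), **kw
        )
        t2 = mg.run_scenario_one(
            records, small_grm, ["dl"], ["UTUE"], mg.CVScheme(n_cycles=1, seed=4), **kw
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_noiseless_trait_recovered(self, tiny_settings):
        # family-structured panel (near-duplicate sibs) so held-out lines are
        # genuinely related to training lines; with h2 = 1 the kinship model
        # must then recover the phenotype almost exactly
        founders = mg.simulate_genotypes(n_lines=50, n_markers=1000, n_chromosomes=5, seed=55)
        rng = np.random.default_rng(56)
        dosage = np.repeat(founders.dosage, 4, axis=0)
        flips = rng.random(dosage.shape) < 0.02
        dosage[flips] = 2.0 - dosage[flips]
        panel = mg.GenotypePanel(
            line_ids=[f"L{i:03d}" for i in range(200)],
            marker_ids=founders.marker_ids,
            chromosome=founders.chromosome,
            position_bp=founders.position_bp,
            dosage=dosage,
        )
        grm = mg.vanraden_grm(panel)
        cfg = mg.TraitConfig(
            trait_names=("FF",), target_h2={"FF": 1.0}, asi_is_difference=False,
            gxe_variance_share=0.0,
        )
        rec, _ = mg.simulate_phenotypes(panel, cfg, ("E1",), seed=6, n_replicates=1)
        table = mg.run_scenario_one(
            rec, grm, ["mcmc_mixed"], ["UTUE"],
            mg.CVScheme(n_cycles=2, seed=7), settings=tiny_settings,
        )
        assert table["pearson_r"].mean() >= 0.9


class TestScenarioTwo:
    def test_target_overlap_raises(self, small_phenotypes, small_grm):
        records, _ = small_phenotypes
        with pytest.raises(ValueError, match="overlap"):
            run_scenario_two(
                records, small_grm, ["mcmc_mixed"], "DT1", {"DT1": ["E2"]}, "E2"
            )

    def test_dt3_is_union_of_dt1_and_dt2(self):
        sets = {"DT1": ["E3"], "DT2": ["E1", "E2"], "DT3": ["E1", "E2", "E3"]}
        assert sorted(sets["DT1"] + sets["DT2"]) == sorted(sets["DT3"])

    def test_copied_environment_predicts_itself(self, small_panel, small_grm, tiny_settings):
        """Training on an environment identical to the target recovers it."""
        cfg = mg.TraitConfig(
            trait_names=("FF",), target_h2={"FF": 0.95}, asi_is_difference=False,
            gxe_variance_share=0.0,
        )
        rec, _ = mg.simulate_phenotypes(small_panel, cfg, ("E1",), seed=8, n_replicates=1)
        copy = rec.copy()
        copy["environment"] = "E2"
        both = pd.concat([rec, copy], ignore_index=True)
        table = run_scenario_two(
            both, small_grm, ["mcmc_mixed"], "DT1", {"DT1": ["E1"]}, "E2",
            settings=mg.MCMCSettings(3000, 800, 2, seed=9),
        )
        assert (table["pearson_r"] >= 0.95).all()

    def test_accuracy_tracks_cross_environment_correlation(self, small_panel, small_grm):
        """A trait with strong G x E transfers worse across environments."""
        wins = 0
        for seed in range(6):
            stable = mg.TraitConfig(
                trait_names=("FF",), target_h2={"FF": 0.7}, asi_is_difference=False,
                gxe_variance_share=0.0,
            )
            unstable = mg.TraitConfig(
                trait_names=("FF",), target_h2={"FF": 0.7}, asi_is_difference=False,
                gxe_variance_share=0.8,
            )
            acc = {}
            for name, cfg in (("stable", stable), ("unstable", unstable)):
                rec, _ = mg.simulate_phenotypes(
                    small_panel, cfg, ("E1", "E2"), seed=20 + seed, n_replicates=1
                )
                t = run_scenario_two(
                    rec, small_grm, ["mcmc_mixed"], "DT1", {"DT1": ["E1"]}, "E2",
                    settings=mg.MCMCSettings.tiny(seed),
                )
                acc[name] = t["pearson_r"].mean()
            wins += acc["stable"] > acc["unstable"]
        assert wins >= 5


def test_accuracy_table_round_trips_through_tsv(tmp_path, small_phenotypes, small_grm, tiny_settings):
    records, _ = small_phenotypes
    table = mg.run_scenario_one(
        records, small_grm, ["mcmc_mixed"], ["UTUE"],
        mg.CVScheme(n_cycles=1, seed=10), settings=tiny_settings,
    )
    path = tmp_path / "acc.tsv"
    table.to_csv(path, sep="\t", index=False)
    back = pd.read_csv(path, sep="\t")
    pd.testing.assert_frame_equal(table, back)
    pivot = pivot_accuracy_table(table)
    assert pivot.shape[0] == table.groupby(["environment", "trait"]).ngroups
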