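import numpy as np
import pandas as pd
import pytest

import sigrev
from sigrev.connectivity import QuerySignature, instance_connectivity
from sigrev.errors import ConfigError, DataError
from sigrev.simulate import (SimulationConfig, simulate_bibliometrics,
                             simulate_expression_pair, simulate_gene_sets,
                             simulate_perturbagen_db)


class TestConfigValidation:
    def test_fractions_summing_above_one_rejected(self):
        with pytest.raises(ConfigError, match="sum"):
            SimulationConfig(frac_de_shared=0.6, frac_de_private=0.5)

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(ConfigError, match="positive"):
            SimulationConfig(n_case=0)

    def test_too_many_planted_drugs_rejected(self):
        with pytest.raises(ConfigError, match="exceeds"):
            SimulationConfig(n_perturbagens=3, n_reversers=2, n_mimickers=2)


class TestExpressionPair:
    def test_deterministic_under_seed(self, small_sim_config):
        a = simulate_expression_pair(small_sim_config)
        b = simulate_expression_pair(small_sim_config)
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[2].pairs, b[2].pairs)
        pd.testing.assert_frame_equal(a[3].genes, b[3].genes)

    def test_planted_count_forced_by_config(self):
        cfg = SimulationConfig(n_genes=1000, frac_de_shared=0.1, seed=1)
        _, _, _, truth = simulate_expression_pair(cfg)
        assert len(truth.shared_concordant) == 100

    def test_zero_noise_reproduces_planted_logfc_exactly(self):
        cfg = SimulationConfig(n_genes=100, n_case=4, n_control=4,
                               noise_sd=0.0, effect_logfc=2.0, seed=2)
        study_h, _, _, truth = simulate_expression_pair(cfg)
        fit = sigrev.fit_two_groups(study_h)
        planted = truth.genes["true_lfc_human"]
        assert np.allclose(fit["logfc"].to_numpy(), planted.to_numpy())

    def test_ortholog_map_respects_missing_fraction(self):
        cfg = SimulationConfig(n_genes=500, ortholog_missing_frac=0.2, seed=3)
        _, _, omap, truth = simulate_expression_pair(cfg)
        assert len(omap) == 400
        assert (~truth.genes["in_ortholog_map"]).sum() == 100

    def test_mouse_symbols_are_distinct_but_linked(self):
        cfg = SimulationConfig(n_genes=50, seed=4)
        study_h, study_m, omap, _ = simulate_expression_pair(cfg)
        assert not (set(study_h.values.index) & set(study_m.values.index))
        assert set(omap.pairs["human_symbol"]) <= set(study_h.values.index)
        assert set(omap.pairs["mouse_symbol"]) <= set(study_m.values.index)

    def test_null_config_calls_near_nominal_rate(self):
        cfg = SimulationConfig(n_genes=1000, effect_logfc=0.0, seed=8)
        study_h, _, _, _ = simulate_expression_pair(cfg)
        _, _, degs = sigrev.run_de(study_h, alpha=0.05)
        assert 31 <= len(degs) <= 69  # 99% binomial interval, n=1000, p=0.05


class TestPerturbagenDb:
    def test_instance_count_is_product(self, small_sim_config):
        _, _, _, truth = simulate_expression_pair(small_sim_config)
        cfg = sigrev.SimulationConfig(
            **{**small_sim_config.__dict__, "n_perturbagens": 5,
               "instances_per_perturbagen": 4, "n_reversers": 1,
               "n_mimickers": 1})
        db = simulate_perturbagen_db(cfg, truth)
        assert len(db) == 20
        assert len(db.manifest) == 20

    def test_perfect_reverser_places_query_at_wrong_ends(self):
        """reversal_strength=1 (no residual noise): up-tags sink to the
        bottom, down-tags rise to the top, giving a maximally negative raw
        connectivity."""
        cfg = SimulationConfig(n_genes=200, reversal_strength=1.0,
                               n_perturbagens=3, n_reversers=1,
                               n_mimickers=0, seed=5)
        _, _, _, truth = simulate_expression_pair(cfg)
        db = simulate_perturbagen_db(cfg, truth)
        reverser = truth.drugs[truth.drugs["label"] == "reverser"][
            "perturbagen"].iloc[0]
        inst = next(i for i in db.instances if i.perturbagen == reverser)
        q = QuerySignature(up=tuple(sorted(truth.shared_by_sign(True))),
                           down=tuple(sorted(truth.shared_by_sign(False))))
        score = instance_connectivity(q, inst)
        assert score.raw < -1.8  # close to the -2 floor

    def test_neutral_scores_centered_at_zero(self):
        """With reversal_strength 0 every drug is noise; mean scaled ES over
        many instances stays within 3 standard errors of zero."""
        cfg = SimulationConfig(n_genes=300, reversal_strength=0.0,
                               n_perturbagens=70, instances_per_perturbagen=3,
                               n_reversers=0, n_mimickers=0, seed=6)
        _, _, _, truth = simulate_expression_pair(cfg)
        db = simulate_perturbagen_db(cfg, truth)
        q = QuerySignature(up=tuple(sorted(truth.shared_by_sign(True))),
                           down=tuple(sorted(truth.shared_by_sign(False))))
        scores = sigrev.score_screen(q, db.instances)
        es = scores["es"].to_numpy()
        assert len(es) >= 200
        assert abs(es.mean()) < 3 * es.std(ddof=1) / np.sqrt(len(es))

    def test_cell_lines_cover_all_bands_and_pin_planted_drugs(self,
                                                              small_sim_config):
        _, _, _, truth = simulate_expression_pair(small_sim_config)
        db = simulate_perturbagen_db(small_sim_config, truth)
        assert set(db.manifest["cell_line"]) == {"HL60", "MCF7", "PC3"}
        planted = truth.drugs[truth.drugs["label"] != "neutral"]
        assert (planted["cell_line"] == "HL60").all()

    def test_signatureless_truth_rejected(self):
        cfg = SimulationConfig(n_genes=50, effect_logfc=0.0, seed=7)
        _, _, _, truth = simulate_expression_pair(cfg)
        with pytest.raises(DataError, match="signature"):
            simulate_perturbagen_db(cfg, truth)


class TestBibliometrics:
    def test_deterministic_and_within_domain(self):
        mols = [f"m{i}" for i in range(50)]
        a = simulate_bibliometrics(mols, seed=1)
        b = simulate_bibliometrics(mols, seed=1)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 50
        assert a["i"].isin([1, 2, 3]).all()
        assert (a["c"] >= 0).all() and (a["p"] >= 0).all()

    def test_zero_rate_gives_all_zero_counts(self):
        out = simulate_bibliometrics(["a", "b"], seed=0, trial_rate=0.0)
        assert (out["c"] == 0).all()

    def test_empty_list_rejected(self):
        with pytest.raises(DataError, match="empty"):
            simulate_bibliometrics([])


def test_gene_sets_include_planted_modules(small_sim_config):
    _, _, _, truth = simulate_expression_pair(small_sim_config)
    sets = simulate_gene_sets(truth, seed=0, n_random=5)
    names = {s.name for s in sets}
    assert {"PLANTED_UP_MODULE", "PLANTED_DOWN_MODULE"} <= names
    up = next(s for s in sets if s.name == "PLANTED_UP_MODULE")
    assert up.genes <= truth.shared_by_sign(True)
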