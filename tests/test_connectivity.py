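from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sigrev
from sigrev.connectivity import (QuerySignature, RankedInstance, build_query,
                                 filter_hits, instance_connectivity,
                                 ks_statistic, scale_scores, score_screen,
                                 summarize_perturbagens)
from sigrev.errors import DataError
from .conftest import make_deg_list


def ks_oracle(tag_ranks, n):
    """Brute-force evaluation of both maxima with explicit loops."""
    v = sorted(tag_ranks)
    t = len(v)
    a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
    b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


def make_instance(genes, perturbagen="drug", cell_line="HL60", iid="i1"):
    return RankedInstance(instance_id=iid, perturbagen=perturbagen,
                          cell_line=cell_line, genes=tuple(genes))


class TestKsStatistic:
    def test_top_heavy_tags(self):
        assert ks_statistic(np.array([1, 2]), 10) == pytest.approx(0.8)

    def test_bottom_heavy_tags(self):
        assert ks_statistic(np.array([9, 10]), 10) == pytest.approx(-0.9)

    def test_exhaustive_oracle_on_all_small_lists(self):
        """Every tag subset of every list length up to 8."""
        for n in range(1, 9):
            for t in range(1, n + 1):
                for ranks in combinations(range(1, n + 1), t):
                    got = ks_statistic(np.array(ranks), n)
                    assert got == pytest.approx(ks_oracle(ranks, n)), (ranks, n)

    def test_empty_tags_rejected(self):
        with pytest.raises(DataError):
            ks_statistic(np.array([]), 10)


GENES10 = [f"g{i}" for i in range(1, 11)]


class TestInstanceConnectivity:
    def test_hand_composed_raw_score(self):
        inst = make_instance(GENES10)
        query = QuerySignature(up=("g1", "g2"), down=("g9", "g10"))
        score = instance_connectivity(query, inst)
        assert score.ks_up == pytest.approx(0.8)
        assert score.ks_down == pytest.approx(-0.9)
        assert score.raw == pytest.approx(1.7)

    def test_swapping_tag_sets_negates_score(self):
        inst = make_instance(GENES10)
        q = QuerySignature(up=("g1", "g2"), down=("g9", "g10"))
        q_swapped = QuerySignature(up=q.down, down=q.up)
        assert instance_connectivity(q_swapped, inst).raw == pytest.approx(-1.7)

    def test_same_sign_sides_zero_out(self):
        inst = make_instance(GENES10)
        q = QuerySignature(up=("g1", "g2"), down=("g3", "g4"))  # both top-heavy
        assert instance_connectivity(q, inst).raw == 0.0

    def test_absent_tags_dropped_with_counts(self):
        inst = make_instance(GENES10)
        q = QuerySignature(up=("g1", "nope"), down=("g10",))
        score = instance_connectivity(q, inst)
        assert (score.n_up_used, score.n_down_used) == (1, 1)

    def test_fully_absent_side_errors_with_instance_name(self):
        inst = make_instance(GENES10, iid="batch7")
        q = QuerySignature(up=("missing",), down=("g10",))
        with pytest.raises(DataError, match="batch7"):
            instance_connectivity(q, inst)

    @given(st.permutations(GENES10), st.data())
    def test_reversing_ranked_list_flips_sign(self, genes, data):
        """A non-zero combined score changes sign (not necessarily magnitude:
        the rank-based KS statistic carries a 1/t - 1/n offset under list
        reversal) when the reference list is reversed."""
        up = data.draw(st.sets(st.sampled_from(GENES10), min_size=1, max_size=4))
        down = data.draw(
            st.sets(st.sampled_from(sorted(set(GENES10) - up)),
                    min_size=1, max_size=4))
        inst = make_instance(genes)
        q = QuerySignature(up=tuple(sorted(up)), down=tuple(sorted(down)))
        raw = instance_connectivity(q, inst).raw
        raw_rev = instance_connectivity(q, inst.reversed_copy()).raw
        # a reversed non-zero score is never non-zero with the same sign; it
        # may collapse to 0 when a tag set sits exactly at the list midpoint
        # (tie in the two KS maxima)
        assert raw * raw_rev <= 0

    def test_reversal_flips_sign_strictly_off_ties(self):
        inst = make_instance(GENES10)
        q = QuerySignature(up=("g1", "g2"), down=("g9", "g10"))
        raw = instance_connectivity(q, inst).raw
        raw_rev = instance_connectivity(q, inst.reversed_copy()).raw
        assert raw > 0 > raw_rev


class TestScaleScores:
    def test_worked_scaling(self):
        scaled = scale_scores(np.array([1.7, -1.0, 0.85]))
        assert scaled == pytest.approx([1.0, -1.0, 0.5])

    def test_single_positive_self_normalizes(self):
        assert scale_scores(np.array([0.4])) == pytest.approx([1.0])

    def test_all_equal_negative(self):
        assert scale_scores(np.array([-0.3, -0.3])) == pytest.approx([-1.0, -1.0])

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            out = scale_scores(np.zeros(3))
        assert (out == 0).all()

    @given(st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=30))
    def test_bounds_and_extremes(self, raw):
        raw = np.asarray(raw)
        if not (raw != 0).any():
            return
        scaled = scale_scores(raw)
        assert np.all(np.abs(scaled) <= 1 + 1e-12)
        assert np.isclose(np.abs(scaled), 1.0).any()


class TestSummaries:
    def _null_scores(self, rng, n_inst=60):
        return pd.DataFrame({
            "instance_id": [f"i{k}" for k in range(n_inst)],
            "perturbagen": [f"d{k // 3}" for k in range(n_inst)],
            "cell_line": "HL60",
            "es": rng.uniform(-1, 1, n_inst),
        })

    def test_singleton_group_mean(self):
        scores = pd.DataFrame({
            "instance_id": ["i1", "i2"], "perturbagen": ["a", "b"],
            "cell_line": ["HL60", "HL60"], "es": [-0.6, 0.2]})
        out = summarize_perturbagens(scores, n_perm=100, seed=0)
        row = out[out["perturbagen"] == "a"].iloc[0]
        assert row["mean_es"] == pytest.approx(-0.6)
        assert row["n"] == 1

    def test_identical_member_scores_identical_summaries(self):
        scores = pd.DataFrame({
            "instance_id": ["i1", "i2", "i3", "i4"],
            "perturbagen": ["a", "a", "b", "b"],
            "cell_line": "HL60", "es": [0.5, -0.1, 0.5, -0.1]})
        out = summarize_perturbagens(scores, n_perm=500, seed=1)
        a = out[out["perturbagen"] == "a"].iloc[0]
        b = out[out["perturbagen"] == "b"].iloc[0]
        assert a["mean_es"] == b["mean_es"] and a["perm_p"] == b["perm_p"]

    def test_permutation_p_uniform_under_null(self):
        """Group means drawn from the screen's own null give uniform p."""
        from scipy import stats
        rng = np.random.default_rng(99)
        pvals = []
        for rep in range(200):
            scores = self._null_scores(rng)
            out = summarize_perturbagens(scores, n_perm=400, seed=rep)
            pvals.append(out["perm_p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFilterHits:
    SUMMARIES = pd.DataFrame({
        "perturbagen": ["drugA", "drugB", "drugC"],
        "cell_line": ["HL60", "HL60", "MCF7"],
        "mean_es": [-0.5, -0.9, -0.8],
        "n": [3, 2, 5],
        "perm_p": [0.01, 0.02, 0.03],
    })

    def test_default_rule_application(self):
        hits = filter_hits(self.SUMMARIES)
        assert hits["perturbagen"].tolist() == ["drugA"]

    def test_permissive_settings_keep_everything(self):
        hits = filter_hits(self.SUMMARIES, cell_line=None, min_n=1,
                           direction="both")
        assert len(hits) == 3
        assert hits["perturbagen"].tolist() == ["drugB", "drugC", "drugA"]

    def test_empty_summaries(self):
        empty = self.SUMMARIES.iloc[:0]
        assert len(filter_hits(empty, cell_line=None)) == 0

    def test_unknown_cell_line_lists_available(self):
        with pytest.raises(DataError, match="MCF7"):
            filter_hits(self.SUMMARIES, cell_line="A549")


class TestBuildQuery:
    def _csig(self, up, down, pvals):
        human = make_deg_list([(g, 1.0, pvals.get(g, 0.01)) for g in up]
                              + [(g, -1.0, pvals.get(g, 0.01)) for g in down])
        return sigrev.conserved_signature(human, human), human.table

    def test_no_truncation_keeps_all(self):
        csig, table = self._csig(["A", "B", "C"], ["D", "E"], {})
        q = build_query(csig, table, max_per_side=1000)
        assert (len(q.up), len(q.down)) == (3, 2)

    def test_truncation_keeps_smallest_p(self):
        pvals = {f"U{i}": 0.001 * i for i in range(1, 6)}
        csig, table = self._csig(list(pvals), ["D1"], pvals)
        q = build_query(csig, table, max_per_side=3)
        assert set(q.up) == {"U1", "U2", "U3"}

    def test_p_ties_break_lexicographically(self):
        csig, table = self._csig(["B", "A", "C"], ["D"], {})
        q = build_query(csig, table, max_per_side=2)
        assert q.up == ("A", "B")

    def test_empty_side_rejected(self):
        human = make_deg_list([("A", 1.0)])
        csig = sigrev.conserved_signature(human, human)
        with pytest.raises(DataError, match="down"):
            build_query(csig, human.table)


def test_screen_recovers_planted_reversers_and_mimicker_sign(small_sim_config):
    _, _, _, truth = sigrev.simulate_expression_pair(small_sim_config)
    db = sigrev.simulate_perturbagen_db(small_sim_config, truth)
    up = tuple(sorted(truth.shared_by_sign(True)))
    down = tuple(sorted(truth.shared_by_sign(False)))
    scores = score_screen(QuerySignature(up=up, down=down), db.instances)
    summaries = summarize_perturbagens(scores, n_perm=200, seed=0)
    labels = truth.drug_labels()
    merged = summaries.assign(label=summaries["perturbagen"].map(labels))
    rev = merged[merged["label"] == "reverser"]
    mim = merged[merged["label"] == "mimicker"]
    neut = merged[merged["label"] == "neutral"]
    assert (rev["mean_es"] < 0).all()
    assert (mim["mean_es"] > 0).all()
    assert rev["mean_es"].abs().min() > neut["mean_es"].abs().max()
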