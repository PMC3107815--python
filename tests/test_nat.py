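import numpy as np
import pandas as pd
import pytest

from clamarray.containers import Orientation, ProbeRecord
from clamarray.nat import (
    PairCrossTab,
    classify_pairs,
    concordance,
    crosstab,
    nat_candidate_list,
    pair_probes,
    summarize_crosstab,
)
from clamarray.normalize import quantile_normalize
from clamarray.pipeline import load_reference_crosstab
from clamarray.simulate import SimulationConfig, simulate_experiment

from conftest import make_matrix


def ann_pair(t):
    return [
        ProbeRecord(f"{t}_s", t, Orientation.SENSE, 1),
        ProbeRecord(f"{t}_as", t, Orientation.ANTISENSE, 1),
    ]


class TestPairProbes:
    def test_pairs_and_skips_counted(self):
        ann = ann_pair("t1") + ann_pair("t2") + ann_pair("t3")
        ann += [ProbeRecord("x1_s", "x1", Orientation.SENSE, 1),
                ProbeRecord("x2_s", "x2", Orientation.SENSE, 1)]
        pairs, skipped = pair_probes(ann)
        assert len(pairs) == 3 and skipped == 2

    def test_empty_annotation(self):
        pairs, skipped = pair_probes([])
        assert pairs == [] and skipped == 0

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(0)
        ann = []
        expect = 0
        for i in range(50):
            has_s, has_a = rng.random() < 0.7, rng.random() < 0.7
            if has_s:
                ann.append(ProbeRecord(f"t{i}_s", f"t{i}", Orientation.SENSE, 1))
            if has_a:
                ann.append(ProbeRecord(f"t{i}_as", f"t{i}", Orientation.ANTISENSE, 1))
            expect += has_s and has_a
        pairs, _ = pair_probes(ann)
        assert len(pairs) == expect


class TestClassifyPairs:
    def make(self, sense_vals, anti_vals, found=None):
        probes = ["t1_s", "t1_as"]
        vals = np.vstack([sense_vals, anti_vals])
        m = make_matrix(vals, probes=probes, found=found)
        pairs, _ = pair_probes(ann_pair("t1"))
        return classify_pairs(m, pairs)

    def test_direct_binning(self):
        (c,) = self.make([500.0, 500.0], [40.0, 40.0])
        assert (c.f_min, c.f_class) == (40.0, "f_10_100")
        assert c.ratio == pytest.approx(12.5)
        assert c.ratio_class == "r_ge_10"

    def test_left_inclusive_boundaries(self):
        (c,) = self.make([100.0, 100.0], [100.0, 100.0])
        assert c.f_class == "f_100_1000"
        assert c.ratio == 1.0 and c.ratio_class == "r_lt_1p5"

    def test_zero_signal_floored_into_top_ratio_class(self):
        (c,) = self.make([50.0, 50.0], [0.0, 0.0], found=[[True, True], [True, True]])
        assert c.f_min == 1.0  # floor
        assert c.ratio_class == "r_ge_10"

    def test_missing_replicate_excludes_pair(self):
        (c,) = self.make([50.0, 50.0], [20.0, 20.0], found=[[True, True], [True, False]])
        assert c.excluded

    def test_empty_replicate_set_rejected(self):
        m = make_matrix(np.ones((2, 2)), probes=["t1_s", "t1_as"])
        pairs, _ = pair_probes(ann_pair("t1"))
        with pytest.raises(ValueError):
            classify_pairs(m, pairs, replicate_arrays=[])


class TestCrossTab:
    def test_cells_and_totals(self):
        classes = classify_pairs(
            make_matrix(np.array([[500.0], [40.0], [600.0], [45.0]]),
                        probes=["t1_s", "t1_as", "t2_s", "t2_as"]),
            pair_probes(ann_pair("t1") + ann_pair("t2"))[0],
        )
        tab = crosstab(classes)
        assert tab.counts.loc["f_10_100", "r_ge_10"] == 2
        assert tab.grand_total == 2

    def test_empty_input_all_zero(self):
        tab = crosstab([])
        assert tab.grand_total == 0
        assert (tab.counts.to_numpy() == 0).all()

    def test_marginals_match_recount(self):
        rng = np.random.default_rng(1)
        n = 40
        probes, vals = [], []
        ann = []
        for i in range(n):
            ann += ann_pair(f"t{i}")
            probes += [f"t{i}_s", f"t{i}_as"]
            vals += [rng.uniform(1, 5000), rng.uniform(1, 5000)]
        m = make_matrix(np.array(vals)[:, None], probes=probes)
        classes = classify_pairs(m, pair_probes(ann)[0])
        tab = crosstab(classes)
        assert tab.grand_total == n
        # independent recount
        recount = {}
        for c in classes:
            recount[c.f_class] = recount.get(c.f_class, 0) + 1
        for f_class, total in recount.items():
            assert tab.row_totals[f_class] == total
        assert tab.column_totals.sum() == tab.row_totals.sum() == n


class TestSummarize:
    def test_reference_gills_aggregates(self):
        s = summarize_crosstab(load_reference_crosstab("gills"))
        assert s.grand_total == 14340
        assert round(100 * s.frac_ratio_gt3) == 75
        assert s.n_minor_strand_bright == 1267
        assert s.n_nat_candidates == 223

    def test_reference_digestive_gland_aggregates(self):
        s = summarize_crosstab(load_reference_crosstab("digestive_gland"))
        assert s.grand_total == 15027
        assert s.n_minor_strand_bright == 985
        assert s.n_nat_candidates == 151

    def test_nested_cell_sets(self):
        s = summarize_crosstab(load_reference_crosstab("gills"))
        assert s.n_nat_candidates <= s.n_minor_strand_bright <= s.grand_total

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_crosstab(crosstab([]))


class TestNatCandidates:
    def test_threshold_rules(self):
        probes = ["a_s", "a_as", "b_s", "b_as"]
        vals = np.array([[500.0], [250.0], [100.0], [50.0]])
        classes = classify_pairs(
            make_matrix(vals, probes=probes), pair_probes(ann_pair("a") + ann_pair("b"))[0]
        )
        assert nat_candidate_list(classes) == ["a"]  # ratio 2, f_min 250 in; f_min 50 out

    def test_recovery_of_planted_nats(self):
        cfg = SimulationConfig(
            n_transcripts=2000, frac_paired=1.0, frac_nat=0.1, n_duplicated=0,
            arrays_per_group={"digestive_gland": 4, "gills": 3},
            frac_de=0.1, noise_log2_sd=0.25, n_gene_sets=0, seed=42,
        )
        exp = simulate_experiment(cfg)
        norm = quantile_normalize(exp.matrix)
        pairs, _ = pair_probes(exp.annotation)
        arrays = [s.array_id for s in exp.samples if s.tissue.value == "digestive_gland"]
        candidates = set(nat_candidate_list(classify_pairs(norm, pairs, arrays)))
        planted = exp.truth.nat_transcripts
        precision = len(candidates & planted) / max(1, len(candidates))
        recall = len(candidates & planted) / len(planted)
        assert precision >= 0.7
        assert recall >= 0.5

    def test_orientation_swap_leaves_crosstab_unchanged(self):
        # the procedure uses min/max, not strand identity
        rng = np.random.default_rng(2)
        probes, vals, ann, ann_swapped = [], [], [], []
        for i in range(30):
            probes += [f"t{i}_x", f"t{i}_y"]
            vals += [rng.uniform(1, 2000), rng.uniform(1, 2000)]
            ann += [ProbeRecord(f"t{i}_x", f"t{i}", Orientation.SENSE, 1),
                    ProbeRecord(f"t{i}_y", f"t{i}", Orientation.ANTISENSE, 1)]
            ann_swapped += [ProbeRecord(f"t{i}_x", f"t{i}", Orientation.ANTISENSE, 1),
                            ProbeRecord(f"t{i}_y", f"t{i}", Orientation.SENSE, 1)]
        m = make_matrix(np.array(vals)[:, None], probes=probes)
        tab = crosstab(classify_pairs(m, pair_probes(ann)[0]))
        tab_swapped = crosstab(classify_pairs(m, pair_probes(ann_swapped)[0]))
        pd.testing.assert_frame_equal(tab.counts, tab_swapped.counts)


def sam_frame(rows):
    return pd.DataFrame(
        rows, columns=["probe_id", "d", "fold_change", "direction", "q_value", "called"]
    )


class TestConcordance:
    PAIRS = pair_probes(ann_pair("t1") + ann_pair("t2") + ann_pair("t3"))[0]

    def test_counts_and_directions(self):
        res = sam_frame(
            [
                ("t1_s", 3.0, 2.0, "up_in_group2", 0.005, True),
                ("t1_as", 2.5, 1.8, "up_in_group2", 0.008, True),
                ("t2_s", 3.0, 2.0, "up_in_group2", 0.005, True),
                ("t2_as", -2.5, 1.8, "up_in_group1", 0.002, True),
                ("t3_s", 0.1, 1.05, "up_in_group2", 0.9, False),
                ("t3_as", 0.1, 1.05, "up_in_group2", 0.9, False),
            ]
        )
        (c,) = concordance(res, self.PAIRS, q_thresholds=[0.01], fc_threshold=1.5)
        assert c.n_both_significant == 2
        assert c.n_concordant == 1 and c.n_discordant == 1
        assert c.n_concordant_up_group2 == 1
        assert c.discordant_fraction == pytest.approx(0.5)

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        rows = []
        for t in ("t1", "t2", "t3"):
            for suffix in ("_s", "_as"):
                q = rng.random()
                rows.append((t + suffix, 1.0, 2.0, "up_in_group2", q, q < 0.1))
        res = sam_frame(rows)
        out = concordance(res, self.PAIRS, q_thresholds=[0.05, 0.2, 0.5, 1.0], fc_threshold=1.0)
        counts = [c.n_both_significant for c in out]
        assert counts == sorted(counts)

    def test_missing_probe_skipped_and_tallied(self):
        res = sam_frame([("t1_s", 3.0, 2.0, "up_in_group2", 0.005, True)])
        (c,) = concordance(res, self.PAIRS, q_thresholds=[0.5])
        assert c.n_skipped == 3  # t1 lacks its antisense row; t2, t3 absent

    def test_no_significant_pairs_all_zero(self):
        res = sam_frame(
            [(p, 0.0, 1.0, "up_in_group2", 1.0, False)
             for pair in self.PAIRS for p in (pair.sense_probes[0], pair.antisense_probes[0])]
        )
        (c,) = concordance(res, self.PAIRS, q_thresholds=[0.1])
        assert c.n_both_significant == 0 and c.discordant_fraction == 0.0
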