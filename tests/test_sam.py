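import math

import numpy as np
import pandas as pd
import pytest

from clamarray.containers import Orientation, ProbeRecord
from clamarray.sam import (
    SamConfig,
    direction_bias_test,
    estimate_s0,
    probe_to_transcript_summary,
    sam_statistic,
    sam_two_class,
)
from clamarray.simulate import SimulationConfig, simulate_experiment

from conftest import make_matrix


class TestSamStatistic:
    def test_identical_groups_give_zero(self):
        assert sam_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], s0=0.5) == 0.0

    def test_hand_example_zero_variance(self):
        # s = 0, so d = (1 - 0) / (0 + 1) = 1
        assert sam_statistic([0.0, 0.0], [1.0, 1.0], s0=1.0) == pytest.approx(1.0)

    def test_pooled_standard_error_formula(self):
        x1, x2 = [1.0, 3.0, 2.0], [4.0, 8.0, 6.0]
        n1 = n2 = 3
        ss = sum((v - 2.0) ** 2 for v in x1) + sum((v - 6.0) ** 2 for v in x2)
        s = math.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
        assert sam_statistic(x1, x2, 0.2) == pytest.approx(4.0 / (s + 0.2))

    def test_antisymmetric_under_group_swap(self):
        x1, x2 = [1.0, 2.0, 4.0], [3.0, 5.0, 9.0]
        assert sam_statistic(x1, x2, 0.1) == pytest.approx(-sam_statistic(x2, x1, 0.1))

    def test_scale_invariant_when_s0_zero(self):
        x1, x2 = np.array([1.0, 2.0]), np.array([5.0, 7.0])
        assert sam_statistic(x1, x2, 0.0) == pytest.approx(sam_statistic(3 * x1, 3 * x2, 0.0))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sam_statistic([1.0], [1.0, 2.0], 0.1)


class TestEstimateS0:
    def test_identical_s_ties_to_smallest_candidate(self):
        rng = np.random.default_rng(0)
        r = rng.normal(size=500)
        s = np.full(500, 2.0)
        assert estimate_s0(r, s, grid=(0, 50, 100)) == 0.0

    def test_grid_of_zero_gives_zero(self):
        rng = np.random.default_rng(1)
        assert estimate_s0(rng.normal(size=200), rng.uniform(0.5, 1, 200), grid=(0,)) == 0.0

    def test_all_zero_s_floored_with_warning(self):
        with pytest.warns(UserWarning):
            s0 = estimate_s0(np.ones(50), np.zeros(50))
        assert s0 > 0

    def test_stabilizes_d_across_s_windows(self):
        # heteroscedastic null: var of d should be much flatter with s0
        rng = np.random.default_rng(2)
        n = 2000
        sigma = rng.uniform(0.05, 2.0, n)
        r = rng.normal(0, sigma)
        s = sigma * np.sqrt(0.5)  # pooled-SE scale
        s0 = estimate_s0(r, s)
        d = r / (s + s0)
        order = np.argsort(s)
        windows = np.array_split(order, 10)
        mads = [np.median(np.abs(d[w] - np.median(d[w]))) for w in windows]
        assert max(mads) / min(mads) <= 1.5


class TestDirectionBias:
    def test_published_site_bias_is_extreme(self):
        assert direction_bias_test(852, 1127) < 1e-5

    def test_even_split_gives_one(self):
        assert direction_bias_test(10, 20) == pytest.approx(1.0)

    @pytest.mark.parametrize("n_up,n", [(7, 10), (0, 12), (13, 20), (9, 17)])
    def test_matches_exhaustive_enumeration(self, n_up, n):
        p_obs = math.comb(n, n_up) * 0.5**n
        total = sum(
            math.comb(n, k) * 0.5**n for k in range(n + 1) if math.comb(n, k) * 0.5**n <= p_obs + 1e-15
        )
        assert direction_bias_test(n_up, n) == pytest.approx(total)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            direction_bias_test(5, 4)


def null_experiment(n=300, seed=0, **kw):
    cfg = SimulationConfig(
        n_transcripts=n, frac_paired=0.0, n_duplicated=0,
        arrays_per_group={"digestive_gland": 4, "gills": 4},
        frac_de=kw.pop("frac_de", 0.0), noise_log2_sd=0.25, array_scale_sd=0.0,
        n_gene_sets=0, seed=seed, **kw,
    )
    return simulate_experiment(cfg)


CONTRAST = ("tissue", "digestive_gland", "gills")


class TestSamTwoClass:
    def test_fc_filter_dominates(self):
        exp = null_experiment(frac_de=0.3, seed=3)
        out = sam_two_class(
            exp.matrix, exp.samples, CONTRAST,
            SamConfig(fdr_target=0.5, fc_threshold=1e6), annotation=exp.annotation,
        )
        assert not out.results["called"].any()

    def test_group_swap_flips_directions_only(self):
        exp = null_experiment(frac_de=0.2, seed=4)
        fwd = sam_two_class(exp.matrix, exp.samples, CONTRAST, SamConfig(), annotation=exp.annotation)
        rev = sam_two_class(
            exp.matrix, exp.samples, ("tissue", "gills", "digestive_gland"),
            SamConfig(), annotation=exp.annotation,
        )
        f = fwd.results.set_index("probe_id")
        r = rev.results.set_index("probe_id").loc[f.index]
        assert np.allclose(f["d"], -r["d"], atol=1e-9)
        assert set(f.index[f["called"]]) == set(r.index[r["called"]])
        swapped = {"up_in_group1": "up_in_group2", "up_in_group2": "up_in_group1"}
        assert (r["direction"] == f["direction"].map(swapped)).all()

    def test_exhaustive_runs_are_seed_independent(self):
        exp = null_experiment(frac_de=0.2, seed=5)
        a = sam_two_class(exp.matrix, exp.samples, CONTRAST, SamConfig(seed=1), annotation=exp.annotation)
        b = sam_two_class(exp.matrix, exp.samples, CONTRAST, SamConfig(seed=999), annotation=exp.annotation)
        assert a.exhaustive and b.exhaustive
        pd.testing.assert_frame_equal(a.results, b.results)

    def test_q_values_monotone_along_each_tail(self):
        exp = null_experiment(frac_de=0.2, seed=6)
        out = sam_two_class(exp.matrix, exp.samples, CONTRAST, SamConfig(), annotation=exp.annotation)
        res = out.results.sort_values("d")
        pos = res[res["d"] > 0]
        assert (np.diff(pos["q_value"]) <= 1e-12).all()  # larger d, smaller q
        neg = res[res["d"] < 0]
        assert (np.diff(neg["q_value"]) >= -1e-12).all()

    def test_fdr_column_monotone_in_delta(self):
        exp = null_experiment(frac_de=0.2, seed=7)
        out = sam_two_class(exp.matrix, exp.samples, CONTRAST, SamConfig(), annotation=exp.annotation)
        assert (np.diff(out.delta_table["fdr"]) <= 1e-12).all()

    def test_detection_filter_excludes_and_tallies(self):
        exp = null_experiment(seed=8)
        m = exp.matrix.copy()
        target = m.probes[0]
        m.found.loc[target] = False
        out = sam_two_class(m, exp.samples, CONTRAST, SamConfig(), annotation=exp.annotation)
        assert target in out.excluded_probes
        assert target not in set(out.results["probe_id"])

    def test_too_few_assignments_rejected(self):
        cfg = SimulationConfig(
            n_transcripts=50, frac_paired=0.0, n_duplicated=0,
            arrays_per_group={"digestive_gland": 2, "gills": 2},
            frac_de=0.0, n_gene_sets=0, seed=9,
        )
        exp = simulate_experiment(cfg)
        with pytest.raises(ValueError, match="replicates"):
            sam_two_class(exp.matrix, exp.samples, CONTRAST, SamConfig(), annotation=exp.annotation)

    def test_planted_effects_recovered(self):
        exp = null_experiment(n=800, frac_de=0.1, seed=10)
        out = sam_two_class(
            exp.matrix, exp.samples, CONTRAST, SamConfig(fdr_target=0.10), annotation=exp.annotation
        )
        truth = {f"{t}_s1" for t in exp.truth.de_transcripts}
        called = set(out.results.loc[out.results["called"], "probe_id"])
        assert len(called & truth) / len(truth) >= 0.8
        assert len(called - truth) / max(1, len(called)) <= 0.2


ANN = [
    ProbeRecord("pA_s", "tA", Orientation.SENSE, 1),
    ProbeRecord("pA_as", "tA", Orientation.ANTISENSE, 1),
    ProbeRecord("pB_s", "tB", Orientation.SENSE, 1),
    ProbeRecord("pC_s", "tC", Orientation.SENSE, 1),
    ProbeRecord("pC_as", "tC", Orientation.ANTISENSE, 1),
]


def results_frame(rows):
    return pd.DataFrame(
        rows, columns=["probe_id", "d", "fold_change", "direction", "q_value", "called"]
    )


class TestProbeToTranscriptSummary:
    def test_any_called_probe_marks_transcript(self):
        res = results_frame(
            [
                ("pA_s", 3.0, 4.0, "up_in_group2", 0.01, True),
                ("pA_as", 0.1, 1.1, "up_in_group1", 0.8, False),
                ("pB_s", 0.2, 1.2, "up_in_group2", 0.9, False),
            ]
        )
        summary = probe_to_transcript_summary(res, ANN).set_index("transcript_id")
        assert bool(summary.loc["tA", "significant"])
        assert summary.loc["tA", "direction"] == "up_in_group2"
        assert not bool(summary.loc["tB", "significant"])

    def test_direction_from_best_q_and_tie_flagged(self):
        res = results_frame(
            [
                ("pA_s", 3.0, 4.0, "up_in_group2", 0.01, True),
                ("pA_as", -4.0, 5.0, "up_in_group1", 0.005, True),
                ("pC_s", 2.0, 3.0, "up_in_group2", 0.02, True),
                ("pC_as", -2.0, 3.0, "up_in_group1", 0.02, True),
            ]
        )
        summary = probe_to_transcript_summary(res, ANN).set_index("transcript_id")
        assert summary.loc["tA", "direction"] == "up_in_group1"  # smaller q wins
        assert summary.loc["tC", "direction"] == "ambiguous"

    def test_counts_match_set_union_oracle(self):
        rng = np.random.default_rng(11)
        rows = []
        for rec in ANN:
            called = bool(rng.random() < 0.5)
            rows.append((rec.probe_id, 1.0, 2.0, "up_in_group2", rng.random(), called))
        res = results_frame(rows)
        summary = probe_to_transcript_summary(res, ANN)
        expected = {
            rec.transcript_id
            for rec, row in zip(ANN, rows)
            if row[5]
        }
        got = set(summary.loc[summary["significant"], "transcript_id"])
        assert got == expected
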