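"""Two-class SAM differential expression with planted truth.

Simulates a 4 vs 4 comparison in which 10% of probes carry a planted
log2 fold change of 1.5-4, runs the permutation SAM test at FDR 10%, and
scores the calls against the planted truth. The q-value of a probe is the
smallest estimated false discovery rate at which it would be called.
"""

from clamarray import SamConfig, SimulationConfig, sam_two_class, simulate_experiment

cfg = SimulationConfig(
    n_transcripts=2000,
    frac_paired=0.0,
    n_duplicated=0,
    arrays_per_group={"digestive_gland": 4, "gills": 4},
    frac_de=0.10,
    de_log2fc_range=(1.5, 4.0),
    noise_log2_sd=0.25,
    array_scale_sd=0.0,  # arrays already on a common scale
    seed=11,
)
exp = simulate_experiment(cfg)
out = sam_two_class(
    exp.matrix,
    exp.samples,
    ("tissue", "digestive_gland", "gills"),
    SamConfig(fdr_target=0.10, seed=11),
    annotation=exp.annotation,
)

print(f"fudge factor s0 = {out.s0:.3f}, pi0 = {out.pi0:.3f}, "
      f"{out.n_permutations} permutations (exhaustive={out.exhaustive})")
called = out.results[out.results["called"]]
truth = {f"{t}_s1" for t in exp.truth.de_transcripts}
tp = len(set(called["probe_id"]) & truth)
print(f"called {len(called)} probes; sensitivity {tp / len(truth):.2%}, "
      f"empirical FDR {(len(called) - tp) / max(1, len(called)):.2%}")
print(called.sort_values("q_value").head(5).to_string(index=False))
# Sensitivity near 1 and empirical FDR well under the 10% target show the
# permutation FDR machinery is calibrated on data meeting its assumptions.
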