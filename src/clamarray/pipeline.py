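"""End-to-end orchestration: simulate -> normalize -> qc -> sam -> nat -> enrich.

Also carries the verification of the packaged reference tables: the
published sense/antisense cross-tabulations and concordance counts for the
Manila clam 4x44K platform (gills and digestive gland), transcribed as
plain-text fixtures in ``clamarray/data``. ``verify_reference_tables``
recomputes the nine headline aggregates those tables imply and checks them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import io as aio
from . import nat, normalize, qc, sam
from .enrich import enrich as enrich_gene_sets, records_frame
from .nat import PairCrossTab
from .simulate import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "qc", "sam", "nat", "enrich")


@dataclass
class RunConfig:
    outdir: Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    sam_config: sam.SamConfig = field(default_factory=sam.SamConfig)
    nat_q_thresholds: tuple[float, ...] = (0.011, 0.10, 0.18)
    nat_fc_threshold: float = 1.5
    nat_ratio_threshold: float = 3.0
    nat_f_threshold: float = 100.0
    enrich_min_count: int = 4
    enrich_max_ease: float = 0.05
    min_found: int = 4
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage on a synthetic experiment; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def record(stage: str, outputs: dict[str, Path], **params) -> None:
        entry = {
            "stage": stage,
            "params": params,
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
            },
        }
        manifest["stages"].append(entry)
        logger.info("[%s] done: %s", stage, ", ".join(outputs))

    # 1. simulate
    config.simulation.seed = config.seed
    exp = simulate_experiment(config.simulation)
    exp.write(outdir / "inputs")
    record(
        "simulate",
        {
            "annotation": outdir / "inputs" / "annotation.tsv",
            "samples": outdir / "inputs" / "samples.tsv",
            "gene_sets": outdir / "inputs" / "gene_sets.gmt",
            "truth": outdir / "inputs" / "truth.tsv",
        },
        n_transcripts=config.simulation.n_transcripts,
        n_arrays=len(exp.samples),
    )

    # 2. normalize (re-reading the written tables keeps the run auditable)
    annotation = aio.read_probe_annotation(outdir / "inputs" / "annotation.tsv")
    samples = aio.read_sample_sheet(outdir / "inputs" / "samples.tsv")
    tables = [outdir / "inputs" / f"{s.array_id}.tsv" for s in samples]
    raw = aio.assemble_signal_matrix(tables, annotation, [s.array_id for s in samples])
    norm, reports = normalize.choose_normalization(raw, annotation)
    aio.write_signal_matrix(norm, outdir / "normalized.tsv", outdir / "normalized_found.tsv")
    normalize.report_frame(reports).to_csv(outdir / "normalization_report.tsv", sep="\t", index=False)
    record(
        "normalize",
        {"matrix": outdir / "normalized.tsv", "report": outdir / "normalization_report.tsv"},
        chosen=[r.method for r in reports if r.chosen][0],
    )

    # 3. qc
    det = qc.detection_summary(norm, k=min(config.min_found, len(samples)))
    r_mat, _ = qc.replicate_correlation(norm, samples)
    dup = qc.duplicate_probe_agreement(norm, annotation)
    pd.DataFrame(
        [
            {
                "n_never_found": det.n_never_found,
                "n_always_found": det.n_always_found,
                "n_found_ge_k": det.n_found_ge_k,
                "k": det.k,
                "n_probes": det.n_probes,
            }
        ]
    ).to_csv(outdir / "qc_detection.tsv", sep="\t", index=False)
    r_mat.to_csv(outdir / "qc_replicate_correlation.tsv", sep="\t")
    dup.fc_summary.to_csv(outdir / "qc_duplicate_ratio.tsv", sep="\t")
    record(
        "qc",
        {
            "detection": outdir / "qc_detection.tsv",
            "replicate_correlation": outdir / "qc_replicate_correlation.tsv",
            "duplicate_ratio": outdir / "qc_duplicate_ratio.tsv",
        },
        min_found=det.k,
    )

    # 4. sam
    groups = list(config.simulation.arrays_per_group)
    attr = "tissue" if groups[0] in ("digestive_gland", "gills") else "site"
    contrast = (attr, groups[0], groups[1])
    config.sam_config.seed = config.seed
    out = sam.sam_two_class(norm, samples, contrast, config.sam_config, annotation=annotation)
    aio.write_result_table(out.results, outdir / "sam_results.tsv")
    aio.write_result_table(out.delta_table, outdir / "sam_delta_table.tsv")
    record(
        "sam",
        {"results": outdir / "sam_results.tsv", "delta_table": outdir / "sam_delta_table.tsv"},
        s0=out.s0,
        pi0=out.pi0,
        n_permutations=out.n_permutations,
        exhaustive=out.exhaustive,
        contrast=list(contrast),
        n_called=int(out.results["called"].sum()),
    )

    # 5. nat
    pairs, n_skip = nat.pair_probes(annotation)
    group1_arrays = [s.array_id for s in samples if getattr(s, attr).value == groups[0]]
    classified = nat.classify_pairs(norm, pairs, group1_arrays)
    tab = nat.crosstab(classified, label=groups[0])
    tab.counts.to_csv(outdir / "nat_crosstab.tsv", sep="\t")
    candidates = nat.nat_candidate_list(
        classified, config.nat_ratio_threshold, config.nat_f_threshold
    )
    pd.DataFrame({"transcript_id": candidates}).to_csv(
        outdir / "nat_candidates.tsv", sep="\t", index=False
    )
    conc = nat.concordance(out.results, pairs, config.nat_q_thresholds, config.nat_fc_threshold)
    pd.DataFrame([vars(c) for c in conc]).to_csv(outdir / "nat_concordance.tsv", sep="\t", index=False)
    record(
        "nat",
        {
            "crosstab": outdir / "nat_crosstab.tsv",
            "candidates": outdir / "nat_candidates.tsv",
            "concordance": outdir / "nat_concordance.tsv",
        },
        n_pairs=len(pairs),
        n_skipped=n_skip,
        n_candidates=len(candidates),
    )

    # 6. enrich: significant transcripts vs all transcripts on the array
    summary = sam.probe_to_transcript_summary(out.results, annotation)
    sig = summary.loc[summary["significant"], "transcript_id"].tolist()
    background = summary["transcript_id"].tolist()
    gene_sets = aio.read_gmt(outdir / "inputs" / "gene_sets.gmt")
    if sig:
        records = enrich_gene_sets(
            sig, background, gene_sets, config.enrich_min_count, config.enrich_max_ease
        )
    else:
        records = []
    records_frame(records).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    record(
        "enrich",
        {"enrichment": outdir / "enrichment.tsv"},
        n_significant_transcripts=len(sig),
        n_terms_reported=len(records),
    )

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# packaged reference tables


def load_reference_crosstab(tissue: str) -> PairCrossTab:
    """Published 4x4 pair cross-tabulation for one tissue (packaged fixture)."""
    with resources.files("clamarray.data").joinpath("reference_pair_crosstab.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    sub = df[df["tissue"] == tissue].set_index("f_class")[list(nat.RATIO_LABELS)]
    if sub.empty:
        raise ValueError(f"unknown tissue {tissue!r} in reference cross-tab")
    return PairCrossTab(sub.loc[list(nat.F_LABELS)].astype(int), label=tissue)


def load_reference_marginals() -> pd.DataFrame:
    with resources.files("clamarray.data").joinpath("reference_crosstab_marginals.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t").set_index("tissue")


def load_reference_concordance() -> pd.DataFrame:
    with resources.files("clamarray.data").joinpath("reference_concordance.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def verify_reference_tables() -> pd.DataFrame:
    """Recompute the nine headline aggregates from the packaged tables.

    Returns a frame with columns target, expected, computed, passed; the
    expected values are the ones quoted alongside the published tables.
    """
    checks: list[tuple[str, float, float]] = []

    gills = nat.summarize_crosstab(load_reference_crosstab("gills"))
    dg = nat.summarize_crosstab(load_reference_crosstab("digestive_gland"))
    checks.append(("gills_ratio_gt3_pct_rounded", 75.0, round(100 * gills.frac_ratio_gt3)))
    checks.append(("gills_minor_strand_bright", 1267, gills.n_minor_strand_bright))
    checks.append(("digestive_gland_minor_strand_bright", 985, dg.n_minor_strand_bright))
    checks.append(("gills_nat_candidates", 223, gills.n_nat_candidates))
    checks.append(("digestive_gland_nat_candidates", 151, dg.n_nat_candidates))

    conc = load_reference_concordance()
    strict = conc[conc["q_threshold"] == 0.011].iloc[0]
    loose = conc[conc["q_threshold"] == 0.10].iloc[0]
    s = nat.concordance_bookkeeping(
        int(strict["n_discordant"]),
        int(strict["n_concordant_up_digestive_gland"]),
        int(strict["n_concordant_up_gills"]),
        0.011,
    )
    l = nat.concordance_bookkeeping(
        int(loose["n_discordant"]),
        int(loose["n_concordant_up_digestive_gland"]),
        int(loose["n_concordant_up_gills"]),
        0.10,
    )
    checks.append(("strict_both_significant", 688, s.n_both_significant))
    checks.append(("strict_concordant", 658, s.n_concordant))
    checks.append(("strict_discordant_fraction_rounded", 0.04, round(s.discordant_fraction, 2)))
    checks.append(("loose_both_significant", 3042, l.n_both_significant))

    df = pd.DataFrame(checks, columns=["target", "expected", "computed"])
    df["passed"] = df["expected"] == df["computed"]
    return df
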