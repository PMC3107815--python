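"""Synthetic experiment generator with known planted structure.

Emulates a one-color 4x44K sense/antisense platform: a subset of
transcripts is represented by opposite-orientation probe pairs, some
transcripts have a duplicated sense probe, spike-in controls sit at fixed
known levels, and two biological groups (tissue or site contrast) differ
by planted log2 fold changes on a fraction of transcripts.

Generative model (all on the log2 scale unless noted):

* sense abundance  ``a_s ~ Normal(baseline_log2_mean, baseline_log2_sd)``
* a ``frac_de`` fraction of transcripts receives a group-2 effect of
  ``+/- log2FC`` with ``log2FC ~ Uniform(de_log2fc_range)`` and a random sign
* the antisense strand of a non-NAT pair is suppressed:
  ``a_as = a_s - delta`` with ``delta ~ Uniform(3.5, 8)``, so such pairs fall
  overwhelmingly into the ratio > 10 class
* the antisense strand of a planted NAT is independently transcribed:
  ``a_as`` is drawn afresh from the baseline law and may carry its own DE
  effect with probability ``frac_de``
* linear signal on array j is ``2**(a + scale_j + eps) + background_level``
  with per-array scale ``scale_j ~ Normal(0, array_scale_sd)`` and per-cell
  noise ``eps ~ Normal(0, noise_log2_sd)``; duplicate probe copies share
  ``a`` but draw independent ``eps``
* spike-ins have a fixed abundance per level shared across arrays; they
  carry the array scale but no per-cell noise, so before scaling they are
  identical across arrays
* detection flag ``found = signal > 2 * background_level``

Randomness: one child stream per array, spawned from the master seed by
array index, so appending arrays never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ArraySample,
    ControlType,
    Orientation,
    ProbeRecord,
    SignalMatrix,
    Site,
    Tissue,
    validate_annotation,
)
from . import io as aio

_TISSUE_GROUPS = {Tissue.DIGESTIVE_GLAND.value, Tissue.GILLS.value}
_SITE_GROUPS = {Site.CLEAN.value, Site.POLLUTED.value}

SUPPRESSION_GAP = (3.5, 8.0)  # log2 gap of the silenced strand in non-NAT pairs


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the real platform scale: ~24K transcripts of which
    roughly two thirds carry an opposite-orientation probe pair, 2,000
    duplicated sense probes, ten spike-in levels, and a 4 vs 3 array
    tissue design.
    """

    n_transcripts: int = 24_281
    frac_paired: float = 0.661
    frac_nat: float = 0.10
    n_duplicated: int = 2_000
    n_spike_levels: int = 10
    arrays_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"digestive_gland": 4, "gills": 3}
    )
    frac_de: float = 0.10
    de_log2fc_range: tuple[float, float] = (1.5, 4.0)
    baseline_log2_mean: float = 8.5
    baseline_log2_sd: float = 1.0
    noise_log2_sd: float = 0.25
    background_level: float = 5.0
    array_scale_sd: float = 0.2
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (20, 200)
    n_enriched_sets: int = 3  # sets deliberately over-sampling DE transcripts
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        for name in ("frac_paired", "frac_nat", "frac_de"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("baseline_log2_sd", "noise_log2_sd", "array_scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.arrays_per_group) != 2:
            raise ValueError("exactly two groups are supported")
        groups = set(self.arrays_per_group)
        if groups != _TISSUE_GROUPS and groups != _SITE_GROUPS:
            raise ValueError(
                "groups must be the tissue contrast {digestive_gland, gills} "
                "or the site contrast {clean, polluted}"
            )
        if any(n < 2 for n in self.arrays_per_group.values()):
            raise ValueError("arrays_per_group values must be >= 2")
        if self.n_duplicated > self.n_transcripts:
            raise ValueError("n_duplicated cannot exceed n_transcripts")
        lo, hi = self.de_log2fc_range
        if not (0 <= lo <= hi):
            raise ValueError("de_log2fc_range must satisfy 0 <= lo <= hi")


@dataclass
class GroundTruth:
    """Planted structure: what a perfect analysis should recover."""

    de_transcripts: dict[str, float]  # transcript -> signed log2FC (group2 - group1)
    nat_transcripts: set[str]
    array_scales: dict[str, float]
    spike_log2_levels: list[float]


@dataclass
class SimulatedExperiment:
    annotation: list[ProbeRecord]
    matrix: SignalMatrix
    samples: list[ArraySample]
    gene_sets: dict[str, set[str]]
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        """Write annotation, per-array signal tables, sample sheet, truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aio.write_probe_annotation(self.annotation, outdir / "annotation.tsv")
        aio.write_sample_sheet(self.samples, outdir / "samples.tsv")
        aio.write_gmt(self.gene_sets, outdir / "gene_sets.gmt")
        for aid in self.matrix.arrays:
            df = pd.DataFrame(
                {
                    "probe_id": self.matrix.probes,
                    "signal": self.matrix.values[aid].to_numpy(),
                    "found": self.matrix.found[aid].to_numpy().astype(int),
                }
            )
            df.to_csv(outdir / f"{aid}.tsv", sep="\t", index=False, float_format="%.17g")
        truth_report(self.truth, outdir / "truth.tsv")


def _make_annotation(cfg: SimulationConfig, rng: np.random.Generator):
    transcripts = [f"transcript_{i:06d}" for i in range(cfg.n_transcripts)]
    n_paired = int(round(cfg.frac_paired * cfg.n_transcripts))
    paired = transcripts[:n_paired]  # deterministic prefix; abundances are iid anyway
    n_nat = int(round(cfg.frac_nat * n_paired))
    nat = set(paired[:n_nat])
    # duplicated sense probes are drawn from unpaired transcripts when
    # possible (the real platform duplicated known-orientation probes)
    unpaired = transcripts[n_paired:]
    dup_pool = unpaired if len(unpaired) >= cfg.n_duplicated else transcripts
    duplicated = set(dup_pool[: cfg.n_duplicated])

    records: list[ProbeRecord] = []
    for t in transcripts:
        records.append(ProbeRecord(f"{t}_s1", t, Orientation.SENSE, 1))
        if t in duplicated:
            records.append(ProbeRecord(f"{t}_s2", t, Orientation.SENSE, 2))
        if t in paired:
            records.append(ProbeRecord(f"{t}_as1", t, Orientation.ANTISENSE, 1))
    for lvl in range(cfg.n_spike_levels):
        records.append(
            ProbeRecord(f"spike_{lvl:02d}", "", Orientation.UNKNOWN, 1, ControlType.SPIKE_IN)
        )
    for k in range(8):
        records.append(
            ProbeRecord(f"neg_{k:02d}", "", Orientation.UNKNOWN, 1, ControlType.NEGATIVE)
        )
    validate_annotation(records)
    return records, paired, nat, duplicated


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a complete experiment; fully deterministic given the seed."""
    config.validate()
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    global_rng = np.random.Generator(np.random.PCG64(master.spawn(1)[0]))

    annotation, paired, nat, duplicated = _make_annotation(cfg, global_rng)
    transcripts = [f"transcript_{i:06d}" for i in range(cfg.n_transcripts)]

    # per-transcript log2 abundances
    a_sense = global_rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_transcripts)
    a_sense = pd.Series(a_sense, index=transcripts)

    # planted DE on sense transcripts
    n_de = int(round(cfg.frac_de * cfg.n_transcripts))
    de_idx = global_rng.choice(cfg.n_transcripts, size=n_de, replace=False)
    lo, hi = cfg.de_log2fc_range
    fc = global_rng.uniform(lo, hi, n_de) * global_rng.choice([-1.0, 1.0], n_de)
    de_effect = pd.Series(0.0, index=transcripts)
    de_effect.iloc[de_idx] = fc
    de_transcripts = {transcripts[i]: float(f) for i, f in zip(de_idx, fc)}

    # antisense abundances and their (independent) DE effects
    a_anti = pd.Series(np.nan, index=transcripts)
    anti_effect = pd.Series(0.0, index=transcripts)
    paired_set = list(paired)
    gap = global_rng.uniform(*SUPPRESSION_GAP, len(paired_set))
    a_nat = global_rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, len(paired_set))
    nat_de_mask = global_rng.random(len(paired_set)) < cfg.frac_de
    nat_fc = global_rng.uniform(lo, hi, len(paired_set)) * global_rng.choice(
        [-1.0, 1.0], len(paired_set)
    )
    for j, t in enumerate(paired_set):
        if t in nat:
            a_anti[t] = a_nat[j]
            if nat_de_mask[j]:
                anti_effect[t] = nat_fc[j]
        else:
            a_anti[t] = a_sense[t] - gap[j]
            anti_effect[t] = de_effect[t]  # suppressed strand tracks its sense

    spike_levels = [4.0 + 10.0 * lvl / max(1, cfg.n_spike_levels - 1) for lvl in range(cfg.n_spike_levels)]

    # baseline log2 abundance per probe (group-1 reference)
    probe_ids: list[str] = []
    probe_base: list[float] = []
    probe_group_eff: list[float] = []
    is_spike: list[bool] = []
    for rec in annotation:
        probe_ids.append(rec.probe_id)
        if rec.control_type is ControlType.SPIKE_IN:
            lvl = int(rec.probe_id.split("_")[1])
            probe_base.append(spike_levels[lvl])
            probe_group_eff.append(0.0)
            is_spike.append(True)
        elif rec.control_type is ControlType.NEGATIVE:
            probe_base.append(-np.inf)  # zero signal before background
            probe_group_eff.append(0.0)
            is_spike.append(False)
        elif rec.orientation is Orientation.SENSE:
            probe_base.append(float(a_sense[rec.transcript_id]))
            probe_group_eff.append(float(de_effect[rec.transcript_id]))
            is_spike.append(False)
        else:
            probe_base.append(float(a_anti[rec.transcript_id]))
            probe_group_eff.append(float(anti_effect[rec.transcript_id]))
            is_spike.append(False)
    base = np.array(probe_base)
    group_eff = np.array(probe_group_eff)
    spike_mask = np.array(is_spike)

    groups = list(cfg.arrays_per_group)
    group2 = groups[1]
    samples: list[ArraySample] = []
    columns: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    array_index = 0
    for g in groups:
        for rep in range(cfg.arrays_per_group[g]):
            aid = f"{g}_pool{rep + 1}"
            stream = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence((cfg.seed, 1000 + array_index)))
            )
            scale = stream.normal(0.0, cfg.array_scale_sd) if cfg.array_scale_sd > 0 else 0.0
            eps = (
                stream.normal(0.0, cfg.noise_log2_sd, base.shape[0])
                if cfg.noise_log2_sd > 0
                else np.zeros(base.shape[0])
            )
            eps[spike_mask] = 0.0  # spike-ins: scale only, no per-cell noise
            a = base + (group_eff if g == group2 else 0.0)
            with np.errstate(over="ignore"):
                signal = np.exp2(a + scale + eps)
            signal = np.where(np.isfinite(signal), signal, 0.0)  # negatives (-inf base)
            signal = signal + cfg.background_level
            columns[aid] = signal
            scales[aid] = float(scale)
            if set(groups) == _TISSUE_GROUPS:
                tissue, site = Tissue(g), Site.CLEAN
            else:
                tissue, site = Tissue.DIGESTIVE_GLAND, Site(g)
            samples.append(ArraySample(aid, tissue, site, f"{g}_pool{rep + 1}"))
            array_index += 1

    values = pd.DataFrame(columns, index=probe_ids)
    values.index.name = "probe_id"
    found = values > 2.0 * cfg.background_level
    matrix = SignalMatrix(values, found)

    gene_sets = _make_gene_sets(cfg, global_rng, transcripts, de_transcripts)

    truth = GroundTruth(
        de_transcripts=de_transcripts,
        nat_transcripts=set(nat),
        array_scales=scales,
        spike_log2_levels=spike_levels,
    )
    return SimulatedExperiment(annotation, matrix, samples, gene_sets, truth, cfg)


def _make_gene_sets(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    transcripts: list[str],
    de_transcripts: dict[str, float],
) -> dict[str, set[str]]:
    """Random term sets; the first few over-sample DE transcripts 5:1."""
    if cfg.n_gene_sets == 0:
        return {}
    lo, hi = cfg.gene_set_size_range
    lo = max(1, min(lo, len(transcripts)))
    hi = max(lo, min(hi, len(transcripts)))
    de = sorted(de_transcripts)
    sets: dict[str, set[str]] = {}
    weights = np.ones(len(transcripts))
    if de:
        de_idx = {t: i for i, t in enumerate(transcripts)}
        enriched_w = weights.copy()
        for t in de:
            enriched_w[de_idx[t]] = 5.0
        enriched_w = enriched_w / enriched_w.sum()
    for k in range(cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if de and k < cfg.n_enriched_sets:
            members = rng.choice(len(transcripts), size=size, replace=False, p=enriched_w)
            name = f"set_enriched_{k:03d}"
        else:
            members = rng.choice(len(transcripts), size=size, replace=False)
            name = f"set_random_{k:03d}"
        sets[name] = {transcripts[i] for i in members}
    return sets


def truth_report(gt: GroundTruth, path: str | Path) -> None:
    """Write planted DE and NAT labels as one long-format TSV."""
    rows = [
        {"kind": "de", "transcript_id": t, "log2fc": v} for t, v in sorted(gt.de_transcripts.items())
    ] + [
        {"kind": "nat", "transcript_id": t, "log2fc": ""} for t in sorted(gt.nat_transcripts)
    ]
    df = pd.DataFrame(rows, columns=["kind", "transcript_id", "log2fc"])
    df.to_csv(path, sep="\t", index=False)


def read_truth_report(path: str | Path) -> tuple[dict[str, float], set[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str}, keep_default_na=False)
    de = {
        r.transcript_id: float(r.log2fc)
        for r in df.itertuples(index=False)
        if r.kind == "de"
    }
    nat = {r.transcript_id for r in df.itertuples(index=False) if r.kind == "nat"}
    return de, nat
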