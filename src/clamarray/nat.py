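"""Sense-antisense probe-pair analysis and NAT candidate calling.

For every transcript carrying both a sense and an antisense probe, the two
probe means across biological replicates are compared. The pair is placed
in a 4x4 cross-tabulation: rows by the mean fluorescence of the *minor*
(lower-signal) strand, columns by the max/min signal ratio. Pairs with a
bright minor strand and a small ratio — both strands substantially
transcribed — are candidates for natural antisense transcripts (NATs).
A complementary view asks whether sense and antisense probes of the same
transcript respond concordantly in a differential-expression contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ControlType, Orientation, ProbeRecord, SignalMatrix

F_EDGES = (10.0, 100.0, 1000.0)  # fluorescence bins: [0,10),[10,100),[100,1000),[1000,inf)
RATIO_EDGES = (1.5, 3.0, 10.0)  # ratio bins: [1,1.5),[1.5,3),[3,10),[10,inf)
F_LABELS = ("f_lt_10", "f_10_100", "f_100_1000", "f_ge_1000")
RATIO_LABELS = ("r_lt_1p5", "r_1p5_3", "r_3_10", "r_ge_10")

SIGNAL_FLOOR = 1.0  # normalized fluorescence units; keeps ratios finite


@dataclass(frozen=True)
class ProbePair:
    transcript_id: str
    sense_probes: tuple[str, ...]  # duplicate copies collapsed by mean downstream
    antisense_probes: tuple[str, ...]


@dataclass
class PairClassification:
    transcript_id: str
    f_min: float
    ratio: float
    f_class: str
    ratio_class: str
    excluded: bool


@dataclass
class PairCrossTab:
    counts: pd.DataFrame  # 4x4, F_LABELS rows x RATIO_LABELS columns
    label: str = ""

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def pair_probes(annotation: Sequence[ProbeRecord]) -> tuple[list[ProbePair], int]:
    """Group experimental probes into sense/antisense pairs per transcript.

    Returns the pairs and the number of transcripts skipped for lacking one
    of the two orientations.
    """
    sense: dict[str, list[str]] = {}
    anti: dict[str, list[str]] = {}
    transcripts: list[str] = []
    seen: set[str] = set()
    for rec in annotation:
        if rec.control_type is not ControlType.EXPERIMENTAL:
            continue
        if rec.transcript_id not in seen:
            seen.add(rec.transcript_id)
            transcripts.append(rec.transcript_id)
        if rec.orientation is Orientation.SENSE:
            sense.setdefault(rec.transcript_id, []).append(rec.probe_id)
        elif rec.orientation is Orientation.ANTISENSE:
            anti.setdefault(rec.transcript_id, []).append(rec.probe_id)
    pairs: list[ProbePair] = []
    n_skipped = 0
    for t in transcripts:
        if t in sense and t in anti:
            pairs.append(ProbePair(t, tuple(sense[t]), tuple(anti[t])))
        else:
            n_skipped += 1
    return pairs, n_skipped


def _bin_label(value: float, edges: tuple[float, ...], labels: tuple[str, ...]) -> str:
    return labels[int(np.searchsorted(edges, value, side="right"))]


def classify_pairs(
    m: SignalMatrix,
    pairs: Sequence[ProbePair],
    replicate_arrays: Sequence[str] | None = None,
    floor: float = SIGNAL_FLOOR,
) -> list[PairClassification]:
    """Classify each pair by minor-strand fluorescence and strand ratio.

    Probe means are taken across the replicate arrays after normalization;
    duplicate probe copies of an orientation are averaged first. A pair is
    excluded (no classes) when any constituent probe is undetected in any
    replicate. Means are floored at ``floor`` before the ratio.
    """
    arrays = list(replicate_arrays) if replicate_arrays is not None else m.arrays
    if not arrays:
        raise ValueError("empty replicate set")
    values = m.values[arrays]
    found = m.found[arrays]
    out: list[PairClassification] = []
    for pair in pairs:
        probes = list(pair.sense_probes) + list(pair.antisense_probes)
        if not found.loc[probes].to_numpy().all():
            out.append(PairClassification(pair.transcript_id, np.nan, np.nan, "", "", True))
            continue
        mean_s = float(values.loc[list(pair.sense_probes)].to_numpy().mean())
        mean_a = float(values.loc[list(pair.antisense_probes)].to_numpy().mean())
        lo = max(min(mean_s, mean_a), floor)
        hi = max(max(mean_s, mean_a), floor)
        ratio = hi / lo
        out.append(
            PairClassification(
                transcript_id=pair.transcript_id,
                f_min=lo,
                ratio=ratio,
                f_class=_bin_label(lo, F_EDGES, F_LABELS),
                ratio_class=_bin_label(ratio, RATIO_EDGES, RATIO_LABELS),
                excluded=False,
            )
        )
    return out


def crosstab(classified: Sequence[PairClassification], label: str = "") -> PairCrossTab:
    counts = pd.DataFrame(0, index=list(F_LABELS), columns=list(RATIO_LABELS), dtype=int)
    for c in classified:
        if c.excluded:
            continue
        counts.loc[c.f_class, c.ratio_class] += 1
    return PairCrossTab(counts, label)


@dataclass
class CrossTabSummary:
    grand_total: int
    n_ratio_gt3: int
    frac_ratio_gt3: float
    n_ratio_gt10: int
    frac_ratio_gt10: float
    n_minor_strand_bright: int  # pairs with f_min >= 100
    frac_minor_strand_bright: float
    n_nat_candidates: int  # ratio < 3 and f_min >= 100
    frac_nat_candidates: float


def summarize_crosstab(t: PairCrossTab) -> CrossTabSummary:
    """Headline aggregates of the 4x4 pair table."""
    total = t.grand_total
    if total == 0:
        raise ValueError("empty cross-tab: fractions undefined")
    c = t.counts
    n_gt3 = int(c[["r_3_10", "r_ge_10"]].to_numpy().sum())
    n_gt10 = int(c["r_ge_10"].to_numpy().sum())
    bright_rows = ["f_100_1000", "f_ge_1000"]
    n_bright = int(c.loc[bright_rows].to_numpy().sum())
    n_nat = int(c.loc[bright_rows, ["r_lt_1p5", "r_1p5_3"]].to_numpy().sum())
    return CrossTabSummary(
        grand_total=total,
        n_ratio_gt3=n_gt3,
        frac_ratio_gt3=n_gt3 / total,
        n_ratio_gt10=n_gt10,
        frac_ratio_gt10=n_gt10 / total,
        n_minor_strand_bright=n_bright,
        frac_minor_strand_bright=n_bright / total,
        n_nat_candidates=n_nat,
        frac_nat_candidates=n_nat / total,
    )


def nat_candidate_list(
    classified: Sequence[PairClassification],
    threshold_ratio: float = 3.0,
    threshold_f: float = 100.0,
) -> list[str]:
    """Transcripts with both strands bright: ratio < threshold_ratio and
    f_min >= threshold_f, sorted by descending minor-strand fluorescence."""
    hits = [
        c
        for c in classified
        if not c.excluded and c.ratio < threshold_ratio and c.f_min >= threshold_f
    ]
    hits.sort(key=lambda c: (-c.f_min, c.transcript_id))
    return [c.transcript_id for c in hits]


@dataclass
class ConcordanceSummary:
    q_threshold: float
    n_both_significant: int
    n_concordant: int
    n_discordant: int
    n_concordant_up_group1: int
    n_concordant_up_group2: int
    discordant_fraction: float
    n_skipped: int  # pairs with a probe missing from the SAM output


def concordance(
    sam_results: pd.DataFrame,
    pairs: Sequence[ProbePair],
    q_thresholds: Sequence[float],
    fc_threshold: float = 1.5,
) -> list[ConcordanceSummary]:
    """Sense/antisense concordance of differential expression.

    For each q threshold, a pair counts when *both* probes have
    q < threshold and fold change >= fc_threshold; it is concordant when
    both probes moved in the same direction. Pairs whose probes were
    excluded upstream of SAM are skipped and tallied.
    """
    indexed = sam_results.set_index("probe_id")
    out: list[ConcordanceSummary] = []
    for thr in q_thresholds:
        n_both = n_conc = n_disc = up1 = up2 = n_skipped = 0
        for pair in pairs:
            # concordance is one-vs-one: first copy of each orientation
            ps, pa = pair.sense_probes[0], pair.antisense_probes[0]
            if ps not in indexed.index or pa not in indexed.index:
                n_skipped += 1
                continue
            rs, ra = indexed.loc[ps], indexed.loc[pa]
            if (
                rs["q_value"] < thr
                and ra["q_value"] < thr
                and rs["fold_change"] >= fc_threshold
                and ra["fold_change"] >= fc_threshold
            ):
                n_both += 1
                if rs["direction"] == ra["direction"]:
                    n_conc += 1
                    if rs["direction"] == "up_in_group1":
                        up1 += 1
                    else:
                        up2 += 1
                else:
                    n_disc += 1
        out.append(
            ConcordanceSummary(
                q_threshold=float(thr),
                n_both_significant=n_both,
                n_concordant=n_conc,
                n_discordant=n_disc,
                n_concordant_up_group1=up1,
                n_concordant_up_group2=up2,
                discordant_fraction=n_disc / n_both if n_both else 0.0,
                n_skipped=n_skipped,
            )
        )
    return out


def concordance_bookkeeping(
    n_discordant: int, n_concordant_up_group1: int, n_concordant_up_group2: int, q_threshold: float
) -> ConcordanceSummary:
    """Aggregate a pre-tabulated concordance row (discordant / concordant-by-
    direction counts) into the summary form."""
    n_conc = n_concordant_up_group1 + n_concordant_up_group2
    n_both = n_conc + n_discordant
    return ConcordanceSummary(
        q_threshold=q_threshold,
        n_both_significant=n_both,
        n_concordant=n_conc,
        n_discordant=n_discordant,
        n_concordant_up_group1=n_concordant_up_group1,
        n_concordant_up_group2=n_concordant_up_group2,
        discordant_fraction=n_discordant / n_both if n_both else 0.0,
        n_skipped=0,
    )
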