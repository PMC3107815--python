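"""Array quality assessment.

Three diagnostics: per-probe detection-success accounting from the scanner's
found flags, between-replicate Pearson correlation on the full expression
vector, and agreement between duplicate prints of the same probe (ratio
distribution per array, correlation per duplicated transcript across
arrays).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ArraySample, ControlType, Orientation, ProbeRecord, SignalMatrix

RATIO_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class DetectionSummary:
    n_never_found: int
    n_always_found: int
    n_found_ge_k: int
    k: int
    n_probes: int


def detection_summary(m: SignalMatrix, k: int) -> DetectionSummary:
    """Tally probes never / always / in >= k arrays detected."""
    n_arrays = m.shape[1]
    if not 1 <= k <= n_arrays:
        raise ValueError(f"k must be in [1, {n_arrays}], got {k}")
    counts = m.found.to_numpy(dtype=bool).sum(axis=1)
    return DetectionSummary(
        n_never_found=int((counts == 0).sum()),
        n_always_found=int((counts == n_arrays).sum()),
        n_found_ge_k=int((counts >= k).sum()),
        k=k,
        n_probes=m.shape[0],
    )


def replicate_correlation(
    m: SignalMatrix,
    samples: Sequence[ArraySample],
    group: Callable[[ArraySample], bool] | None = None,
    log2: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and two-sided p) over the full probe vector.

    Computed on linear-scale normalized values by default; set ``log2`` for
    log-scale correlations.
    """
    selected = [s for s in samples if (group is None or group(s))]
    ids = [s.array_id for s in selected if s.array_id in m.values.columns]
    if len(ids) < 2:
        raise ValueError("need >= 2 arrays in the filtered group")
    x = m.values[ids].to_numpy(dtype=float)
    if log2:
        x = np.log2(x + 1.0)
    for j, aid in enumerate(ids):
        if np.isclose(x[:, j].std(), 0.0):
            raise ValueError(f"array {aid!r} has zero variance; r undefined")
    r = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    p = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            res = stats.pearsonr(x[:, i], x[:, j])
            r.iloc[i, j] = r.iloc[j, i] = res.statistic
            p.iloc[i, j] = p.iloc[j, i] = res.pvalue
    return r, p


@dataclass
class DuplicateAgreement:
    """Duplicate-probe diagnostics.

    ``fc_summary``: per array, quantiles of the copy-1 / copy-2 ratio
    (healthy arrays centre near 1). ``pair_correlations``: per duplicated
    transcript, Pearson r of (copy1, copy2) across arrays.
    ``n_skipped_zero``: (transcript, array) ratio cells skipped because a
    copy signal was 0.
    """

    fc_summary: pd.DataFrame
    pair_correlations: pd.Series
    n_skipped_zero: int


def duplicate_probe_agreement(
    m: SignalMatrix, annotation: Sequence[ProbeRecord]
) -> DuplicateAgreement:
    by_transcript: dict[str, dict[int, str]] = {}
    for rec in annotation:
        if rec.control_type is not ControlType.EXPERIMENTAL:
            continue
        if rec.orientation is Orientation.SENSE:
            by_transcript.setdefault(rec.transcript_id, {})[rec.copy_index] = rec.probe_id
    pairs = {
        t: (copies[1], copies[2])
        for t, copies in by_transcript.items()
        if 1 in copies and 2 in copies
    }
    if not pairs:
        raise ValueError("no duplicated transcripts in annotation")

    t_ids = sorted(pairs)
    c1 = m.values.loc[[pairs[t][0] for t in t_ids]].to_numpy(dtype=float)
    c2 = m.values.loc[[pairs[t][1] for t in t_ids]].to_numpy(dtype=float)

    ok = (c1 > 0) & (c2 > 0)
    n_skipped = int((~ok).sum())
    ratio = np.where(ok, c1 / np.where(c2 > 0, c2, 1.0), np.nan)
    qs = {}
    for j, aid in enumerate(m.values.columns):
        col = ratio[:, j]
        col = col[np.isfinite(col)]
        qs[aid] = np.quantile(col, RATIO_QUANTILES) if col.size else [np.nan] * 5
    fc_summary = pd.DataFrame(qs, index=[f"q{int(q * 100)}" for q in RATIO_QUANTILES]).T

    corr = {}
    for i, t in enumerate(t_ids):
        a, b = c1[i], c2[i]
        if np.isclose(a.std(), 0) or np.isclose(b.std(), 0):
            corr[t] = np.nan
        else:
            corr[t] = stats.pearsonr(a, b).statistic
    return DuplicateAgreement(fc_summary, pd.Series(corr, name="pearson_r"), n_skipped)
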