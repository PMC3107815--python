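"""Between-array normalization for one-color data.

Two methods are provided — quantile and cyclic loess — together with the
spike-in criterion used to choose between them: after normalization the
exogenous spike-in controls should be uniform across arrays, so the method
with the smaller summed spike coefficient of variation wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ControlType, ProbeRecord, SignalMatrix


@dataclass
class NormalizationReport:
    method: str  # "quantile" | "cyclic_loess"
    spike_cv_total: float
    chosen: bool


def _quantile_column(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map one column onto the reference distribution.

    Value at rank r becomes reference[r]; tied input values receive the mean
    of the reference values across their rank span.
    """
    order = np.argsort(col, kind="stable")
    out = np.empty_like(reference)
    out[order] = reference
    sorted_vals = col[order]
    # average the reference over each run of ties
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(col)]))
    for s, e in zip(starts, ends):
        if e - s > 1:
            out[order[s:e]] = reference[s:e].mean()
    return out


def quantile_normalize(m: SignalMatrix) -> SignalMatrix:
    """Force every array to share the mean order-statistic distribution."""
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("empty matrix")
    x = m.values.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.column_stack([_quantile_column(x[:, j], reference) for j in range(x.shape[1])])
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return SignalMatrix(values, m.found.copy())


def cyclic_loess_normalize(
    m: SignalMatrix, span: float = 0.3, iterations: int = 3
) -> SignalMatrix:
    """Pairwise MA-trend loess normalization on log2(x+1).

    For each array pair an M-vs-A loess trend is fitted and half of it is
    subtracted from each member; the full cycle over pairs repeats
    ``iterations`` times. Output is back-transformed to the linear scale.
    """
    if m.shape[1] < 2:
        raise ValueError("cyclic loess needs >= 2 arrays")
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0,1], got {span}")
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    y = np.log2(m.values.to_numpy(dtype=float) + 1.0)
    n = y.shape[1]
    for _ in range(iterations):
        for i in range(n - 1):
            for j in range(i + 1, n):
                mdiff = y[:, i] - y[:, j]
                avg = 0.5 * (y[:, i] + y[:, j])
                fit = lowess(mdiff, avg, frac=span, return_sorted=False)
                y[:, i] -= fit / 2.0
                y[:, j] += fit / 2.0
    out = np.clip(np.exp2(y) - 1.0, 0.0, None)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return SignalMatrix(values, m.found.copy())


def _spike_ids(annotation: Sequence[ProbeRecord]) -> list[str]:
    return [r.probe_id for r in annotation if r.control_type is ControlType.SPIKE_IN]


def spike_cv(m: SignalMatrix, annotation: Sequence[ProbeRecord]) -> float:
    """Sum over spike probes of the across-array coefficient of variation."""
    ids = [p for p in _spike_ids(annotation) if p in m.values.index]
    if not ids:
        raise ValueError("no spike-in probes present")
    total = 0.0
    for p in ids:
        vals = m.values.loc[p].to_numpy(dtype=float)
        mean = vals.mean()
        if mean == 0:
            raise ValueError(f"spike probe {p!r} has zero mean signal")
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        total += sd / mean
    return float(total)


def drop_negative_controls(m: SignalMatrix, annotation: Sequence[ProbeRecord]) -> SignalMatrix:
    """Exclude negative-control features; experimental + spike-ins remain."""
    keep = [
        r.probe_id
        for r in annotation
        if r.control_type is not ControlType.NEGATIVE and r.probe_id in m.values.index
    ]
    return m.subset_probes(keep)


def choose_normalization(
    m: SignalMatrix,
    annotation: Sequence[ProbeRecord],
    span: float = 0.3,
    iterations: int = 3,
) -> tuple[SignalMatrix, list[NormalizationReport]]:
    """Run both methods and keep the one with the smaller spike CV.

    Ties go to quantile. With a single array, quantile is the identity and
    is chosen trivially.
    """
    m = drop_negative_controls(m, annotation)
    q = quantile_normalize(m)
    cv_q = spike_cv(q, annotation)
    if m.shape[1] < 2:
        reports = [NormalizationReport("quantile", cv_q, True)]
        return q, reports
    c = cyclic_loess_normalize(m, span=span, iterations=iterations)
    cv_c = spike_cv(c, annotation)
    quantile_wins = cv_q <= cv_c
    reports = [
        NormalizationReport("quantile", cv_q, quantile_wins),
        NormalizationReport("cyclic_loess", cv_c, not quantile_wins),
    ]
    return (q if quantile_wins else c), reports


def report_frame(reports: Sequence[NormalizationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": [r.method for r in reports],
            "spike_cv_total": [r.spike_cv_total for r in reports],
            "chosen": [int(r.chosen) for r in reports],
        }
    )
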