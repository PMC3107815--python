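"""Two-class unpaired SAM (significance analysis of microarrays).

The method ranks probes by a regularized relative-difference statistic

    d_i = (mean2_i - mean1_i) / (s_i + s0)

where ``s_i`` is the pooled standard error of the group-mean difference and
``s0`` (the fudge factor) is a small constant chosen to stabilize the
variance of ``d`` across the expression range. Significance is assessed
against a permutation null: group labels are permuted (exhaustively when the
number of distinct assignments is small, otherwise by seeded sampling), the
expected order statistics ``dbar`` are formed, and for each threshold
``delta`` the called set is the probes whose sorted ``d`` departs from
``dbar`` by more than ``delta`` on either tail (asymmetric cutoffs). The
false discovery rate of each called set is estimated from the number of
permuted ``d`` values falling beyond the same cutoffs, scaled by an
estimate of the null proportion ``pi0``; a probe's q-value is the smallest
estimated FDR over all ``delta`` whose called set contains it.

All statistics are computed on log2(x + 1) of normalized signals; fold
changes are reported on the linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ArraySample, ControlType, Orientation, ProbeRecord, SignalMatrix

UP_IN_GROUP2 = "up_in_group2"
UP_IN_GROUP1 = "up_in_group1"

DEFAULT_S0_GRID = tuple(range(0, 101, 5))


@dataclass
class SamConfig:
    n_permutations: int = 200
    seed: int = 0
    fdr_target: float = 0.10
    fc_threshold: float = 1.0  # linear scale; 1 disables the filter
    s0_percentile_grid: Sequence[float] = DEFAULT_S0_GRID
    exhaustive_limit: int = 1000  # enumerate all assignments when <= this
    n_delta: int = 101

    def validate(self) -> None:
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must be in (0,1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1 (1 disables)")
        if self.n_permutations < 50:
            raise ValueError("n_permutations must be >= 50 when sampling")


@dataclass
class SamOutput:
    results: pd.DataFrame  # probe_id, d, fold_change, direction, q_value, called
    delta_table: pd.DataFrame  # delta, n_called, mean_false, median_false, fdr
    s0: float
    pi0: float
    n_permutations: int
    exhaustive: bool
    seed: int
    excluded_probes: list[str]
    contrast: tuple[str, str, str]


def _group_moments(x: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = x[:, idx]
    return sub.mean(axis=1), sub


def sam_statistic(x1: np.ndarray, x2: np.ndarray, s0: float) -> float:
    """Relative difference for one probe (group2 mean - group1 mean)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs >= 2 values")
    n1, n2 = x1.size, x2.size
    ss = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return float((x2.mean() - x1.mean()) / (s + s0))


def _r_and_s(x: np.ndarray, masks: np.ndarray, n1: int, n2: int):
    """Vectorized numerators and pooled SEs for B label assignments.

    ``x`` is (probes, arrays); ``masks`` is (B, arrays) with 1 marking
    group 2. Returns (probes, B) arrays.
    """
    m = masks.T.astype(float)  # (arrays, B)
    sum2 = x @ m
    sum1 = x @ (1.0 - m)
    mean2 = sum2 / n2
    mean1 = sum1 / n1
    x2 = x**2
    sq2 = x2 @ m
    sq1 = x2 @ (1.0 - m)
    ss = (sq1 - n1 * mean1**2) + (sq2 - n2 * mean2**2)
    ss = np.clip(ss, 0.0, None)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return mean2 - mean1, s


def estimate_s0(
    r: np.ndarray, s: np.ndarray, grid: Sequence[float] = DEFAULT_S0_GRID, n_windows: int = 100
) -> float:
    """Fudge factor: the s-percentile candidate that stabilizes var(d).

    For each candidate s0 (percentiles of the s distribution, plus 0) the
    probes are split into s-quantile windows; the spread of d = r/(s+s0) in
    each window is summarized by a scaled MAD and the candidate minimizing
    the coefficient of variation of those window spreads wins. Ties go to
    the smallest candidate.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.all(s == 0):
        warnings.warn("all standard errors are zero; using floor s0")
        return 1e-8
    # candidate 0 is the constant zero, not the 0th percentile of s
    candidates = sorted(
        {0.0} | {float(np.percentile(s, p)) for p in grid if p > 0}
    )
    n = len(s)
    n_windows = max(2, min(n_windows, n // 10)) if n >= 20 else 2
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)
    best_cv, best_s0 = np.inf, candidates[0]
    for s0 in candidates:
        den = s + s0
        if (den == 0).any():
            continue  # candidate cannot regularize zero-variance probes
        d = r / den
        mads = np.array([stats.median_abs_deviation(d[w]) / 0.64 for w in windows])
        mean = mads.mean()
        cv = mads.std(ddof=0) / mean if mean > 0 else 0.0
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def _assignments(n: int, n2: int, config: SamConfig) -> tuple[np.ndarray, bool]:
    total = comb(n, n2)
    if total < 10:
        raise ValueError(
            f"only {total} distinct label assignments; add replicates for a permutation test"
        )
    if total <= config.exhaustive_limit:
        masks = np.zeros((total, n), dtype=bool)
        for b, combo in enumerate(combinations(range(n), n2)):
            masks[b, list(combo)] = True
        return masks, True
    rng = np.random.default_rng(config.seed)
    masks = np.zeros((config.n_permutations, n), dtype=bool)
    for b in range(config.n_permutations):
        masks[b, rng.choice(n, size=n2, replace=False)] = True
    return masks, False


def _exclusion_mask(found: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """True for probes to exclude: not detected in >= half of either group."""
    miss1 = (~found[:, idx1]).sum(axis=1)
    miss2 = (~found[:, idx2]).sum(axis=1)
    return (2 * miss1 >= len(idx1)) | (2 * miss2 >= len(idx2))


def sam_two_class(
    m: SignalMatrix,
    samples: Sequence[ArraySample],
    contrast: tuple[str, str, str],
    config: SamConfig | None = None,
    annotation: Sequence[ProbeRecord] | None = None,
) -> SamOutput:
    """Run SAM for a two-group contrast.

    ``contrast`` is (attribute, group1, group2) with attribute "tissue" or
    "site"; d > 0 means higher in group2. When ``annotation`` is given,
    control features (spike-ins, negatives) are excluded from testing.
    """
    config = config or SamConfig()
    config.validate()
    if annotation is not None:
        experimental = [
            r.probe_id
            for r in annotation
            if r.control_type is ControlType.EXPERIMENTAL and r.probe_id in m.values.index
        ]
        m = m.subset_probes(experimental)
    attr, g1, g2 = contrast
    ids1 = [s.array_id for s in samples if getattr(s, attr).value == g1 and s.array_id in m.values.columns]
    ids2 = [s.array_id for s in samples if getattr(s, attr).value == g2 and s.array_id in m.values.columns]
    if len(ids1) < 2 or len(ids2) < 2:
        raise ValueError(f"both groups need >= 2 arrays (got {len(ids1)} vs {len(ids2)})")
    cols = ids1 + ids2
    x = np.log2(m.values[cols].to_numpy(dtype=float) + 1.0)
    found = m.found[cols].to_numpy(dtype=bool)
    n1, n2 = len(ids1), len(ids2)
    idx1 = np.arange(n1)
    idx2 = np.arange(n1, n1 + n2)

    exclude = _exclusion_mask(found, idx1, idx2)
    excluded_probes = [p for p, e in zip(m.probes, exclude) if e]
    keep = ~exclude
    probe_ids = [p for p, k in zip(m.probes, keep) if k]
    x = x[keep]
    if x.shape[0] == 0:
        raise ValueError("all probes excluded by the detection filter")

    observed_mask = np.zeros((1, n1 + n2), dtype=bool)
    observed_mask[0, idx2] = True
    r_obs, s_obs = _r_and_s(x, observed_mask, n1, n2)
    r_obs, s_obs = r_obs[:, 0], s_obs[:, 0]
    s0 = estimate_s0(r_obs, s_obs, config.s0_percentile_grid)
    if s0 == 0.0 and (s_obs == 0).any():
        s0 = 1e-8  # keep d finite for zero-variance probes
    d_obs = r_obs / (s_obs + s0)

    masks, exhaustive = _assignments(n1 + n2, n2, config)
    r_null, s_null = _r_and_s(x, masks, n1, n2)
    d_null = r_null / (s_null + s0)

    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]
    dbar = np.sort(d_null, axis=0).mean(axis=1)

    # pi0: fraction of observed d inside the permutation ensemble's IQR
    q25, q75 = np.percentile(d_null, [25, 75])
    pi0 = min(1.0, 2.0 * float(np.mean((d_obs > q25) & (d_obs < q75))))

    n_probes = d_sorted.size
    mid = int(np.argmin(np.abs(d_sorted)))
    g = d_sorted - dbar
    g_up = g[mid:]
    g_dn = g[:mid + 1][::-1]  # from the middle downward

    deltas = np.linspace(0.0, float(np.abs(g).max()) + 1e-12, config.n_delta)
    cut_up = np.empty(deltas.size)
    cut_dn = np.empty(deltas.size)
    for k, delta in enumerate(deltas):
        hits = np.flatnonzero(g_up > delta)
        cut_up[k] = d_sorted[mid + hits[0]] if hits.size else np.inf
        hits = np.flatnonzero(g_dn < -delta)
        cut_dn[k] = d_sorted[mid - hits[0]] if hits.size else -np.inf

    n_called = np.empty(deltas.size, dtype=int)
    mean_false = np.empty(deltas.size)
    med_false = np.empty(deltas.size)
    fdr = np.empty(deltas.size)
    for k in range(deltas.size):
        called = (d_obs >= cut_up[k]) | (d_obs <= cut_dn[k])
        n_called[k] = int(called.sum())
        counts = (d_null >= cut_up[k]).sum(axis=0) + (d_null <= cut_dn[k]).sum(axis=0)
        mean_false[k] = float(np.mean(counts))
        med_false[k] = float(np.median(counts))
        # average falsely-called count over the permutation ensemble (the
        # original SAM estimator); the median is reported alongside
        fdr[k] = min(1.0, pi0 * mean_false[k] / max(1, n_called[k]))

    # q(i) = min FDR over deltas whose called set contains i; called sets
    # nest as delta grows, so this is the prefix minimum of FDR evaluated at
    # the largest delta still calling i.
    prefix_min_fdr = np.minimum.accumulate(fdr)
    q = np.ones(n_probes)
    # cut_up is non-decreasing and cut_dn non-increasing in delta, so the
    # largest delta index still calling a probe is found by bisection
    k_up = np.searchsorted(cut_up, d_obs, side="right") - 1  # largest k: cut_up[k] <= d
    k_dn = deltas.size - 1 - np.searchsorted(cut_dn[::-1], d_obs, side="left")  # largest k: cut_dn[k] >= d
    up_called = k_up >= 0
    q[up_called] = prefix_min_fdr[k_up[up_called]]
    dn_called = k_dn >= 0
    q[dn_called] = np.minimum(q[dn_called], prefix_min_fdr[k_dn[dn_called]])

    lfc = r_obs  # mean log2 difference (group2 - group1)
    fold_change = np.exp2(np.abs(lfc))
    direction = np.where(lfc > 0, UP_IN_GROUP2, UP_IN_GROUP1)
    called = (q <= config.fdr_target) & (fold_change >= config.fc_threshold)

    results = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "d": d_obs,
            "fold_change": fold_change,
            "direction": direction,
            "q_value": q,
            "called": called,
        }
    )
    delta_table = pd.DataFrame(
        {
            "delta": deltas,
            "n_called": n_called,
            "mean_false": mean_false,
            "median_false": med_false,
            "fdr_raw": fdr,
            "fdr": prefix_min_fdr,  # monotone non-increasing in delta
        }
    )
    return SamOutput(
        results=results,
        delta_table=delta_table,
        s0=s0,
        pi0=pi0,
        n_permutations=masks.shape[0],
        exhaustive=exhaustive,
        seed=config.seed,
        excluded_probes=excluded_probes,
        contrast=contrast,
    )


def probe_to_transcript_summary(
    results: pd.DataFrame, annotation: Sequence[ProbeRecord]
) -> pd.DataFrame:
    """Collapse per-probe calls to per-transcript significance.

    A transcript is significant if any of its probes is called; its
    direction is the direction of its best-q called probe (q ties with
    conflicting directions are flagged ``ambiguous``).
    """
    probe_to_transcript = {
        r.probe_id: r.transcript_id
        for r in annotation
        if r.control_type is ControlType.EXPERIMENTAL
    }
    df = results.copy()
    df["transcript_id"] = df["probe_id"].map(probe_to_transcript)
    df = df.dropna(subset=["transcript_id"])
    rows = []
    for t, grp in df.groupby("transcript_id", sort=True):
        called = grp[grp["called"]]
        if called.empty:
            rows.append({"transcript_id": t, "significant": False, "direction": "", "best_q": float(grp["q_value"].min())})
            continue
        best_q = called["q_value"].min()
        best = called[called["q_value"] == best_q]
        dirs = set(best["direction"])
        direction = best["direction"].iloc[0] if len(dirs) == 1 else "ambiguous"
        rows.append({"transcript_id": t, "significant": True, "direction": direction, "best_q": float(best_q)})
    return pd.DataFrame(rows, columns=["transcript_id", "significant", "direction", "best_q"])


def direction_bias_test(n_up: int, n_total: int) -> float:
    """Exact two-sided binomial p under p = 0.5 for an up/down imbalance."""
    if not 0 <= n_up <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_up <= n_total, n_total >= 1")
    return float(stats.binomtest(n_up, n_total, 0.5, alternative="two-sided").pvalue)
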