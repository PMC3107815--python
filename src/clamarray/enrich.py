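"""Gene-set over-representation with the EASE score.

The EASE score is a conservative variant of the one-tailed Fisher exact
test: one hit is removed from the gene list before computing the
hypergeometric upper tail, which penalizes categories supported by very few
genes. Fold enrichment is the ratio of a term's proportion in the list to
its proportion in the background (all transcripts on the array).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentRecord:
    term_id: str
    count: int
    ease_p: float
    fisher_p: float
    fold_enrichment: float
    list_total: int
    pop_hits: int
    pop_total: int
    bh_adjusted: float = float("nan")


def _check_counts(count: int, list_total: int, pop_hits: int, pop_total: int) -> None:
    ok = (
        0 <= count <= list_total <= pop_total
        and 0 <= pop_hits <= pop_total
        and count <= pop_hits
    )
    if not ok:
        raise ValueError(
            f"inconsistent contingency counts: count={count}, list_total={list_total}, "
            f"pop_hits={pop_hits}, pop_total={pop_total}"
        )


def fisher_p(count: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """Plain one-tailed (over-representation) Fisher exact p: P[X >= count]."""
    _check_counts(count, list_total, pop_hits, pop_total)
    return float(hypergeom.sf(count - 1, pop_total, pop_hits, list_total))


def ease_score(count: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """One-removed Fisher tail: P[X >= count - 1]; a single hit scores 1."""
    _check_counts(count, list_total, pop_hits, pop_total)
    return float(hypergeom.sf(max(count - 1, 0) - 1, pop_total, pop_hits, list_total))


def fold_enrichment(count: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """(count/list_total) / (pop_hits/pop_total)."""
    if min(count, list_total, pop_hits, pop_total) < 1:
        raise ValueError("all counts must be >= 1 for fold enrichment")
    return (count / list_total) / (pop_hits / pop_total)


def enrich(
    gene_list: Iterable[str],
    background: Iterable[str],
    sets: Mapping[str, set[str]],
    min_count: int = 2,
    max_ease: float = 0.1,
) -> list[EnrichmentRecord]:
    """Score every gene set against the list/background contingency.

    Records with ``count >= min_count`` and ``ease_p <= max_ease`` are
    returned sorted by EASE p ascending (term id breaks ties). A
    Benjamini-Hochberg column over the *reported* terms is included.
    """
    glist = set(gene_list)
    bg = set(background)
    offenders = sorted(glist - bg)
    if offenders:
        raise ValueError(f"gene list members missing from background: {offenders[:20]}")
    list_total, pop_total = len(glist), len(bg)
    records: list[EnrichmentRecord] = []
    for term in sets:
        members = sets[term] & bg
        pop_hits = len(members)
        if pop_hits == 0:
            continue
        count = len(glist & members)
        if count < min_count or count == 0:
            continue
        p = ease_score(count, list_total, pop_hits, pop_total)
        if p > max_ease:
            continue
        records.append(
            EnrichmentRecord(
                term_id=term,
                count=count,
                ease_p=p,
                fisher_p=fisher_p(count, list_total, pop_hits, pop_total),
                fold_enrichment=fold_enrichment(count, list_total, pop_hits, pop_total),
                list_total=list_total,
                pop_hits=pop_hits,
                pop_total=pop_total,
            )
        )
    records.sort(key=lambda r: (r.ease_p, r.term_id))
    if records:
        adj = multipletests([r.ease_p for r in records], method="fdr_bh")[1]
        for r, a in zip(records, adj):
            r.bh_adjusted = float(a)
    return records


def records_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "count": [r.count for r in records],
            "ease_p": [r.ease_p for r in records],
            "fisher_p": [r.fisher_p for r in records],
            "bh_adjusted": [r.bh_adjusted for r in records],
            "fold_enrichment": [r.fold_enrichment for r in records],
            "list_total": [r.list_total for r in records],
            "pop_hits": [r.pop_hits for r in records],
            "pop_total": [r.pop_total for r in records],
        }
    )
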