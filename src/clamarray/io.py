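"""Readers and writers for the on-disk artifacts.

All tables are UTF-8 tab-delimited text with a header row (tolerant of
``\\n`` or ``\\r\\n`` line endings). The per-array signal dialect is the
minimal subset of a feature-extraction export actually consumed downstream:
``probe_id``, ``signal``, ``found`` (0/1).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

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

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["probe_id", "transcript_id", "orientation", "copy_index", "control_type"]
SIGNAL_COLUMNS = ["probe_id", "signal", "found"]
SAMPLE_COLUMNS = ["array_id", "tissue", "site", "pool_id"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")


def read_probe_annotation(path: str | Path) -> list[ProbeRecord]:
    """Parse a probe annotation table into validated :class:`ProbeRecord` s."""
    df = _read_tsv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} lacks columns: {missing}")
    records: list[ProbeRecord] = []
    for row in df.itertuples(index=False):
        try:
            orientation = Orientation(row.orientation)
        except ValueError:
            raise ValueError(
                f"unknown orientation token {row.orientation!r} for probe {row.probe_id!r}"
            ) from None
        try:
            control = ControlType(row.control_type)
        except ValueError:
            raise ValueError(
                f"unknown control_type token {row.control_type!r} for probe {row.probe_id!r}"
            ) from None
        records.append(
            ProbeRecord(
                probe_id=row.probe_id,
                transcript_id=row.transcript_id,
                orientation=orientation,
                copy_index=int(row.copy_index),
                control_type=control,
            )
        )
    validate_annotation(records)
    return records


def write_probe_annotation(records: Sequence[ProbeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "transcript_id": [r.transcript_id for r in records],
            "orientation": [r.orientation.value for r in records],
            "copy_index": [r.copy_index for r in records],
            "control_type": [r.control_type.value for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[ArraySample]:
    df = _read_tsv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns: {missing}")
    samples = [
        ArraySample(
            array_id=row.array_id,
            tissue=Tissue(row.tissue),
            site=Site(row.site),
            pool_id=row.pool_id,
        )
        for row in df.itertuples(index=False)
    ]
    ids = [s.array_id for s in samples]
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate array_id in sample sheet: {dup!r}")
    return samples


def write_sample_sheet(samples: Sequence[ArraySample], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "array_id": [s.array_id for s in samples],
            "tissue": [s.tissue.value for s in samples],
            "site": [s.site.value for s in samples],
            "pool_id": [s.pool_id for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def assemble_signal_matrix(
    per_array_tables: Sequence[str | Path],
    annotation: Sequence[ProbeRecord],
    array_ids: Sequence[str] | None = None,
) -> SignalMatrix:
    """Collate per-array signal tables into one :class:`SignalMatrix`.

    Arrays appear in input order. Probe sets must be identical across
    tables; negative input signals are clamped to 0 and the clamp count
    logged (feature-extraction background subtraction can go negative).
    """
    if not per_array_tables:
        raise ValueError("no signal tables given")
    if array_ids is None:
        array_ids = [Path(p).stem for p in per_array_tables]
    if len(array_ids) != len(per_array_tables):
        raise ValueError("array_ids length must match table count")

    probe_order = [r.probe_id for r in annotation]
    values: dict[str, pd.Series] = {}
    found: dict[str, pd.Series] = {}
    ref_set: set[str] | None = None
    n_clamped = 0
    for path, aid in zip(per_array_tables, array_ids):
        df = pd.read_csv(path, sep="\t", encoding="utf-8")
        missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"signal table {path} lacks columns: {missing}")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicated probe row {dup!r} in {path}")
        this_set = set(df["probe_id"])
        if ref_set is None:
            ref_set = this_set
        elif this_set != ref_set:
            diff = sorted(ref_set.symmetric_difference(this_set))
            raise ValueError(
                f"probe sets differ across arrays (symmetric difference: {diff[:20]}"
                f"{'...' if len(diff) > 20 else ''})"
            )
        sig = df.set_index("probe_id")["signal"].astype(float)
        neg = sig < 0
        n_clamped += int(neg.sum())
        sig = sig.clip(lower=0.0)
        values[aid] = sig
        found[aid] = df.set_index("probe_id")["found"].astype(int).astype(bool)

    assert ref_set is not None
    missing_probes = [p for p in probe_order if p not in ref_set]
    if missing_probes:
        raise ValueError(f"annotation probes absent from signal tables: {missing_probes[:20]}")
    if n_clamped:
        logger.warning("clamped %d negative signal values to 0", n_clamped)

    vdf = pd.DataFrame({a: values[a] for a in array_ids}).loc[probe_order]
    fdf = pd.DataFrame({a: found[a] for a in array_ids}).loc[probe_order]
    vdf.index.name = fdf.index.name = "probe_id"
    return SignalMatrix(vdf, fdf)


def write_signal_matrix(m: SignalMatrix, values_path: str | Path, found_path: str | Path | None = None) -> None:
    m.values.to_csv(values_path, sep="\t", float_format="%.17g")
    if found_path is not None:
        m.found.astype(int).to_csv(found_path, sep="\t")


def read_signal_matrix(values_path: str | Path, found_path: str | Path | None = None) -> SignalMatrix:
    vdf = pd.read_csv(values_path, sep="\t", index_col=0)
    if found_path is not None:
        fdf = pd.read_csv(found_path, sep="\t", index_col=0).astype(bool)
    else:
        fdf = pd.DataFrame(True, index=vdf.index, columns=vdf.columns)
    return SignalMatrix(vdf, fdf)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, members (tab-separated).

    Duplicate members within a term are de-duplicated; empty or malformed
    lines are skipped with a warning.
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("skipping malformed GMT line %d (%d field(s))", lineno, len(fields))
                continue
            term, _desc, *members = fields
            members = {m for m in members if m}
            if not members:
                logger.warning("skipping GMT term %r with empty member list", term)
                continue
            sets[term] = members
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sets:
            fh.write("\t".join([term, ""] + sorted(sets[term])) + "\n")


def write_result_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with header, full float precision."""
    records.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")
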