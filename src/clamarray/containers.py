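"""Core in-memory containers for the array platform.

The platform is a one-color oligo array in which many transcripts are
represented by a *pair* of 60-mer probes with opposite strand orientation
(sense / antisense), a subset of sense probes is printed twice on the array
(duplicate copies at different coordinates), and exogenous spike-in controls
are hybridized at fixed concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Orientation(str, Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"
    UNKNOWN = "unknown"


class ControlType(str, Enum):
    EXPERIMENTAL = "experimental"
    SPIKE_IN = "spike_in"
    NEGATIVE = "negative"


class Tissue(str, Enum):
    DIGESTIVE_GLAND = "digestive_gland"
    GILLS = "gills"


class Site(str, Enum):
    CLEAN = "clean"
    POLLUTED = "polluted"


@dataclass(frozen=True)
class ProbeRecord:
    """One array feature.

    ``copy_index`` distinguishes duplicate prints of the same probe design
    (>= 1); control probes (spike-in / negative) carry an empty
    ``transcript_id``.
    """

    probe_id: str
    transcript_id: str
    orientation: Orientation
    copy_index: int = 1
    control_type: ControlType = ControlType.EXPERIMENTAL

    def __post_init__(self) -> None:
        if self.copy_index < 1:
            raise ValueError(
                f"copy_index must be >= 1, got {self.copy_index} for {self.probe_id}"
            )
        if self.control_type is not ControlType.EXPERIMENTAL and self.transcript_id:
            raise ValueError(
                f"control probe {self.probe_id} must have empty transcript_id"
            )


@dataclass(frozen=True)
class ArraySample:
    """One hybridized array: tissue, sampling site and biological pool."""

    array_id: str
    tissue: Tissue
    site: Site
    pool_id: str


def validate_annotation(records: Sequence[ProbeRecord]) -> None:
    """Enforce annotation-level invariants.

    probe_id unique; (transcript_id, orientation, copy_index) unique among
    experimental probes.
    """
    seen_ids: set[str] = set()
    seen_keys: set[tuple[str, str, int]] = set()
    for rec in records:
        if rec.probe_id in seen_ids:
            raise ValueError(f"duplicate probe_id in annotation: {rec.probe_id!r}")
        seen_ids.add(rec.probe_id)
        if rec.control_type is ControlType.EXPERIMENTAL:
            key = (rec.transcript_id, rec.orientation.value, rec.copy_index)
            if key in seen_keys:
                raise ValueError(
                    f"duplicate (transcript, orientation, copy) triple: {key}"
                )
            seen_keys.add(key)


@dataclass
class SignalMatrix:
    """Probes x arrays fluorescence with per-cell detection flags.

    ``values`` holds nonnegative linear-scale fluorescence; ``found`` holds
    the scanner's detection flag (signal above background). Both frames are
    indexed by probe_id with array_id columns, in matching order.
    """

    values: pd.DataFrame
    found: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.found.index) or not self.values.columns.equals(
            self.found.columns
        ):
            raise ValueError("values and found must share index and columns")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated probe row in matrix: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("signal values must be finite")
        if (arr < 0).any():
            raise ValueError("signal values must be nonnegative")

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def arrays(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids: Iterable[str]) -> "SignalMatrix":
        ids = [p for p in probe_ids]
        return SignalMatrix(self.values.loc[ids].copy(), self.found.loc[ids].copy())

    def subset_arrays(self, array_ids: Iterable[str]) -> "SignalMatrix":
        ids = [a for a in array_ids]
        return SignalMatrix(self.values[ids].copy(), self.found[ids].copy())

    def copy(self) -> "SignalMatrix":
        return SignalMatrix(self.values.copy(), self.found.copy())
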