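"""Activity labeling and descriptor redundancy removal.

The single-concentration inhibition readout (% inhibition at 20 µM) is
thresholded at 40%: compounds at or above the threshold are actives and
receive the conventional bioassay activity score of 20, everything else is
inactive with score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable
from .errors import ValidationError

ACTIVITY_THRESHOLD = 40.0  # % inhibition at 20 µM; inclusive
ACTIVE_SCORE = 20
INACTIVE_SCORE = 0


@dataclass(frozen=True)
class AssayRecord:
    compound_id: str
    percent_inhibition: float
    activity_class: str  # "active" | "inactive"
    activity_score: int  # 20 | 0

    @classmethod
    def from_readout(cls, compound_id: str, percent_inhibition) -> "AssayRecord":
        try:
            value = float(percent_inhibition)
        except (TypeError, ValueError):
            raise ValidationError(
                f"compound {compound_id!r}: non-numeric inhibition readout "
                f"{percent_inhibition!r}"
            ) from None
        if not math.isfinite(value):
            raise ValidationError(
                f"compound {compound_id!r}: non-finite inhibition readout {value!r}"
            )
        cls_, score = label_activity(value)
        return cls(compound_id, value, cls_, score)


def label_activity(percent_inhibition: float) -> tuple[str, int]:
    """Label a readout: >= 40% inhibition -> ("active", 20), else ("inactive", 0)."""
    if not math.isfinite(percent_inhibition):
        raise ValidationError(f"non-finite inhibition readout {percent_inhibition!r}")
    if percent_inhibition >= ACTIVITY_THRESHOLD:
        return "active", ACTIVE_SCORE
    return "inactive", INACTIVE_SCORE


def read_assay_csv(path: str | Path) -> list[AssayRecord]:
    """Read ``compound_id,percent_inhibition`` and label every record."""
    df = pd.read_csv(path)
    required = {"compound_id", "percent_inhibition"}
    if not required.issubset(df.columns):
        raise ValidationError(f"assay CSV must have columns {sorted(required)}")
    return [
        AssayRecord.from_readout(str(row.compound_id), row.percent_inhibition)
        for row in df.itertuples()
    ]


def write_labeled_csv(records: Iterable[AssayRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.compound_id, r.percent_inhibition, r.activity_class, r.activity_score)
            for r in records
        ],
        columns=["compound_id", "percent_inhibition", "activity_class", "activity_score"],
    ).to_csv(path, index=False)


def labels_for(records: Iterable[AssayRecord], compound_ids: Iterable[str]) -> np.ndarray:
    """Activity classes aligned to ``compound_ids`` (1 = active, 0 = inactive)."""
    by_id = {r.compound_id: r for r in records}
    out = []
    for cid in compound_ids:
        if cid not in by_id:
            raise ValidationError(f"no assay record for compound {cid!r}")
        out.append(1 if by_id[cid].activity_class == "active" else 0)
    return np.array(out, dtype=int)


def remove_useless(
    table: DescriptorTable, max_identical_fraction: float = 0.99
) -> DescriptorTable:
    """Drop near-constant descriptor columns.

    A column is dropped when its single most common value accounts for strictly
    more than ``max_identical_fraction`` of the rows; constant columns are the
    special case fraction = 1.0. Surviving columns keep their original order and
    the row set is unchanged.
    """
    if len(table.compound_ids) == 0 or not table.columns:
        raise ValidationError("empty descriptor table")
    if not 0.0 < max_identical_fraction <= 1.0:
        raise ValidationError("max_identical_fraction must be in (0, 1]")
    n = len(table.compound_ids)
    keep = []
    for j in range(len(table.columns)):
        _, counts = np.unique(table.values[:, j], return_counts=True)
        if counts.max() / n <= max_identical_fraction:
            keep.append(j)
    if not keep:
        raise ValidationError("no informative descriptors: every column is near-constant")
    return DescriptorTable(
        compound_ids=list(table.compound_ids),
        columns=[table.columns[j] for j in keep],
        values=table.values[:, keep],
    )
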