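"""Dual-scale severity banding and three-group assignment.

Both screening instruments (MMSE and MoCA, each scored 0-30) are banded on
an ordinal 0-3 severity scale; the two levels are summed (0-6) and the sum
alone determines the group: 0-1 -> G1 (no/mild impairment), 2-3 -> G2
(moderate), 4-6 -> G3 (severe).  Scores must be integers; fractional input
is rejected rather than rounded, since silent rounding could flip a band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

# (low, high, scale) bands, inclusive at both ends
MOCA_BANDS = ((26, 30, 0), (18, 25, 1), (10, 17, 2), (0, 9, 3))
MMSE_BANDS = ((24, 30, 0), (18, 23, 1), (10, 17, 2), (0, 9, 3))

GROUPS = ("G1", "G2", "G3")


@dataclass
class PatientRecord:
    """One patient: raw scores, optional lesion reference, and the derived
    severity fields (filled by :func:`grade_record`)."""

    subject_id: str
    mmse: int
    moca: int
    lesion_volume: Optional[int] = None
    lesion_path: Optional[str] = None
    mmse_scale: Optional[int] = None
    moca_scale: Optional[int] = None
    combined: Optional[int] = None
    group: Optional[str] = None


def _check_score(value, name: str) -> int:
    if isinstance(value, bool):
        raise TypeError(f"{name} must be an integer score, got bool")
    if float(value) != int(value):
        raise ValueError(f"{name}={value} is not an integer (fractional scores are rejected)")
    value = int(value)
    if not 0 <= value <= 30:
        raise ValueError(f"{name}={value} outside the valid range [0, 30]")
    return value


def _band(value: int, bands) -> int:
    for low, high, scale in bands:
        if low <= value <= high:
            return scale
    raise AssertionError("bands must cover 0-30")  # pragma: no cover


def scale_moca(moca) -> int:
    """MoCA severity band: 26-30 -> 0, 18-25 -> 1, 10-17 -> 2, 0-9 -> 3."""
    return _band(_check_score(moca, "moca"), MOCA_BANDS)


def scale_mmse(mmse) -> int:
    """MMSE severity band: 24-30 -> 0, 18-23 -> 1, 10-17 -> 2, 0-9 -> 3."""
    return _band(_check_score(mmse, "mmse"), MMSE_BANDS)


def combined_level(moca, mmse) -> int:
    """Sum of the two 0-3 bands (0-6)."""
    return scale_moca(moca) + scale_mmse(mmse)


def assign_group(moca, mmse) -> str:
    """Three-group assignment from the combined level: 0-1 -> G1,
    2-3 -> G2, 4-6 -> G3."""
    combined = combined_level(moca, mmse)
    if combined <= 1:
        return "G1"
    if combined <= 3:
        return "G2"
    return "G3"


def grade_record(record: PatientRecord) -> PatientRecord:
    """Fill the derived severity fields of a record, in place, and return it."""
    record.moca_scale = scale_moca(record.moca)
    record.mmse_scale = scale_mmse(record.mmse)
    record.combined = record.moca_scale + record.mmse_scale
    record.group = assign_group(record.moca, record.mmse)
    return record


def grade_records(records: List[PatientRecord]) -> List[PatientRecord]:
    return [grade_record(r) for r in records]
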