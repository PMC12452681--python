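"""Electrode quality control ahead of fold-over detection.

Two stages mirror the clinical pre-processing of a trans-impedance matrix:

1. *Initial impedance check* — classify each contact from its main
   (diagonal) impedance: open above 30 kΩ, short-to-ground below 0.5 kΩ,
   and partial shorts between contact pairs whose cross-impedance
   approaches their main impedances.  Flagged contacts have their row and
   column removed.
2. *Data-integrity validation* — refuse to run the detector when more
   than three contacts were removed, or when any cross-impedance in the
   stimulation row of the most apical contact exceeds 5 kΩ (the signature
   of a case ground isolated from tissue, e.g. by an intraoperative air
   pocket).

Threshold comparisons are strict: a main impedance of exactly 30.0 or
0.5 kΩ is not flagged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .efi_model import EFIMatrix

__all__ = [
    "ContactStatus",
    "AbortReason",
    "QCThresholds",
    "QCReport",
    "initial_impedance_check",
    "validate_integrity",
    "preprocess",
]


class ContactStatus(str, enum.Enum):
    OK = "ok"
    OPEN = "open"
    SHORT_TO_GROUND = "short_to_ground"
    PARTIAL_SHORT = "partial_short"


class AbortReason(str, enum.Enum):
    NONE = "none"
    TOO_MANY_BAD = "too_many_bad"
    FIRSTROW_HIGH = "firstrow_high"


@dataclass(frozen=True)
class QCThresholds:
    """Tunable QC limits, all impedances in kΩ.

    ``open_kohm`` / ``short_kohm`` bound the acceptable main impedance;
    ``firstrow_kohm`` caps cross-impedances in the apical stimulation row;
    ``max_removed`` is the largest number of removed contacts the detector
    will tolerate; ``partial_short_ratio`` is the fraction of the smaller
    main impedance a cross-impedance must reach before a contact pair is
    called a partial short (the clinical rule states no formula; see the
    methods documentation).
    """

    open_kohm: float = 30.0
    short_kohm: float = 0.5
    firstrow_kohm: float = 5.0
    max_removed: int = 3
    partial_short_ratio: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.short_kohm < self.open_kohm:
            raise ValueError("require 0 < short_kohm < open_kohm")
        if self.max_removed < 0:
            raise ValueError("max_removed must be >= 0")
        if not 0.0 < self.partial_short_ratio <= 1.0:
            raise ValueError("partial_short_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class QCReport:
    """Per-contact QC classification plus the run/abort verdict."""

    status_per_contact: dict[int, ContactStatus]
    partial_short_pairs: tuple[tuple[int, int], ...]
    removed: tuple[int, ...]
    runnable: bool
    abort_reason: AbortReason
    reduced: EFIMatrix
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.runnable != (self.abort_reason is AbortReason.NONE):
            raise ValueError("runnable must be False iff abort_reason is set")


def _partial_short_pairs(
    m: EFIMatrix, t: QCThresholds, eligible: set[int]
) -> list[tuple[int, int]]:
    """Contact pairs whose cross-impedance approaches the main impedances.

    Only contacts in ``eligible`` (not already flagged open or shorted to
    ground — an out-of-range main impedance makes the ratio meaningless)
    are paired.  A pair (i, j) is flagged when *both* orientations of its
    cross-impedance reach ``partial_short_ratio`` of the smaller main
    impedance — a physical low-impedance path between two contacts shows
    in both measurement directions, unlike a single elevated row — and
    the cross stands clear of the typical level of both contacts' rows
    (more than twice either row's median off-diagonal), which suppresses
    flags in globally flat matrices.
    """
    v = m.values
    n = m.dim
    if n < 2:
        return []
    mask = ~np.eye(n, dtype=bool)
    row_median = np.array([np.median(v[i][mask[i]]) for i in range(n)])
    pairs: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if m.labels[i] not in eligible or m.labels[j] not in eligible:
                continue
            cross = min(v[i, j], v[j, i])
            limit = t.partial_short_ratio * min(v[i, i], v[j, j])
            guard = 2.0 * max(row_median[i], row_median[j])
            if cross >= limit and cross > guard:
                pairs.append((m.labels[i], m.labels[j]))
    return pairs


def initial_impedance_check(m: EFIMatrix, t: QCThresholds | None = None) -> QCReport:
    """Classify contacts and remove flagged rows/columns.

    Pure classification: never aborts; ``validate_integrity`` decides
    whether the reduced matrix may feed the detector.
    """
    t = t or QCThresholds()
    status: dict[int, ContactStatus] = {}
    for lbl in m.labels:
        z = m.values[m.label_index(lbl), m.label_index(lbl)]
        if z > t.open_kohm:
            status[lbl] = ContactStatus.OPEN
        elif z < t.short_kohm:
            status[lbl] = ContactStatus.SHORT_TO_GROUND
        else:
            status[lbl] = ContactStatus.OK

    eligible = {lbl for lbl, st in status.items() if st is ContactStatus.OK}
    pairs = tuple(_partial_short_pairs(m, t, eligible))
    for a, b in pairs:
        status[a] = ContactStatus.PARTIAL_SHORT
        status[b] = ContactStatus.PARTIAL_SHORT

    removed = tuple(lbl for lbl in m.labels if status[lbl] is not ContactStatus.OK)
    keep = [lbl for lbl in m.labels if status[lbl] is ContactStatus.OK]
    reduced = m.submatrix(keep) if removed else m
    return QCReport(
        status_per_contact=status,
        partial_short_pairs=pairs,
        removed=removed,
        runnable=True,
        abort_reason=AbortReason.NONE,
        reduced=reduced,
    )


def validate_integrity(r: QCReport, t: QCThresholds | None = None) -> QCReport:
    """Apply the run/abort rules to an initial-impedance-check report."""
    t = t or QCThresholds()
    notes = list(r.notes)

    if len(r.removed) > t.max_removed:
        return replace(
            r,
            runnable=False,
            abort_reason=AbortReason.TOO_MANY_BAD,
            notes=tuple(
                notes
                + [
                    f"{len(r.removed)} contacts out of range "
                    f"(limit {t.max_removed}): {list(r.removed)}"
                ]
            ),
        )

    reduced = r.reduced
    if reduced.dim >= 2:
        # The case-ground check reads the stimulation row of the most
        # apical surviving contact; normally that is electrode 1.
        apical = reduced.labels[0]
        if apical != min(r.status_per_contact):
            notes.append(
                f"most apical contact removed; case-ground check uses row {apical}"
            )
        i = reduced.label_index(apical)
        row = reduced.values[i].copy()
        cross = np.delete(row, i)
        if np.any(cross > t.firstrow_kohm):
            worst = float(cross.max())
            return replace(
                r,
                runnable=False,
                abort_reason=AbortReason.FIRSTROW_HIGH,
                notes=tuple(
                    notes
                    + [
                        f"cross-impedance {worst:.3g} kOhm in row {apical} exceeds "
                        f"{t.firstrow_kohm:g} kOhm (case-ground contact suspect)"
                    ]
                ),
            )

    return replace(r, runnable=True, abort_reason=AbortReason.NONE, notes=tuple(notes))


def preprocess(m: EFIMatrix, t: QCThresholds | None = None) -> QCReport:
    """Full QC pass: impedance check followed by integrity validation."""
    t = t or QCThresholds()
    return validate_integrity(initial_impedance_check(m, t), t)
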