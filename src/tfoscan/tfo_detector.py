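"""Tip fold-over detection from a trans-impedance matrix.

The detector treats each stimulation row of the (QC-reduced, optionally
log-transformed) matrix as one observation and projects the rows onto
their first two principal components.  Plotted in order of electrode
label, the projections form the ΔZ polyline: a normally inserted array
traces a smooth curve with obtuse interior angles, while a fold-over
doubles the trace back on itself, producing a sharp (acute) bend at the
fold contact.  A fold is reported when

* the minimum interior turning angle falls below ``angle_threshold_deg``
  at a contact other than the apical guard contact, and
* (by default) the row-wise decay-reversal consensus — the modal location
  where cross-impedance decay toward the apex turns back into a rise —
  agrees with the bend location to within ``agreement_tolerance``
  contacts.

Interior angles are measured at each vertex between the two adjacent
segments: 180° for a straight continuation, near 0° for a full
fold-back.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .efi_model import EFIMatrix
from .qc_preprocess import QCReport, QCThresholds, preprocess

__all__ = [
    "DetectorConfig",
    "DeltaZEmbedding",
    "DecayProfile",
    "TFOResult",
    "InsufficientContactsError",
    "MIN_CONTACTS",
    "embed_delta_z",
    "decay_reversal",
    "detect_tfo",
    "symmetry_score",
]

#: Fewer than five surviving contacts cannot support bend analysis.
MIN_CONTACTS = 5


class InsufficientContactsError(ValueError):
    """Raised when too few contacts survive QC for the ΔZ embedding."""


@dataclass(frozen=True)
class DetectorConfig:
    """Free parameters of the detection criterion.

    ``log_transform`` applies log10 before PCA (cross-impedances span an
    order of magnitude; the log also makes the verdict invariant to a
    global impedance scale).  ``angle_threshold_deg`` separates the
    obtuse angles of a smooth trace from the acute bend of a fold.
    ``apical_guard`` exempts the most apical contact(s) from being called
    a fold site, matching the clinical rule that the criterion must fire
    at a contact other than electrode 1.  ``require_decay_reversal``
    demands row-level corroboration; ``reversal_guard_frac`` is the
    fraction of a row's cross-impedance dynamic range a post-minimum rise
    must exceed to count as a reversal rather than jitter.
    ``mask_diagonal`` (default on) replaces each main impedance with the
    mean of its neighboring cross-impedances before PCA: contact access
    resistance varies idiosyncratically between contacts and carries no
    placement information, so leaving the raw diagonal in jitters the
    polyline; set False to embed the raw matrix.
    """

    log_transform: bool = True
    angle_threshold_deg: float = 90.0
    apical_guard: int = 1
    agreement_tolerance: int = 1
    require_decay_reversal: bool = True
    reversal_guard_frac: float = 0.05
    mask_diagonal: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_threshold_deg < 180.0:
            raise ValueError("angle_threshold_deg must lie in (0, 180)")
        if self.agreement_tolerance < 0:
            raise ValueError("agreement_tolerance must be >= 0")


@dataclass(frozen=True)
class DeltaZEmbedding:
    """Ordered PC1/PC2 scores per surviving electrode, with turn angles."""

    labels: tuple[int, ...]
    points: np.ndarray  # (n, 2)
    variance_explained: tuple[float, float]
    turning_angle_deg: dict[int, float]  # interior labels only

    def min_angle(self) -> tuple[int, float]:
        """(label, angle) of the sharpest interior vertex; ties break
        toward the more apical (smaller) label."""
        label = min(
            self.turning_angle_deg,
            key=lambda lbl: (self.turning_angle_deg[lbl], lbl),
        )
        return label, self.turning_angle_deg[label]


@dataclass(frozen=True)
class DecayProfile:
    """Row-wise decay-reversal scan results."""

    reversal_flags: dict[int, bool]  # stimulating label -> reversal seen
    reversal_index: dict[int, int]  # stimulating label -> reversal label
    consensus: int | None  # modal reversal label, None if no reversals

    def n_reversals(self) -> int:
        return sum(self.reversal_flags.values())


@dataclass(frozen=True)
class TFOResult:
    """Detection verdict with its evidence trail."""

    tfo_detected: bool
    fold_electrode: int | None
    min_angle_deg: float | None
    min_angle_electrode: int | None
    decay_reversal_electrode: int | None
    qc: QCReport
    embedding: DeltaZEmbedding | None = None
    symmetry: float | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ran(self) -> bool:
        """Whether the detector actually executed (QC allowed the run)."""
        return self.qc.runnable


def _interior_angles(points: np.ndarray, labels: tuple[int, ...]) -> dict[int, float]:
    """Interior angle at each vertex between its adjacent segments.

    180° means the polyline continues straight; small angles mean it
    doubles back.  Degenerate zero-length segments yield 180° (no turn
    information).
    """
    angles: dict[int, float] = {}
    for k in range(1, len(points) - 1):
        u = points[k - 1] - points[k]
        v = points[k + 1] - points[k]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            angles[labels[k]] = 180.0
            continue
        c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
        angles[labels[k]] = float(np.degrees(np.arccos(c)))
    return angles


def _feature_matrix(reduced: EFIMatrix, cfg: DetectorConfig) -> np.ndarray:
    x = reduced.values.copy()
    if cfg.mask_diagonal:
        n = x.shape[0]
        for i in range(n):
            neigh = [x[i, j] for j in (i - 1, i + 1) if 0 <= j < n]
            x[i, i] = float(np.mean(neigh))
    if cfg.log_transform:
        x = np.log10(x)
    return x


def embed_delta_z(reduced: EFIMatrix, cfg: DetectorConfig | None = None) -> DeltaZEmbedding:
    """Project stimulation rows onto their first two principal components.

    Rows are the observations (one per stimulating electrode, features =
    the impedances recorded on each contact), mean-centered per feature;
    components come from the singular value decomposition.  The sign
    convention — PC1 increasing from the apical to the basal end of the
    polyline — only serves plot reproducibility; turning angles are
    invariant under either choice.
    """
    cfg = cfg or DetectorConfig()
    n = reduced.dim
    if n < MIN_CONTACTS:
        raise InsufficientContactsError(
            f"insufficient contacts: {n} survive QC, need >= {MIN_CONTACTS}"
        )
    x = _feature_matrix(reduced, cfg)
    xc = x - x.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = xc @ vt[:2].T
    total_var = float((s**2).sum())
    var12 = (
        (float(s[0] ** 2 / total_var), float(s[1] ** 2 / total_var))
        if total_var > 0
        else (0.0, 0.0)
    )
    if scores[0, 0] > scores[-1, 0]:
        scores[:, 0] *= -1.0
    if scores[0, 1] > scores[-1, 1]:
        scores[:, 1] *= -1.0
    return DeltaZEmbedding(
        labels=reduced.labels,
        points=scores,
        variance_explained=var12,
        turning_angle_deg=_interior_angles(scores, reduced.labels),
    )


def _row_reversal(row: np.ndarray, i: int, guard_frac: float) -> int | None:
    """First strict local minimum of the apical-going cross-impedance scan.

    Walks the row from the stimulating contact toward the apex (index
    ``i-1`` down to 0) with the main impedance prepended as the starting
    height.  A reversal exists when the values strictly decrease into a
    minimum and later rise above it by more than ``guard_frac`` of the
    row's cross-impedance dynamic range (off-diagonal values only — the
    large main impedance would otherwise swamp the guard); returns the
    0-based position of that minimum in the surviving order, else None.
    """
    if i < 2:
        return None  # no room for decay-then-rise toward the apex
    seq = np.concatenate(([row[i]], row[:i][::-1]))  # seq[k] = contact i-k
    off = np.delete(row, i)
    rng = float(off.max() - off.min())
    if rng <= 0.0:
        return None
    guard = guard_frac * rng
    for k in range(1, len(seq) - 1):
        if seq[k] < seq[k - 1] and seq[k] <= seq[: k + 1].min():
            rise = float(seq[k + 1 :].max() - seq[k])
            if rise > guard and seq[k + 1] > seq[k]:
                return i - k
    return None


def decay_reversal(
    reduced: EFIMatrix, guard_frac: float = 0.05
) -> DecayProfile:
    """Scan each stimulation row for a decay→rise reversal toward the apex.

    A normally placed array shows monotone cross-impedance decay with
    distance from the stimulating contact; a fold makes rows stimulating
    basal to it decay down to the fold contact and rise again over the
    reflected limb.  The consensus fold site is the modal reversal
    location over all rows that show one (ties break apical).
    """
    if reduced.dim < MIN_CONTACTS:
        raise InsufficientContactsError(
            f"insufficient contacts: {reduced.dim} survive QC, need >= {MIN_CONTACTS}"
        )
    flags: dict[int, bool] = {}
    index: dict[int, int] = {}
    for i, lbl in enumerate(reduced.labels):
        pos = _row_reversal(reduced.values[i], i, guard_frac)
        flags[lbl] = pos is not None
        if pos is not None:
            index[lbl] = reduced.labels[pos]
    consensus: int | None = None
    if index:
        counts = Counter(index.values())
        consensus = min(counts, key=lambda lbl: (-counts[lbl], lbl))
    return DecayProfile(reversal_flags=flags, reversal_index=index, consensus=consensus)


def symmetry_score(reduced: EFIMatrix, fold: int) -> float | None:
    """Mirror-symmetry evidence about a candidate fold contact, in [0, 1].

    For every row stimulating basal to the fold, cross-impedances at
    mirror positions ``fold-k`` / ``fold+k`` are correlated over the
    overlapping range (the fold reflects contact ``fold-k`` next to
    ``fold+k``, so a true fold makes the two profiles track each other).
    Returns the mean Pearson correlation mapped to [0, 1], or None when
    fewer than two mirror pairs exist — supporting evidence only, never a
    gate on detection.
    """
    fi = reduced.label_index(fold)
    n = reduced.dim
    if fi < 2 or fi > n - 3:
        return None  # need >=2 neighbors on each side
    rs: list[float] = []
    for i in range(fi + 2, n):  # rows basal to the fold, clear of it
        ks = [k for k in range(1, fi + 1) if fi + k < i]
        if len(ks) < 3:
            continue
        a = np.array([reduced.values[i, fi - k] for k in ks])
        b = np.array([reduced.values[i, fi + k] for k in ks])
        if a.std() == 0.0 or b.std() == 0.0:
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    if not rs:
        return None
    return float(np.clip((np.mean(rs) + 1.0) / 2.0, 0.0, 1.0))


def detect_tfo(
    m: EFIMatrix,
    qc_t: QCThresholds | None = None,
    cfg: DetectorConfig | None = None,
) -> TFOResult:
    """Full pipeline: QC, ΔZ embedding, bend + decay-reversal criterion.

    When QC refuses the run the result carries ``tfo_detected=False``
    with the QC verdict; callers distinguish "did not run" (``ran`` is
    False) from a negative finding.
    """
    cfg = cfg or DetectorConfig()
    qc = preprocess(m, qc_t)
    if not qc.runnable:
        return TFOResult(
            tfo_detected=False,
            fold_electrode=None,
            min_angle_deg=None,
            min_angle_electrode=None,
            decay_reversal_electrode=None,
            qc=qc,
            notes=("detector not run: " + qc.abort_reason.value,) + qc.notes,
        )

    reduced = qc.reduced
    emb = embed_delta_z(reduced, cfg)
    profile = decay_reversal(reduced, cfg.reversal_guard_frac)
    bend_label, bend_angle = emb.min_angle()

    notes: list[str] = list(qc.notes)
    notes.append(
        f"min interior angle {bend_angle:.1f} deg at electrode {bend_label}; "
        f"decay-reversal consensus: {profile.consensus}"
    )

    angle_hit = (
        bend_angle < cfg.angle_threshold_deg and bend_label > cfg.apical_guard
    )
    if cfg.require_decay_reversal:
        corroborated = (
            profile.consensus is not None
            and abs(profile.consensus - bend_label) <= cfg.agreement_tolerance
        )
    else:
        corroborated = True
    detected = bool(angle_hit and corroborated)

    sym = symmetry_score(reduced, bend_label) if detected else None
    if detected and sym is not None:
        notes.append(f"mirror-symmetry score {sym:.3f} about electrode {bend_label}")

    return TFOResult(
        tfo_detected=detected,
        fold_electrode=bend_label if detected else None,
        min_angle_deg=bend_angle,
        min_angle_electrode=bend_label,
        decay_reversal_electrode=profile.consensus,
        qc=qc,
        embedding=emb,
        symmetry=sym,
        notes=tuple(notes),
    )
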