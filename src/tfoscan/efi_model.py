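"""Domain types for electric field imaging (EFI) matrices.

An EFI measurement stimulates each intracochlear electrode contact in turn
with a small monopolar current pulse and records the voltage appearing on
every contact.  Dividing by the applied current yields a square
trans-impedance matrix: the diagonal holds the monopolar main impedances of
the stimulating contacts, the off-diagonals the cross-impedances picked up
on the non-stimulating contacts.  All values are stored in kilo-ohms.

Electrode labels run 1..16 with label 1 the most apical contact and label
16 the most basal one.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "MAX_CONTACTS",
    "EFIMatrix",
    "EFIFormatError",
    "StimulationParams",
    "read_efi",
    "write_efi",
]

#: Every supported electrode array carries 16 individual contacts.
MAX_CONTACTS = 16

#: CSV cell format: 12 significant digits — byte-stable for a fixed matrix
#: and round-trips clinical-scale impedances to well below 1e-9 kOhm.
_CSV_FLOAT_FORMAT = "%.12g"

_LABEL_RE = re.compile(r"^[eE]?(\d+)$")


class EFIFormatError(ValueError):
    """Raised when a serialized EFI matrix violates the format contract."""


@dataclass(frozen=True)
class StimulationParams:
    """Stimulus metadata for an EFI run (recorded, never used in math).

    Defaults follow the clinical measurement protocol: 32 µA biphasic
    cathodic-leading pulses of 17.96 µs per phase in a monopolar circuit.
    """

    amplitude_ua: float = 32.0
    phase_width_us: float = 17.96
    polarity: str = "cathodic-leading"
    configuration: str = "monopolar"


@dataclass(frozen=True)
class EFIMatrix:
    """A square trans-impedance matrix with electrode labels and metadata.

    Parameters
    ----------
    values
        ``(dim, dim)`` array in kΩ; ``values[i, j]`` is the impedance seen
        on the contact ``labels[j]`` while stimulating ``labels[i]``.
    labels
        Ordered electrode labels (integers, apical first).  Must match the
        matrix dimension.
    meta
        Free-form record: implant type, electrode array type, array family
        (``pre-curved`` / ``straight-lateral-wall`` / ``unknown``), source
        id, timestamp.
    """

    values: np.ndarray
    labels: tuple[int, ...]
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(int(x) for x in self.labels))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise EFIFormatError(
                f"EFI matrix must be square, got shape {values.shape}"
            )
        dim = values.shape[0]
        if not 1 <= dim <= MAX_CONTACTS:
            raise EFIFormatError(
                f"EFI matrix dimension must be in 1..{MAX_CONTACTS}, got {dim}"
            )
        if len(self.labels) != dim:
            raise EFIFormatError(
                f"{len(self.labels)} labels for a {dim}x{dim} matrix"
            )
        if len(set(self.labels)) != dim:
            raise EFIFormatError("electrode labels must be unique")
        bad = np.argwhere(~np.isfinite(values) | (values <= 0.0))
        if bad.size:
            i, j = bad[0]
            raise EFIFormatError(
                "impedances must be finite and > 0 kOhm; offending cell "
                f"(row {i + 1}, col {j + 1}) = {values[i, j]!r}"
            )

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def main_impedances(self) -> np.ndarray:
        """Diagonal of the matrix: monopolar contact impedances, kΩ."""
        return np.diag(self.values)

    def label_index(self, label: int) -> int:
        """Position of ``label`` in the surviving order."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode label {label} not present") from None

    def submatrix(self, keep_labels: Sequence[int]) -> "EFIMatrix":
        """Matrix restricted to ``keep_labels``, original order preserved."""
        keep = [lbl for lbl in self.labels if lbl in set(keep_labels)]
        idx = [self.label_index(lbl) for lbl in keep]
        return EFIMatrix(
            values=self.values[np.ix_(idx, idx)],
            labels=tuple(keep),
            meta=dict(self.meta),
        )


def _parse_cell(token: str, row: int, col: int) -> float:
    try:
        x = float(token)
    except ValueError:
        raise EFIFormatError(
            f"non-numeric cell (row {row}, col {col}): {token!r}"
        ) from None
    if not np.isfinite(x) or x <= 0.0:
        raise EFIFormatError(
            f"non-positive or non-finite cell (row {row}, col {col}): {token!r}"
        )
    return x


def _read_csv(text: str) -> EFIMatrix:
    rows = [r for r in csv.reader(io.StringIO(text)) if any(c.strip() for c in r)]
    if not rows:
        raise EFIFormatError("empty CSV input")

    labels: list[int] | None = None
    first = [c.strip() for c in rows[0]]
    header_like = all(_LABEL_RE.match(c) for c in first if c) and not all(
        _is_number(c) for c in first if c
    )
    if header_like:
        labels = [int(_LABEL_RE.match(c).group(1)) for c in first if c]  # type: ignore[union-attr]
        rows = rows[1:]

    # optional label column: first token of each row like "e3"
    body: list[list[str]] = [[c.strip() for c in r] for r in rows]
    has_label_col = bool(body) and all(
        r and _LABEL_RE.match(r[0]) and not _is_number(r[0]) for r in body
    )
    if has_label_col:
        body = [r[1:] for r in body]

    n = len(body)
    if n == 0:
        raise EFIFormatError("CSV contains a header but no data rows")
    values = np.empty((n, n), dtype=float)
    for i, r in enumerate(body):
        if len(r) != n:
            raise EFIFormatError(
                f"non-square grid: row {i + 1} has {len(r)} cells, expected {n}"
            )
        for j, tok in enumerate(r):
            values[i, j] = _parse_cell(tok, i + 1, j + 1)
    if n > MAX_CONTACTS:
        raise EFIFormatError(f"grid dimension {n} exceeds {MAX_CONTACTS}")
    if labels is None:
        labels = list(range(1, n + 1))
    if len(labels) != n:
        raise EFIFormatError(
            f"header lists {len(labels)} labels for {n} data rows"
        )
    return EFIMatrix(values=values, labels=tuple(labels))


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _read_json(text: str) -> EFIMatrix:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise EFIFormatError(f"invalid JSON: {exc}") from None
    if not isinstance(doc, dict) or "values" not in doc:
        raise EFIFormatError("JSON record must be an object with a 'values' key")
    values = np.asarray(doc["values"], dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise EFIFormatError(f"JSON 'values' must be square, got {values.shape}")
    units = str(doc.get("units", "kOhm"))
    if units.lower() in ("ohm", "ohms"):
        values = values / 1000.0
    elif units.lower() not in ("kohm", "kohms"):
        raise EFIFormatError(f"unknown units {units!r} (expected kOhm or Ohm)")
    labels = doc.get("labels") or list(range(1, values.shape[0] + 1))
    meta = doc.get("meta") or {}
    return EFIMatrix(values=values, labels=tuple(int(x) for x in labels), meta=meta)


def read_efi(source: str, format: str = "csv") -> EFIMatrix:
    """Parse an EFI matrix from CSV or JSON text (or a path to either).

    CSV is a dim×dim numeric grid with an optional ``e1,...,e16`` header
    row and optional label column.  JSON carries ``values``, ``labels``,
    ``meta`` and an optional ``units`` field (``"Ohm"`` values are divided
    by 1000).  Values are returned in kΩ.
    """
    text = source
    if "\n" not in source and not source.lstrip().startswith(("{", "[")):
        # looks like a path, not inline content
        try:
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        except OSError:
            pass  # fall through: treat as inline text (e.g. "5.0")
    if format == "csv":
        return _read_csv(text)
    if format == "json":
        return _read_json(text)
    raise ValueError(f"unknown format {format!r}")


def write_efi(m: EFIMatrix, format: str = "csv") -> str:
    """Serialize an EFI matrix to CSV or JSON text.

    Round-trip safe: ``read_efi(write_efi(m))`` reproduces values to
    better than 1e-9 kΩ and labels exactly.  Output is byte-stable for a
    fixed matrix (fixed float format, sorted JSON keys).
    """
    if format == "csv":
        out = io.StringIO()
        writer = csv.writer(out, lineterminator="\n")
        writer.writerow([f"e{lbl}" for lbl in m.labels])
        for row in m.values:
            writer.writerow([_CSV_FLOAT_FORMAT % x for x in row])
        return out.getvalue()
    if format == "json":
        doc = {
            "labels": list(m.labels),
            "values": [[float(x) for x in row] for row in m.values],
            "meta": dict(m.meta),
            "units": "kOhm",
        }
        return json.dumps(doc, indent=1, sort_keys=True) + "\n"
    raise ValueError(f"unknown format {format!r}")
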