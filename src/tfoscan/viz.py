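"""Diagnostic plots: line/log plot, heat map, and the ΔZ polyline.

All plotting uses a fixed style so regenerated figures are stable; the
Agg backend is forced so plots work headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .efi_model import EFIMatrix
from .tfo_detector import (
    DetectorConfig,
    InsufficientContactsError,
    TFOResult,
    embed_delta_z,
)
from .qc_preprocess import QCThresholds, preprocess

__all__ = ["plot_efi", "PLOT_KINDS"]

PLOT_KINDS = ("line_log", "heatmap", "delta_z")

_STYLE = {
    "figure.figsize": (6.0, 4.5),
    "figure.dpi": 110,
    "axes.grid": True,
    "grid.alpha": 0.3,
    "font.size": 9,
}


def _plot_line_log(m: EFIMatrix, ax: plt.Axes) -> None:
    cmap = plt.get_cmap("viridis")
    for i, lbl in enumerate(m.labels):
        ax.plot(
            m.labels,
            m.values[i],
            color=cmap(i / max(m.dim - 1, 1)),
            lw=1.0,
            label=f"e{lbl}",
        )
    ax.set_yscale("log")
    ax.set_xlabel("recording electrode")
    ax.set_ylabel("impedance (kΩ)")
    ax.set_title("EFI line plot (one trace per stimulating electrode)")


def _plot_heatmap(m: EFIMatrix, ax: plt.Axes) -> None:
    im = ax.imshow(
        m.values,
        origin="upper",
        cmap="viridis",
        extent=(m.labels[0] - 0.5, m.labels[-1] + 0.5, m.labels[-1] + 0.5, m.labels[0] - 0.5),
    )
    ax.figure.colorbar(im, ax=ax, label="impedance (kΩ)")
    ax.set_xlabel("recording electrode")
    ax.set_ylabel("stimulating electrode")
    ax.set_title("EFI heat map")
    ax.grid(False)


def _plot_delta_z(
    m: EFIMatrix,
    ax: plt.Axes,
    qc_t: QCThresholds | None,
    cfg: DetectorConfig | None,
    result: TFOResult | None,
) -> None:
    qc = preprocess(m, qc_t)
    if not qc.runnable:
        raise ValueError(
            f"ΔZ plot unavailable: QC abort ({qc.abort_reason.value}); " + "; ".join(qc.notes)
        )
    try:
        emb = embed_delta_z(qc.reduced, cfg)
    except InsufficientContactsError as exc:
        raise ValueError(f"ΔZ plot unavailable: {exc}") from exc
    pts = emb.points
    ax.plot(pts[:, 0], pts[:, 1], "-o", color="tab:blue", ms=4, lw=1.2)
    for lbl, (x, y) in zip(emb.labels, pts):
        ax.annotate(str(lbl), (x, y), textcoords="offset points", xytext=(4, 4), fontsize=7)
    if result is not None and result.tfo_detected and result.fold_electrode in emb.labels:
        k = emb.labels.index(result.fold_electrode)
        ax.plot(*pts[k], "s", color="tab:red", ms=9, mfc="none", mew=1.6)
        ax.set_title(f"ΔZ plot — fold-over flagged at electrode {result.fold_electrode}")
    else:
        ax.set_title("ΔZ plot")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_aspect("equal", adjustable="datalim")


def plot_efi(
    m: EFIMatrix,
    kind: str,
    out: str | Path,
    qc_t: QCThresholds | None = None,
    cfg: DetectorConfig | None = None,
    result: TFOResult | None = None,
) -> Path:
    """Write one diagnostic plot of the matrix to ``out``.

    ``kind`` is one of ``line_log`` (log-scaled trace per stimulating
    row), ``heatmap`` (dim×dim image, stimulating electrode on the rows),
    or ``delta_z`` (PC1 vs PC2 polyline; requires a QC-runnable matrix
    with at least five surviving contacts — pass a ``TFOResult`` to
    highlight the flagged bend).
    """
    if kind not in PLOT_KINDS:
        raise ValueError(f"unknown plot kind {kind!r}; choose from {PLOT_KINDS}")
    out = Path(out)
    with plt.style.context(_STYLE):
        fig, ax = plt.subplots()
        try:
            if kind == "line_log":
                _plot_line_log(m, ax)
            elif kind == "heatmap":
                _plot_heatmap(m, ax)
            else:
                _plot_delta_z(m, ax, qc_t, cfg, result)
            fig.tight_layout()
            fig.savefig(out)
        finally:
            plt.close(fig)
    return out
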