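"""Quality-control reporting for raw AFM-IR datasets.

A measurement is trustworthy when the trace and retrace passes of the
same raster line agree; the QC report quantifies this as the per-channel
RMS trace-retrace difference, together with the mean absolute deflection
error (relative to the setpoint, nominally 0 V) and the mean absolute IR
phase.  The rendered panel shows every channel map with row profiles
overlaying the trace and retrace passes.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .data_model import AFMIRDataset, CHANNELS

logger = logging.getLogger("ibspec.qc")

__all__ = ["qc_report"]

#: Channels acquired in both scan directions.
BIDIRECTIONAL = ("IRAmplitude", "IRPhase", "PLLFrequency")


def qc_report(
    dataset: AFMIRDataset,
    profile_rows: Sequence[int] | None = None,
    deflection_setpoint_v: float = 0.0,
    figure_path=None,
) -> dict:
    """Machine-readable QC metrics, optionally with a rendered panel.

    Returns a dict with per-channel trace/retrace RMS differences (None
    when the retrace is missing — the report is still produced), the mean
    absolute deflection error and mean absolute IR phase.  When
    ``figure_path`` is given, a panel of all channel maps with trace (blue)
    and retrace (orange) row profiles is written there.
    """
    h, w = dataset.shape
    if profile_rows is None:
        profile_rows = [h // 4, 3 * h // 4]
    metrics: dict = {
        "wavenumber": dataset.wavenumber,
        "sample_id": dataset.sample_id,
        "session_id": dataset.session_id,
        "profile_rows": list(map(int, profile_rows)),
        "trace_retrace_rms": {},
    }
    for ch in BIDIRECTIONAL:
        if dataset.has(ch, "trace") and dataset.has(ch, "retrace"):
            d = dataset.get(ch, "trace").data - dataset.get(ch, "retrace").data
            metrics["trace_retrace_rms"][ch] = float(np.sqrt(np.mean(d**2)))
        else:
            logger.info("qc_report: %s retrace missing; RMS unavailable", ch)
            metrics["trace_retrace_rms"][ch] = None
    if dataset.has("Deflection", "trace"):
        defl = dataset.get("Deflection", "trace").data
        metrics["mean_abs_deflection_v"] = float(
            np.mean(np.abs(defl - deflection_setpoint_v))
        )
    else:
        metrics["mean_abs_deflection_v"] = None
    if dataset.has("IRPhase", "trace"):
        metrics["mean_abs_ir_phase_deg"] = float(
            np.mean(np.abs(dataset.get("IRPhase", "trace").data))
        )
    else:
        metrics["mean_abs_ir_phase_deg"] = None

    if figure_path is not None:
        _render_panel(dataset, profile_rows, figure_path)
        metrics["figure"] = str(figure_path)
    return metrics


def _render_panel(dataset: AFMIRDataset, profile_rows, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    present = [ch for ch in CHANNELS if dataset.has(ch, "trace")]
    n = len(present)
    fig, axes = plt.subplots(2, n, figsize=(3.2 * n, 6.0), squeeze=False)
    extent = (0, dataset.field_of_view_um[0], dataset.field_of_view_um[1], 0)
    for k, ch in enumerate(present):
        cm = dataset.get(ch, "trace")
        ax = axes[0][k]
        im = ax.imshow(cm.data, cmap="viridis", extent=extent)
        for r in profile_rows:
            y = r * dataset.field_of_view_um[1] / dataset.shape[0]
            ax.axhline(y, color="w", lw=0.6, ls="--")
        ax.set_title(f"{ch} ({cm.units})", fontsize=9)
        ax.set_xlabel("x (um)")
        fig.colorbar(im, ax=ax, shrink=0.75)
        axp = axes[1][k]
        for r in profile_rows:
            axp.plot(cm.data[r], color="tab:blue", lw=0.8,
                     label="trace" if r == profile_rows[0] else None)
            if dataset.has(ch, "retrace"):
                axp.plot(dataset.get(ch, "retrace").data[r], color="tab:orange",
                         lw=0.8, label="retrace" if r == profile_rows[0] else None)
        axp.set_xlabel("column (px)")
        axp.legend(fontsize=7)
    fig.suptitle(
        f"QC: {dataset.sample_id} / {dataset.session_id} @ {dataset.wavenumber:g} cm$^{{-1}}$"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
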