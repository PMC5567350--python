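"""Diagnostic plots: trace snippets with called breaths and events.

These are run-inspection figures, not publication graphics.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .trace_io import Trace

__all__ = ["plot_trace_snippet"]


def plot_trace_snippet(
    trace: Trace,
    breaths: pd.DataFrame | None = None,
    events: dict[str, np.ndarray] | None = None,
    start: float | None = None,
    duration: float = 20.0,
    path=None,
):
    """Plot a pressure snippet with breath onsets/peaks and event markers.

    ``events`` maps a label (e.g. ``"apnea"``, ``"sigh"``) to event times.
    Returns the matplotlib figure; saves to ``path`` if given.
    """
    t0 = trace.start_time if start is None else start
    sub = trace.slice(t0, min(t0 + duration, trace.start_time + trace.duration))
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(sub.time, sub.channels["pressure"], lw=0.6, color="k")
    if breaths is not None and not breaths.empty:
        vis = breaths[(breaths["onset"] >= sub.start_time) & (breaths["onset"] < sub.time[-1])]
        ax.plot(vis["onset"], np.interp(vis["onset"], sub.time, sub.channels["pressure"]),
                "b|", ms=12, label="onset")
        ax.plot(vis["peak_time"], np.interp(vis["peak_time"], sub.time, sub.channels["pressure"]),
                "r.", ms=5, label="peak")
    for label, times in (events or {}).items():
        times = np.asarray(times)
        vis_t = times[(times >= sub.start_time) & (times < sub.time[-1])]
        for i, t in enumerate(vis_t):
            ax.axvline(t, color="orange", alpha=0.6, lw=1.5,
                       label=label if i == 0 else None)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pressure (signal units)")
    if breaths is not None or events:
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
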