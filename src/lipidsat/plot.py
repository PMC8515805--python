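"""Basic saturation-curve plotting (optional output of the CLI pipeline)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from lipidsat.saturation import FitResult, SaturationPoint


def plot_saturation(
    points: Sequence[SaturationPoint],
    fit: FitResult | None,
    path: str | Path,
    title: str = "",
) -> None:
    """Scatter the saturation points with the fitted isotherm overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(x, y, "o", ms=4, alpha=0.7, label="observations")
    if fit is not None and fit.converged:
        grid = np.linspace(0, max(x.max(), fit.kd_app * 3), 200)
        ax.plot(grid, fit.predict(grid), "-", label=f"Kd = {fit.kd_app:.2f}%")
    ax.set_xlabel("free cholesterol (%)")
    ax.set_ylabel("site occupancy (%)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
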