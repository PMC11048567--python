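"""Minimal figure helper for the threshold analysis."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .threshold import RunningAverageCurve, ThresholdEstimate


def plot_threshold(
    curve: RunningAverageCurve,
    estimate: ThresholdEstimate,
    path: str | Path,
    standard: float | None = 10.0,
) -> None:
    """Scatter of the running-average richness curve with the fitted
    polynomial trend, the detected threshold, and (optionally) the
    performance-standard line."""
    from numpy.polynomial import Polynomial

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(curve.x, curve.y, s=12, color="0.4", label="running average")
    poly = Polynomial(estimate.coefficients)
    if estimate.axis == "sequence":
        s = np.linspace(0, len(curve.points) - 1, 200)
        xs = np.interp(s, np.arange(len(curve.points)), curve.x[::-1])
        ax.plot(xs, poly(s), color="tab:green",
                label=f"degree-{estimate.fit_degree} trend")
    else:
        xs = np.linspace(curve.x.min(), curve.x.max(), 200)
        ax.plot(xs, poly(xs), color="tab:green",
                label=f"degree-{estimate.fit_degree} trend")
    ax.axvline(estimate.threshold, color="tab:red", ls="--",
               label=f"threshold {estimate.threshold:.1f}%")
    if standard is not None:
        ax.axvline(standard, color="tab:blue", ls=":", label=f"{standard:g}% standard")
    ax.set_xlabel("Invader relative abundance (%)")
    ax.set_ylabel("Native species richness (species/plot)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
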