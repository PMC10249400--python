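"""Optional plot export: empirical PDF points with the fitted SSD curve."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .ssd import PDFPoints, SSDFit, evaluate_ssd


def plot_ssd(points: PDFPoints, fit: SSDFit, path: Path | str) -> None:
    """Write a per-region SSD plot (points + fitted logistic) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(points.concentration, points.pdf, "o", ms=4, color="#1f77b4",
            label="observed")
    if fit.status == "fitted":
        lo = min(points.concentration.min(), fit.a - 4 * fit.b)
        hi = max(points.concentration.max(), fit.a + 4 * fit.b)
        c = np.linspace(max(lo, 0.0), hi, 300)
        ax.plot(c, evaluate_ssd(fit.a, fit.b, c), "-", color="#d62728",
                label=f"logistic fit (a={fit.a:.2f}, b={fit.b:.2f})")
    ax.set_xlabel("total N concentration (mg/L)")
    ax.set_ylabel("potentially disappeared fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"{fit.level} {fit.region_id}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
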