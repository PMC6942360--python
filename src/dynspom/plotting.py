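"""Occupancy-vs-dynamism figures, one panel per species.

Each panel plots mean equilibrium occupancy (with 95% CI ribbons) against
landscape dynamism, one series per habitat-cover level. Every figure is
written together with a sidecar CSV holding exactly the plotted values, so
downstream checks read data, never pixels.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_results"]

log = logging.getLogger(__name__)

_COVER_COLORS = {0.05: "tab:blue", 0.10: "tab:red", 0.20: "tab:green"}


def _cover_color(cover: float):
    for key, col in _COVER_COLORS.items():
        if abs(cover - key) < 1e-9:
            return col
    return None


def plot_results(results: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write one occupancy-vs-dynamism figure (plus sidecar CSV) per species.

    Returns the list of files written. A NaN confidence bound (single
    iteration) drops the ribbon for that series with a logged warning.
    """
    if results.empty:
        raise ValueError("results table is empty — nothing to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sid, sub in results.groupby("species_id"):
        sub = sub.sort_values(["cover", "dynamism"])
        pref = sub["preference"].iloc[0]
        fig, ax = plt.subplots(figsize=(5, 4))
        for cover, series in sub.groupby("cover"):
            color = _cover_color(float(cover))
            label = f"{cover:.0%} cover"
            ax.plot(series["dynamism"], series["mean_occupancy"],
                    marker="o", color=color, label=label)
            if series[["ci_low", "ci_high"]].isna().any().any():
                log.warning(
                    "species %s cover %s: CI undefined, ribbon omitted", sid, cover
                )
            else:
                ax.fill_between(series["dynamism"], series["ci_low"],
                                series["ci_high"], alpha=0.2, color=color)
        ax.set_xlabel("landscape dynamism (patch turnover per step)")
        ax.set_ylabel("equilibrium occupancy")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(f"species {sid} ({pref}-successional)")
        ax.legend(frameon=False)
        fig.tight_layout()
        png = out_dir / f"occupancy_species_{sid:02d}.png"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fig.savefig(png, dpi=150)
        plt.close(fig)
        sidecar = png.with_suffix(".csv")
        sub.to_csv(sidecar, index=False)
        written.extend([png, sidecar])
    return written
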