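"""Renogram and Patlak-Rutland plot artifacts (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .fur import PatlakSeries
from .tac import Renogram

__all__ = ["plot_renograms", "plot_patlak"]


def plot_renograms(renograms: dict[str, Renogram], path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, reno in renograms.items():
        ax.plot(reno.times_min, reno.pct_ia, label=name)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("% injected activity")
    ax.set_title(title or "Renograms")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_patlak(series: dict[str, PatlakSeries], path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, s in series.items():
        ax.plot(s.x_min, s.y, ".", ms=3, label=name)
        if s.slope_per_min is not None and s.segment_min is not None:
            lo, hi = s.segment_min
            sel = (s.times_min >= lo) & (s.times_min <= hi)
            ax.plot(
                s.x_min[sel],
                s.slope_per_min * s.x_min[sel] + (s.intercept or 0.0),
                "-",
                lw=1.5,
                label=f"{name} LU fit (k={s.slope_per_min:.3f}/min)",
            )
    ax.set_xlabel("∫P dτ / P(t)  (min)")
    ax.set_ylabel("R(t) / P(t)")
    ax.set_title(title or "Patlak-Rutland plot")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
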