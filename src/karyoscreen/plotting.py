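"""Minimal Kaplan-Meier plotting for screen hits."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from lifelines import KaplanMeierFitter


def plot_km_pair(
    loss: tuple[Sequence[float], Sequence[int]],
    other: tuple[Sequence[float], Sequence[int]],
    title: str,
    path: str | Path,
    t_max: float = 60.0,
) -> None:
    """Two KM curves (Loss vs Other) with Greenwood 95% CI bands.

    The timeline is truncated at ``t_max`` months for display only;
    testing elsewhere uses the full follow-up.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    for (times, events), label, color in [
        (loss, "Loss", "#c0392b"),
        (other, "Other", "#2c3e50"),
    ]:
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=events, label=label)
        kmf.plot_survival_function(ax=ax, ci_show=True, color=color)
    ax.set_xlim(0, t_max)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("Months")
    ax.set_ylabel("Survival probability")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
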