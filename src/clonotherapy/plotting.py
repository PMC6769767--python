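"""Static plotting conveniences: Kaplan–Meier curves and a clone-prevalence
stream (fishplot-style) view with covered clones highlighted.

These are thin matplotlib wrappers for reports and figures; all numbers are
computed by the analysis modules, never here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clonal_model import ClonalArchitecture
from .survival import KaplanMeier

__all__ = ["plot_km", "plot_clone_stream"]


def plot_km(curves: Mapping[str, KaplanMeier], path: str | Path,
            title: str = "Overall survival") -> Path:
    """Plot one Kaplan–Meier step curve per stratum and save to ``path``."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, km in sorted(curves.items()):
        if km.event_times.size:
            t = np.concatenate(([0.0], np.repeat(km.event_times, 2)))
            s = np.concatenate(([1.0, 1.0], np.repeat(km.survival, 2)[:-1]))
        else:
            t, s = np.array([0.0, 1.0]), np.array([1.0, 1.0])
        ax.plot(t, s, drawstyle="default", label=f"{name} (n at risk {int(km.at_risk[0]) if km.at_risk.size else 0})")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_clone_stream(arch: ClonalArchitecture, path: str | Path,
                      sample_order: Sequence[str] | None = None,
                      covered: set | None = None) -> Path:
    """Stacked clone-prevalence areas across samples (regions/timepoints).

    Clones in ``covered`` are drawn solid, uncovered ones hatched, giving a
    quick view of how much clonal mass a regimen addresses per sample.
    """
    samples = list(sample_order) if sample_order else arch.sample_ids
    clones = arch.clone_ids
    x = np.arange(len(samples))
    prev = np.array([
        [arch.samples[s].prevalence.get(c, 0.0) for s in samples] for c in clones
    ])
    fig, ax = plt.subplots(figsize=(6, 4))
    cmap = plt.get_cmap("tab10")
    bottom = np.zeros(len(samples))
    for i, c in enumerate(clones):
        hatch = None if (covered is None or c in covered) else "//"
        ax.fill_between(x, bottom, bottom + prev[i], label=c,
                        color=cmap(i % 10), alpha=0.8, hatch=hatch)
        bottom += prev[i]
    ax.set_xticks(x, samples)
    ax.set_ylabel("clone prevalence")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
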