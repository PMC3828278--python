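"""Figure generation (headless-safe; data outputs never depend on it).

Histogram figures follow the conventions of published sensitivity
distributions: the local (reference) coefficient as a dashed blue line,
zero as a dashed purple line, and optimisation bounds as dashed green
lines superimposed on the unit-area sampling histogram.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .robustness import RobustnessProfile
from .sampling import SensitivityDistribution
from .swarm import SensitivityBounds


def plot_distribution(
    dist: SensitivityDistribution,
    path: str,
    bounds: SensitivityBounds | None = None,
    title: str | None = None,
) -> None:
    """Unit-area histogram of one sensitivity distribution with overlays."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    if dist.status == "ok" and not dist.degenerate:
        centres = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        ax.bar(
            centres,
            dist.densities,
            width=np.diff(dist.bin_edges),
            color="0.6",
            edgecolor="none",
        )
    elif dist.status == "ok":
        ax.axvline(dist.peak_location, color="0.4", lw=3)
    ax.axvline(0.0, color="purple", ls="--", lw=1, label="zero")
    if dist.local_value is not None:
        ax.axvline(dist.local_value, color="tab:blue", ls="--", lw=1.2, label="local value")
    if bounds is not None and bounds.ok:
        ax.axvline(bounds.lower, color="tab:green", ls="--", lw=1.2, label="bounds")
        ax.axvline(bounds.upper, color="tab:green", ls="--", lw=1.2)
    ax.set_xlabel("scaled sensitivity coefficient")
    ax.set_ylabel("density")
    band = f" (band ±{dist.band:g})" if dist.band is not None else ""
    ax.set_title(title or f"{dist.parameter}{band}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_robustness(profile: RobustnessProfile, path: str, title: str | None = None) -> None:
    """Grouped bar chart: per band, the fraction of parameters able to
    exceed the magnitude threshold, per evidence source."""
    bands = [b for b in profile.bands if b in profile.exceedance_sampling]
    x = np.arange(len(bands))
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    width = 0.35 if profile.exceedance_bounds else 0.6
    ax.bar(
        x - (width / 2 if profile.exceedance_bounds else 0),
        [profile.exceedance_sampling[b] for b in bands],
        width,
        label="sampling",
        color="tab:blue",
    )
    if profile.exceedance_bounds:
        ax.bar(
            x + width / 2,
            [profile.exceedance_bounds.get(b, 0.0) for b in bands],
            width,
            label="optimisation",
            color="tab:green",
        )
    ax.set_xticks(x, [f"±{b:g}" for b in bands])
    ax.set_xlabel("parameter variation band")
    ax.set_ylabel(f"fraction of parameters with |C| ≥ {profile.threshold:g}")
    ax.set_ylim(0, 1.05)
    ax.set_title(title or "model robustness summary")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
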