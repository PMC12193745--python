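"""Optional bar-chart summaries of comparison means and genus profiles."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sisters import SisterComparison
from .twosigma import GenusProfile, SigmaDistribution


def plot_comparison_bars(
    cmps: Sequence[SisterComparison],
    dist: SigmaDistribution,
    path,
    title: str = "Sister-clade K2P divergence",
) -> None:
    """Bars of comparison means (descending) with mean and sigma guide
    lines; error bars show per-comparison SD where defined."""
    cmps = sorted((c for c in cmps if c.mean is not None), key=lambda c: -c.mean)
    labels = [c.label for c in cmps]
    means = [c.mean for c in cmps]
    errs = [c.sd if c.sd is not None else 0.0 for c in cmps]
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(cmps)), 5))
    ax.bar(range(len(cmps)), means, yerr=errs, capsize=2, color="0.35")
    ax.axhline(dist.mu, color="k", ls=":", lw=1.2, label="mean")
    for k, ls in ((1, "--"), (2, "-.")):
        for sign in (-1, 1):
            ax.axhline(dist.mu + sign * k * dist.sigma, color="0.5", ls=ls, lw=0.9)
    ax.set_xticks(range(len(cmps)))
    ax.set_xticklabels(labels, rotation=75, ha="right", fontsize=7)
    ax.set_ylabel("K2P distance (%)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_within_genus_bars(
    profiles: Sequence[GenusProfile], path, title: str = "Within-genus K2P divergence"
) -> None:
    """Bars of within-genus mean divergences with their SDs."""
    profiles = sorted(profiles, key=lambda p: -p.mean_within)
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(profiles)), 5))
    ax.bar(
        range(len(profiles)),
        [p.mean_within for p in profiles],
        yerr=[p.sd_within if p.sd_within is not None else 0.0 for p in profiles],
        capsize=2,
        color="0.35",
    )
    ax.set_xticks(range(len(profiles)))
    ax.set_xticklabels([p.genus for p in profiles], rotation=75, ha="right", fontsize=7)
    ax.set_ylabel("K2P distance (%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
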