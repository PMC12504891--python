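"""Basic plotting utilities: radar (polar) profiles and reliability heatmaps."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .classify import RadarProfile

__all__ = ["plot_radar", "plot_reliability_heatmap"]


def _angles(k: int) -> np.ndarray:
    # most relevant indicator at the top, then counterclockwise
    return (np.pi / 2 + 2 * np.pi * np.arange(k) / k) % (2 * np.pi)


def plot_radar(profile: RadarProfile, path: str) -> str:
    """Render one misclassified-sample radar profile to an image file."""
    k = len(profile.indicators)
    ang = _angles(k)
    ang_closed = np.r_[ang, ang[:1]]

    def close(vals):
        return np.r_[vals, vals[:1]]

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.fill_between(ang_closed, close(profile.hc_q25), close(profile.hc_q75),
                    color="green", alpha=0.15, label="HC IQR")
    ax.plot(ang_closed, close(profile.hc_median), "g--", label="HC median")
    ax.fill_between(ang_closed, close(profile.mci_q25), close(profile.mci_q75),
                    color="red", alpha=0.15, label="MCI IQR")
    ax.plot(ang_closed, close(profile.mci_median), "r--", label="MCI median")
    ax.plot(ang_closed, close(profile.values), "-", color="tab:blue", lw=2,
            label=profile.sample_id)
    ax.set_xticks(ang)
    ax.set_xticklabels(profile.indicators, fontsize=8)
    ax.set_ylim(0, 1)
    ax.set_title(
        f"{profile.sample_id} (true={'MCI' if profile.true_label else 'HC'}, "
        f"pred={'MCI' if profile.pred_label else 'HC'})", fontsize=10,
    )
    ax.legend(loc="lower right", bbox_to_anchor=(1.2, -0.1), fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_reliability_heatmap(tables: dict[str, list], path: str) -> str:
    """Heatmap of reliability coefficients: rows = indicators, cols = strata.

    ``tables`` maps a stratum label (e.g. "list/cursive") to a list of
    ReliabilityResult objects.
    """
    cols = list(tables)
    rows = sorted({r.indicator for results in tables.values() for r in results})
    m = np.full((len(rows), len(cols)), np.nan)
    for j, c in enumerate(cols):
        for r in tables[c]:
            m[rows.index(r.indicator), j] = max(0.0, r.coef_value)
    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * len(cols), 0.8 + 0.3 * len(rows)))
    im = ax.imshow(m, vmin=0, vmax=1, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(len(rows)), rows, fontsize=8)
    fig.colorbar(im, ax=ax, label="reliability coefficient")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
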