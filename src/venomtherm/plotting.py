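"""Basic figures: discriminant score plot and correlation circle."""

from __future__ import annotations

import numpy as np

from .multivariate import LDAResult, TrendArrow

__all__ = ["plot_trend", "plot_correlation_circle"]


def plot_trend(lda: LDAResult, arrow: TrendArrow, groups=None, ax=None):
    """Scatter of individuals in the discriminant plane with the trend arrow.

    ``groups`` (optional) is a per-individual label series used to color
    the points, typically the rearing temperature.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scores = lda.scores.iloc[:, :2].to_numpy()
    if groups is not None:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            mask = groups == g
            ax.scatter(scores[mask, 0], scores[mask, 1], s=12, alpha=0.6,
                       label=str(g))
        ax.legend(title="temperature", fontsize=8)
    else:
        ax.scatter(scores[:, 0], scores[:, 1], s=12, alpha=0.6)
    cent = lda.centroids.iloc[:, :2]
    ax.scatter(cent.iloc[:, 0], cent.iloc[:, 1], marker="x", s=80, c="k")
    for name, row in cent.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]))
    span = float(np.ptp(scores[:, 0]) + np.ptp(scores[:, 1])) / 4 or 1.0
    mid = cent.to_numpy().mean(axis=0)
    ax.annotate(
        "", xy=mid + span * arrow.direction, xytext=mid - span * arrow.direction,
        arrowprops=dict(arrowstyle="->", color="green", lw=2),
    )
    ax.set_xlabel(lda.scores.columns[0])
    ax.set_ylabel(lda.scores.columns[1] if lda.scores.shape[1] > 1 else "")
    return ax


def plot_correlation_circle(correlations, arrow: TrendArrow, ax=None):
    """Band correlations with the two discriminant axes, candidates in red."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="0.8", lw=1)
    for band, row in correlations.iterrows():
        if not row["defined"]:
            continue
        color = "red" if row["candidate"] else "0.4"
        ax.annotate(band, (row["axis1_corr"], row["axis2_corr"]),
                    color=color, fontsize=7, ha="center")
    ax.annotate("", xy=arrow.direction, xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="green", lw=2))
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.set_xlabel("correlation with LD1")
    ax.set_ylabel("correlation with LD2")
    return ax
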