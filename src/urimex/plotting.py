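"""Optional matplotlib views: PCA scores plot with 95% confidence ellipses."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .repeatability import PCAResult


def plot_pca_scores(result: PCAResult, path: str | Path,
                    groups: dict[str, list[str]] | None = None) -> Path:
    """Save a PC1/PC2 scores plot; one colour and 95% ellipse per group.

    ``groups`` maps a label to its sample ids; defaults to the groups that
    already have ellipses in ``result``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    scores = result.scores
    if groups is None:
        groups = {
            label: list(scores.index) for label in result.group_ellipses
        }
    cmap = plt.get_cmap("tab10")
    for k, (label, sids) in enumerate(groups.items()):
        pts = scores.loc[[s for s in sids if s in scores.index]]
        color = cmap(k % 10)
        ax.scatter(pts["PC1"], pts["PC2"], s=30, color=color, label=label)
        ellipse = result.group_ellipses.get(label)
        if ellipse is not None:
            theta = np.linspace(0, 2 * np.pi, 200)
            circle = np.column_stack([np.cos(theta), np.sin(theta)])
            chol = np.linalg.cholesky(ellipse.covariance)
            boundary = ellipse.center + np.sqrt(ellipse.scale) * circle @ chol.T
            ax.plot(boundary[:, 0], boundary[:, 1], color=color, lw=1)
    evf = result.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({100 * evf[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evf[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
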