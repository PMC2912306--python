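"""SVG figure export: correlation clustergram heatmap and 2-D PCA scores.

Vector output only, for publication-quality figures.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .stats import ClusterResult, PcaResult  # noqa: E402


def save_correlation_heatmap(result: ClusterResult, path,
                             cmap: str = "RdBu_r") -> None:
    """Reordered analyte-analyte correlation matrix as an SVG heatmap."""
    n = len(result.leaves)
    fig, ax = plt.subplots(figsize=(max(4, n * 0.12), max(4, n * 0.12)))
    im = ax.imshow(result.correlation.to_numpy(), vmin=-1, vmax=1, cmap=cmap)
    ax.set_xticks(range(n), result.leaves, rotation=90, fontsize=4)
    ax.set_yticks(range(n), result.leaves, fontsize=4)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def save_pca_scores(result: PcaResult, path,
                    labels: dict[str, str] | None = None) -> None:
    """PC1 vs PC2 scores scatter as SVG, optionally coloured by group label."""
    fig, ax = plt.subplots(figsize=(5, 5))
    scores = result.scores
    if labels:
        groups = sorted(set(labels.values()))
        for g in groups:
            idx = [s for s in scores.index if labels.get(s) == g]
            ax.scatter(scores.loc[idx, "PC1"], scores.loc[idx, "PC2"],
                       label=g, s=18)
        ax.legend(fontsize=7)
    else:
        ax.scatter(scores["PC1"], scores["PC2"], s=18)
    ax.set_xlabel(f"PC1 ({result.explained[0]:.1%})")
    ax.set_ylabel(f"PC2 ({result.explained[1]:.1%})")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
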