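"""Phenotype discovery: hierarchical clustering, PLS-DA variable importance,
and the clustered heatmap artifact.

Phenotype letters follow the biology, not cluster size: the cluster with the
highest mean of the designated marker metabolite (succinate by default) is
labelled D; the remaining clusters receive A, B, C in dendrogram leaf order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, leaves_list, linkage


@dataclass
class PhenotypeAssignment:
    labels: pd.Series          # sample id -> integer cluster label (1..k)
    linkage_matrix: np.ndarray
    k: int

    def cluster_members(self) -> dict[int, list[str]]:
        return {int(c): self.labels[self.labels == c].index.tolist()
                for c in sorted(self.labels.unique())}


@dataclass
class VipTable:
    scores: pd.Series          # metabolite -> VIP, sorted descending
    n_components: int

    def top(self, n: int = 10) -> pd.Series:
        return self.scores.head(n)


def hier_cluster(matrix: pd.DataFrame, k: int = 4) -> PhenotypeAssignment:
    """Agglomerative clustering, Euclidean distance, complete linkage.

    Deterministic given input order (SciPy merges the lowest-index pair on
    equal heights); the tree is cut to exactly ``k`` clusters.
    """
    n = len(matrix)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} samples")
    Z = linkage(matrix.to_numpy(dtype=float), method="complete",
                metric="euclidean")
    flat = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=matrix.index, name="cluster")
    if labels.nunique() != k:
        raise RuntimeError(f"cut produced {labels.nunique()} clusters, wanted {k}")
    return PhenotypeAssignment(labels, Z, k)


def assign_phenotype_letters(assignment: PhenotypeAssignment,
                             matrix: pd.DataFrame,
                             marker: str = "succinate") -> pd.Series:
    """Map integer clusters to letters by ascending marker-metabolite mean.

    The cluster with the highest mean of the marker (succinate by default)
    becomes the last letter (D at k = 4), the lowest becomes A — the letters
    encode the marker gradient, not cluster size or dendrogram position.
    """
    if marker not in matrix.columns:
        raise KeyError(f"marker metabolite {marker!r} not in matrix")
    means = matrix[marker].groupby(assignment.labels).mean()
    ranked = means.sort_values().index  # ascending marker mean
    letters = [chr(ord("A") + i) for i in range(assignment.k)]
    mapping = {int(c): letters[i] for i, c in enumerate(ranked)}
    return assignment.labels.map(mapping).rename("phenotype")


def plsda_vip(matrix: pd.DataFrame, labels: pd.Series,
              n_components: int = 2) -> VipTable:
    """PLS-DA on one-hot class labels; standard VIP scores, sorted descending.

    VIP_j = √( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ), where SSY_a is the
    Y-variance explained by component a. Mean squared VIP equals 1.
    """
    from sklearn.cross_decomposition import PLSRegression

    labels = labels.loc[matrix.index]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = labels.value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        raise ValueError(f"classes with a single sample: {singletons}")
    Y = pd.get_dummies(labels).loc[:, classes].to_numpy(dtype=float)
    X = matrix.to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)
    W = pls.x_weights_                     # p × A
    T = pls.x_scores_                      # n × A
    Q = pls.y_loadings_                    # m × A
    p = X.shape[1]
    ssy = np.sum(T ** 2, axis=0) * np.sum(Q ** 2, axis=0)  # per component
    wnorm2 = np.sum(W ** 2, axis=0)
    vip = np.sqrt(p * ((W ** 2 / wnorm2) @ ssy) / ssy.sum())
    scores = pd.Series(vip, index=matrix.columns, name="vip")
    scores = scores.sort_values(ascending=False)
    return VipTable(scores, n_components)


def render_phenotype_heatmap(matrix: pd.DataFrame,
                             assignment: PhenotypeAssignment,
                             path: str | Path) -> dict[str, str]:
    """Write the dendrogram-ordered matrix (CSV) and a heatmap image.

    The CSV is the testable artifact; the image is a convenience rendering.
    Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    order = leaves_list(assignment.linkage_matrix)
    ordered = matrix.iloc[order]
    csv_path = path.with_suffix(".csv")
    ordered.to_csv(csv_path, index_label="sample_id")

    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(10, 8), height_ratios=[1, 4], constrained_layout=True)
    dendrogram(assignment.linkage_matrix, ax=ax_d, no_labels=True,
               color_threshold=0)
    ax_d.set_ylabel("height")
    im = ax_h.imshow(ordered.to_numpy(dtype=float).T, aspect="auto",
                     cmap="RdBu_r", interpolation="nearest")
    ax_h.set_xlabel("samples (dendrogram order)")
    ax_h.set_ylabel("metabolites")
    fig.colorbar(im, ax=ax_h, shrink=0.6)
    img_path = path.with_suffix(".png")
    fig.savefig(img_path, dpi=120)
    plt.close(fig)
    return {"csv": str(csv_path), "image": str(img_path)}
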