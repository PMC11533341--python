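"""Figure-type exports: PCA coordinates, hierarchical tree in Newick,
heatmap matrix, chromosome distribution and paired-sample similarity.

Everything here emits data (TSV / JSON / Newick / BED6), never rendered
images — downstream ideogram/heatmap tools consume these files directly.
Presence/absence (positive = 1) is the default feature encoding for the
embedding and the tree; per-locus depths are available via
``values="depth"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from skbio.tree import TreeNode

from .catalog import HervCatalog, catalog_to_bed
from .cohort import PresenceMatrix
from .scoring import SampleCalls

__all__ = [
    "EmbeddingResult",
    "TreeResult",
    "pca_embedding",
    "cluster_tree",
    "heatmap_matrix",
    "chromosome_distribution",
    "call_similarity",
]


def _feature_matrix(
    matrix: PresenceMatrix, values: Literal["calls", "depth"]
) -> pd.DataFrame:
    """Samples × loci feature table: 0/1 presence or depth values."""
    if values == "calls":
        feats = (matrix.calls == "positive").astype(float)
    else:
        feats = matrix.depths.astype(float)
    return feats.T  # samples as rows


@dataclass
class EmbeddingResult:
    """Sample coordinates on principal components plus explained variance."""

    coordinates: pd.DataFrame  # samples × components, columns PC1..PCk
    explained_variance_ratio: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        out = self.coordinates.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.8g")


def pca_embedding(
    matrix: PresenceMatrix,
    scale: bool = False,
    values: Literal["calls", "depth"] = "calls",
) -> EmbeddingResult:
    """PCA of the column-centered samples × loci matrix.

    Constant loci are dropped before (optional) unit-variance scaling.  The
    full-rank embedding preserves pairwise Euclidean distances between
    samples, so the first components are the best planar view of the
    between-sample structure.
    """
    feats = _feature_matrix(matrix, values)
    if feats.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    variable = feats.loc[:, feats.std(axis=0, ddof=0) > 0]
    if variable.shape[1] == 0:
        # all-constant matrix: every sample sits at the origin
        n = feats.shape[0]
        coords = pd.DataFrame(np.zeros((n, 1)), index=feats.index, columns=["PC1"])
        return EmbeddingResult(coords, np.array([0.0]))
    X = variable.to_numpy()
    if scale:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    coords = pd.DataFrame(scores, index=feats.index, columns=cols)
    return EmbeddingResult(coords, pca.explained_variance_ratio_)


@dataclass
class TreeResult:
    """Hierarchical tree over samples with branch lengths; Newick serializable."""

    tree: TreeNode
    newick: str

    def leaf_names(self) -> set[str]:
        return {tip.name for tip in self.tree.tips()}


def cluster_tree(
    matrix: PresenceMatrix,
    normalize: bool = True,
    linkage: str = "average",
    values: Literal["calls", "depth"] = "calls",
) -> TreeResult:
    """Agglomerative tree on pairwise Euclidean distances between samples.

    ``normalize`` z-scores each locus across samples (zero-variance loci
    dropped) before computing distances.  An all-identical matrix yields a
    star-like tree with zero branch lengths, not an error.
    """
    feats = _feature_matrix(matrix, values)
    if feats.shape[0] < 2:
        raise ValueError("tree requires at least 2 samples")
    X = feats.to_numpy()
    if normalize:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep] if keep.any() else np.zeros(
            (X.shape[0], 1)
        )
    dist = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(dist, method=linkage)
    tree = TreeNode.from_linkage_matrix(Z, list(feats.index))
    newick = str(tree)
    return TreeResult(tree=tree, newick=newick)


def heatmap_matrix(matrix: PresenceMatrix, positive_only: bool = True) -> pd.DataFrame:
    """Depth matrix restricted to loci positive in ≥ 1 sample.

    Row (locus) and column (sample) order follow the presence matrix, so
    the export is stable and recorded by construction.
    """
    depths = matrix.depths.copy()
    if positive_only:
        keep = matrix.positive_mask().any(axis=1)
        depths = depths.loc[keep]
    depths.index.name = "locus_id"
    return depths


def chromosome_distribution(
    locus_set: set[str] | Sequence[str], catalog: HervCatalog
) -> tuple[pd.Series, list[str]]:
    """Per-chromosome locus counts (zero-count chromosomes included) + BED6.

    Chromosomes are taken from the whole catalog, so absent chromosomes
    report 0; counts sum to ``len(locus_set)``.
    """
    ids = set(locus_set)
    missing = ids - set(catalog.locus_ids)
    if missing:
        raise ValueError(f"loci absent from catalog: {sorted(missing)}")
    counts = pd.Series(0, index=pd.Index(catalog.chromosomes(), name="chrom"), dtype=int)
    selected = [locus for locus in catalog if locus.locus_id in ids]
    for locus in selected:
        counts[locus.chrom] += 1
    bed = catalog_to_bed(selected)
    return counts, bed


def call_similarity(sample_a: SampleCalls, sample_b: SampleCalls) -> float:
    """Percent agreement over the union of positive loci (Jaccard × 100).

    100% iff the positive sets are equal and non-empty; 0% when both
    samples have no positive locus (empty union).
    """
    if set(sample_a.scores) != set(sample_b.scores):
        raise ValueError("samples were scored against different catalogs")
    a, b = sample_a.positive_loci, sample_b.positive_loci
    union = a | b
    if not union:
        return 0.0
    return 100.0 * len(a & b) / len(union)
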