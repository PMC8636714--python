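"""Ordination and tree summaries of panel structure.

Principal components are computed on the mean-centered alt-allele dosage
matrix (0/1/2; missing calls imputed with the per-marker mean dosage, in
the PCA only — distances elsewhere use pairwise deletion). Component signs
are fixed by making each component's largest-magnitude marker loading
positive, so results are fully deterministic.

Neighbor joining builds the usual unrooted tree from any of the supported
genetic distance matrices; negative branch lengths are clamped to zero
with the adjustment recorded.

:func:`assign_groups` is a deliberately lightweight grouping heuristic —
k-means on the leading components. It yields hard cluster labels, not
admixture proportions, and is documented as such wherever it stands in
for Bayesian population-structure inference.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .genotypes import GenotypeMatrix, ValidationError

__all__ = ["PcaResult", "TreeResult", "pca", "nj_tree", "assign_groups"]


@dataclass
class PcaResult:
    ids: list[str]
    coordinates: np.ndarray  # (n, n_components)
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray  # (n_components, L)
    dosage_centering: np.ndarray  # per-marker mean dosages used

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def pca(m: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """Principal components of the centered dosage matrix."""
    if m.n_accessions < 2:
        raise ValidationError("need at least 2 accessions for PCA")
    if m.n_markers < 1:
        raise ValidationError("need at least 1 marker for PCA")
    d = m.dosage()
    means = np.nanmean(d, axis=0)
    if np.isnan(means).any():
        bad = [m.marker_ids[j] for j in np.flatnonzero(np.isnan(means))]
        raise ValidationError(f"all calls missing at markers: {bad}")
    filled = np.where(np.isnan(d), means, d)
    centered = filled - means
    max_rank = min(m.n_accessions - 1, m.n_markers)
    if n_components is None:
        n_components = max_rank
    n_components = min(n_components, max_rank)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = float((s**2).sum())
    explained = (
        s[:n_components] ** 2 / total_var
        if total_var > 0
        else np.zeros(n_components)
    )
    coords = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for c in range(n_components):
        lead = np.argmax(np.abs(loadings[c]))
        if loadings[c, lead] < 0:
            loadings[c] *= -1
            coords[:, c] *= -1
    return PcaResult(
        ids=list(m.accession_ids),
        coordinates=coords,
        explained_variance_fraction=explained,
        loadings=loadings,
        dosage_centering=means,
    )


@dataclass
class TreeResult:
    """An unrooted NJ tree with its newick serialization."""

    newick: str
    tree: object  # skbio.TreeNode
    #: (node name or None, original negative length) clamped to zero
    clamped_branches: list[tuple[str | None, float]] = field(
        default_factory=list
    )

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


def nj_tree(d: DistanceMatrix) -> TreeResult:
    """Neighbor-joining tree from a genetic distance matrix."""
    import skbio

    if len(d.ids) < 3:
        raise ValidationError("need at least 3 taxa for a tree")
    dm = skbio.DistanceMatrix(d.d, ids=d.ids)
    tree = skbio.tree.nj(dm)
    clamped = []
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            clamped.append((node.name, float(node.length)))
            node.length = 0.0
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return TreeResult(
        newick=buf.getvalue().strip(), tree=tree, clamped_branches=clamped
    )


def assign_groups(
    p: PcaResult, k: int, seed: int = 0, n_components: int = 10
) -> dict[str, int]:
    """Heuristic hard grouping: k-means on the leading components.

    A stand-in for model-based population-structure inference; labels are
    arbitrary cluster indices, not admixture proportions.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(p.ids):
        raise ValidationError(f"k={k} exceeds {len(p.ids)} accessions")
    X = p.coordinates[:, : min(n_components, p.coordinates.shape[1])]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return {acc: int(lab) for acc, lab in zip(p.ids, labels)}
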