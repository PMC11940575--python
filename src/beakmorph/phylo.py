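"""Phylogenetic signal in trait/latent tables: Blomberg's K, pPCA, PACA.

Under Brownian motion (BM) on a rooted tree, trait covariance among
species is proportional to the matrix C of shared root-to-ancestor branch
lengths.  Everything here is built on C:

* Blomberg's K — the ratio of observed to BM-expected concentration of
  variance among relatives; K ~ 1 under BM, < 1 when relatives resemble
  each other less than BM predicts.  The multivariate generalization
  replaces squared deviations with trace forms over the trait matrix and
  reduces exactly to K at p = 1.
* Phylogenetic PCA — eigenanalysis of the GLS-estimated evolutionary
  covariance, which redistributes (not removes) phylogenetic signal.
* PACA — phylogenetically *aligned* components: directions ordered by
  covariation with the phylogeny (eigenvectors of X_c' C X_c), so the
  first axis concentrates as much phylogenetic signal as a rotation can.

The per-axis K profile and the first-axis-removal classification
experiment probe how signal is distributed across a representation and
whether class prediction depends on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .core import InvalidParameterError
from .ecology import EvalReport, classification_experiment

#: zero-length terminal branches are bumped by this (C must be PD for GLS)
MIN_BRANCH = 1e-8


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, backed by dendropy."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        src = newick
        if "(" not in newick and ";" not in newick:
            src = open(newick).read()
        tree = dendropy.Tree.get(
            data=src, schema="newick", preserve_underscores=True
        )
        bumped = False
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None or edge.length <= 0:
                edge.length = MIN_BRANCH
                bumped = True
        if bumped:
            warnings.warn(
                f"non-positive branch lengths bumped to {MIN_BRANCH}"
            )
        return cls(tree=tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = np.array(list(self.depths().values()))
        return bool(d.max() - d.min() <= tol * max(d.max(), 1.0))

    def clades(self) -> list[list[str]]:
        """Tip-label sets of every internal node."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            out.append([l.taxon.label for l in node.leaf_iter()])
        return out


@dataclass
class PhyloCovariance:
    """BM covariance C (shared root-to-MRCA path lengths) with tip order."""

    C: np.ndarray
    tip_order: list[str]

    def __post_init__(self) -> None:
        C = self.C
        if not np.allclose(C, C.T, atol=1e-12 * max(1.0, np.abs(C).max())):
            raise InvalidParameterError("C must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-9:
            raise InvalidParameterError("C must be positive semi-definite")

    def reorder(self, tip_order: list[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(t) for t in tip_order]
        return PhyloCovariance(self.C[np.ix_(idx, idx)], list(tip_order))


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """C[i, j] = depth of the MRCA of tips i and j; diagonal = tip depths."""
    if tree.tree.seed_node is None:
        raise InvalidParameterError("tree must be rooted")
    tips = tree.tip_labels
    depths = tree.depths()
    d = np.array([depths[t] for t in tips])
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = d[i]
        for j in range(i + 1, n):
            patristic = pdm.patristic_distance(taxa[tips[i]], taxa[tips[j]])
            C[i, j] = C[j, i] = 0.5 * (d[i] + d[j] - patristic)
    return PhyloCovariance(C=C, tip_order=tips)


def _align(
    x: np.ndarray | pd.Series | pd.DataFrame, tree: Phylogeny
) -> tuple[np.ndarray, PhyloCovariance]:
    """Coerce traits to an array in tree tip order, with matching C."""
    cov = phylo_covariance(tree)
    if isinstance(x, (pd.Series, pd.DataFrame)):
        missing = set(cov.tip_order) - set(map(str, x.index))
        if missing:
            raise InvalidParameterError(f"traits missing for tips {sorted(missing)}")
        x = x.loc[cov.tip_order]
        arr = np.asarray(x, dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        if len(arr) != len(cov.tip_order):
            raise InvalidParameterError("trait rows must match tip count")
    return arr, cov


def _gls_mean(X: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    ones = np.ones(len(X))
    denom = ones @ Cinv @ ones
    return (ones @ Cinv @ np.atleast_2d(X.T).T) / denom


def blomberg_K(x, tree: Phylogeny) -> float:
    """Univariate Blomberg's K of one trait on a tree.

    K = [MSE0 / MSE] / E_BM[MSE0 / MSE], where MSE0 is the mean squared
    deviation from the phylogenetic (GLS) mean and MSE the C-weighted
    version; the BM expectation is (tr C - n / sum(C^-1)) / (n - 1).
    """
    arr, cov = _align(x, tree)
    if arr.ndim != 1:
        raise InvalidParameterError("blomberg_K takes a single trait")
    n = len(arr)
    if n < 4:
        raise InvalidParameterError("need at least 4 tips")
    if np.ptp(arr) == 0:
        raise InvalidParameterError("K undefined for a constant trait")
    C = cov.C
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = float((ones @ Cinv @ arr) / (ones @ Cinv @ ones))
    dev = arr - a
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ Cinv @ dev) / (n - 1)
    expected = (np.trace(C) - n / float(ones @ Cinv @ ones)) / (n - 1)
    return float((mse0 / mse) / expected)


def multivariate_K(X, tree: Phylogeny) -> float:
    """Distance-based multivariate K (trace generalization).

    Squared deviations from the (GLS) phylogenetic mean are summed over
    all trait dimensions in both the numerator and the C-weighted
    denominator; reduces to :func:`blomberg_K` at p = 1.
    """
    arr, cov = _align(X, tree)
    arr = np.atleast_2d(arr.T).T
    if arr.ndim == 1:
        arr = arr[:, None]
    n, p = arr.shape
    if n < 4:
        raise InvalidParameterError("need at least 4 tips")
    if np.allclose(arr, arr[0]):
        raise InvalidParameterError("K undefined for constant traits")
    C = cov.C
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Cinv @ arr) / float(ones @ Cinv @ ones)
    dev = arr - a
    num = float((dev * dev).sum())
    den = float(np.trace(dev.T @ Cinv @ dev))
    expected = (np.trace(C) - n / float(ones @ Cinv @ ones)) / (n - 1)
    return float((num / den) / expected)


def phylo_pca(X, tree: Phylogeny) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phylogenetic PCA: eigenanalysis of the GLS evolutionary covariance.

    Returns (scores, vectors, eigenvalues); scores are the GLS-centered
    data projected on the eigenvectors.  On a star tree (C proportional to
    the identity) this is ordinary PCA.
    """
    arr, cov = _align(X, tree)
    if arr.ndim != 2:
        raise InvalidParameterError("X must be 2-D (tips x traits)")
    n, p = arr.shape
    C = cov.C
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:
        raise InvalidParameterError(f"singular phylogenetic covariance: {e}")
    ones = np.ones(n)
    a = (ones @ Cinv @ arr) / float(ones @ Cinv @ ones)
    dev = arr - a
    R = dev.T @ Cinv @ dev / (n - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    scores = dev @ evecs
    return scores, evecs, evals


def paca(X, tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """Phylogenetically aligned components analysis.

    Orders orthonormal directions by covariation between the (GLS-centered)
    data and the phylogenetic structure implied by C: eigenvectors of
    ``dev' C dev``.  Axis 1 concentrates the most phylogenetically
    structured variation a rotation can.  Returns (components, scores).
    """
    arr, cov = _align(X, tree)
    if arr.ndim != 2:
        raise InvalidParameterError("X must be 2-D (tips x traits)")
    n, p = arr.shape
    C = cov.C
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:
        raise InvalidParameterError(f"singular phylogenetic covariance: {e}")
    ones = np.ones(n)
    a = (ones @ Cinv @ arr) / float(ones @ Cinv @ ones)
    dev = arr - a
    S = dev.T @ C @ dev
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    components = evecs[:, order]
    scores = dev @ components
    return components, scores


def signal_profile(X, tree: Phylogeny) -> np.ndarray:
    """Blomberg's K column by column (NaN for constant columns, warned)."""
    arr, _ = _align(X, tree)
    if arr.ndim != 2:
        raise InvalidParameterError("X must be 2-D (tips x traits)")
    out = np.full(arr.shape[1], np.nan)
    for j in range(arr.shape[1]):
        if np.ptp(arr[:, j]) == 0:
            warnings.warn(f"column {j} constant; K undefined")
            continue
        out[j] = blomberg_K(pd.Series(arr[:, j], index=tree.tip_labels), tree)
    return out


def axis_removal_experiment(
    X,
    tree: Phylogeny,
    labels,
    classifier_config: dict | None = None,
    n_drop: int = 1,
) -> EvalReport:
    """Niche classification on PACA scores with leading axes removed.

    Computes PACA scores, drops the first ``n_drop`` columns (the most
    phylogenetically aligned directions), and runs the standard
    classification protocol on the remainder.  ``n_drop = 0`` is the
    baseline.  ``labels`` must be indexable by tip label (Series) or
    already in tree tip order.
    """
    cfg = dict(classifier_config or {})
    _, scores = paca(X, tree)
    if n_drop < 0 or n_drop >= scores.shape[1]:
        raise InvalidParameterError("n_drop out of range")
    feats = scores[:, n_drop:]
    if isinstance(labels, pd.Series):
        labels = labels.loc[phylo_covariance(tree).tip_order]
    return classification_experiment(feats, np.asarray(labels, dtype=object), **cfg)
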