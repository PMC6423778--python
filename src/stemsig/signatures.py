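"""Aging/rejuvenation signature extraction and validation clustering.

A gene joins the *aging* signature when it is robustly detected in the
parental MSCs but absent from the reprogrammed cells, and the
*rejuvenation* signature under the mirror rule:

    aging:        p_MSC < 0.001  and  p_iMSC > 0.1  and  p_iPSC > 0.1
    rejuvenation: p_MSC > 0.1    and  p_iMSC < 0.001 and  p_iPSC < 0.001

with strict inequalities; a gene whose group p lands in the dead zone
[0.001, 0.1] for any group joins neither set, and the contradictory MSC
requirements make the two sets disjoint by construction.

The module also houses the validation machinery: Pearson-correlation
distances, average-linkage hierarchical clustering with deterministic
leaf ordering, GO-subset heatmap matrices and generic hypergeometric
enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from stemsig.microarray import DetectionResult, group_detection


@dataclass
class SignatureRule:
    """Detection-p thresholds and the groups they apply to."""

    expressed_threshold: float = 0.001
    absent_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not self.expressed_threshold < self.absent_threshold:
            raise ValueError(
                "expressed_threshold must be below absent_threshold"
            )


@dataclass
class SignatureResult:
    aging: set[str]
    rejuvenation: set[str]
    per_gene_group_p: pd.DataFrame  # genes x groups

    def __post_init__(self) -> None:
        assert not self.aging & self.rejuvenation


def extract_signatures(
    group_p: dict[str, "pd.Series | dict[str, float]"],
    rule: SignatureRule | None = None,
) -> SignatureResult:
    """Apply the presence/absence rule to per-group detection p-values.

    ``group_p`` maps group name -> per-gene p-value series and must
    contain the keys ``MSC``, ``iMSC`` and ``iPSC`` (composing the MSC
    entry from fMSC and aMSC samples is the caller's job, e.g. via
    :func:`signature_group_pvalues`).  Only genes present in all three
    series are considered.
    """
    rule = rule or SignatureRule()
    for key in ("MSC", "iMSC", "iPSC"):
        if key not in group_p:
            raise KeyError(f"missing group {key!r}")
    frame = pd.DataFrame({g: pd.Series(v) for g, v in group_p.items()}).dropna()
    lo, hi = rule.expressed_threshold, rule.absent_threshold
    aging_mask = (
        (frame["MSC"] < lo) & (frame["iMSC"] > hi) & (frame["iPSC"] > hi)
    )
    rejuvenation_mask = (
        (frame["MSC"] > hi) & (frame["iMSC"] < lo) & (frame["iPSC"] < lo)
    )
    return SignatureResult(
        aging=set(frame.index[aging_mask]),
        rejuvenation=set(frame.index[rejuvenation_mask]),
        per_gene_group_p=frame,
    )


def signature_group_pvalues(
    det: DetectionResult,
    policy: str = "max",
    msc_groups: tuple[str, ...] = ("fMSC", "aMSC"),
) -> dict[str, pd.Series]:
    """Compose the MSC/iMSC/iPSC group p-values the signature rule needs.

    One policy is applied uniformly to all three groups (the combined MSC
    reading pools the fMSC and aMSC samples); ``single:SAMPLE`` policies
    reproduce single-sample figures.
    """
    return {
        "MSC": group_detection(det, list(msc_groups), policy=policy),
        "iMSC": group_detection(det, "iMSC", policy=policy),
        "iPSC": group_detection(det, "iPSC", policy=policy),
    }


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def pearson_distance(
    signals: pd.DataFrame, log2: bool = True
) -> pd.DataFrame:
    """Sample-by-sample distance d(i, j) = 1 - Pearson r over log2 signals."""
    x = np.asarray(signals, dtype=float)
    if log2:
        x = np.log2(x + 1.0)
    if x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 genes")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [signals.columns[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance sample(s): {bad}")
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return pd.DataFrame(d, index=signals.columns, columns=signals.columns)


@dataclass
class ClusterTree:
    """Agglomerative clustering result with a deterministic leaf order.

    Equal-height merges are resolved by scipy's deterministic input
    order; subtree rotation places the child containing the smallest
    original leaf index on the left.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str = "average"

    def _root(self):
        return hierarchy.to_tree(self.linkage_matrix)

    def leaf_order(self) -> list[str]:
        order: list[int] = []

        def walk(node) -> int:
            if node.is_leaf():
                order.append(node.id)
                return node.id
            # decide rotation before emitting leaves
            left_min = _min_leaf(node.left)
            right_min = _min_leaf(node.right)
            first, second = (
                (node.left, node.right)
                if left_min <= right_min
                else (node.right, node.left)
            )
            walk(first)
            walk(second)
            return min(left_min, right_min)

        walk(self._root())
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> dict[str, int]:
        """Partition into k clusters; IDs renumbered by first appearance."""
        flat = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        remap: dict[int, int] = {}
        out: dict[str, int] = {}
        for label, c in zip(self.labels, flat):
            out[label] = remap.setdefault(int(c), len(remap))
        return out

    def to_newick(self) -> str:
        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left_min = _min_leaf(node.left)
            right_min = _min_leaf(node.right)
            first, second = (
                (node.left, node.right)
                if left_min <= right_min
                else (node.right, node.left)
            )
            lb = node.dist - first.dist
            rb = node.dist - second.dist
            return f"({render(first)}:{lb:g},{render(second)}:{rb:g})"

        return render(self._root()) + ";"


def _min_leaf(node) -> int:
    if node.is_leaf():
        return node.id
    return min(_min_leaf(node.left), _min_leaf(node.right))


def hierarchical_cluster(
    dist: pd.DataFrame, linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of a precomputed distance matrix."""
    d = np.asarray(dist, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("need >= 2 observations")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else [
        str(i) for i in range(d.shape[0])
    ]
    return ClusterTree(z, labels, method=linkage)


@dataclass
class SubsetMatrix:
    matrix: pd.DataFrame
    missing: list[str]
    row_tree: ClusterTree | None
    col_tree: ClusterTree | None


def subset_heatmap_matrix(
    signals: pd.DataFrame, gene_list: list[str], cluster: bool = True
) -> SubsetMatrix:
    """Expression submatrix for an annotation gene list, both axes
    clustered by correlation distance.

    Genes absent from the matrix are reported in ``missing``, never
    silently dropped; an empty intersection is an error.
    """
    present = [g for g in gene_list if g in signals.index]
    missing = [g for g in gene_list if g not in signals.index]
    if not present:
        raise KeyError("no genes of the list are present in the matrix")
    sub = signals.loc[present]
    row_tree = col_tree = None
    if cluster:
        if sub.shape[1] >= 2 and sub.shape[0] >= 2:
            col_tree = hierarchical_cluster(pearson_distance(sub))
            row_tree = hierarchical_cluster(pearson_distance(sub.T))
    return SubsetMatrix(sub, missing, row_tree, col_tree)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def hypergeom_enrichment(
    query: set[str],
    annotations: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per annotation term.

    For a background of M genes, a term covering n of them and a query of
    N genes with k hits in the term, the p-value is the upper tail
    P(X >= k) of Hypergeom(M, n, N).  Term sets reaching outside the
    background are clipped with a warning; q-values are Benjamini-
    Hochberg across terms.
    """
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rows = []
    m = len(background)
    for term, genes in annotations.items():
        clipped = genes & background
        if clipped != genes:
            warnings.warn(
                f"term {term!r}: {len(genes - background)} genes outside "
                "background were clipped",
                stacklevel=2,
            )
        k = len(query & clipped)
        p = float(stats.hypergeom.sf(k - 1, m, len(clipped), len(query)))
        rows.append((term, len(clipped), k, min(p, 1.0)))
    frame = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "p"]
    ).set_index("term")
    frame["q"] = stats.false_discovery_control(frame["p"], method="bh")
    return frame.sort_values("p")
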