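"""Groupings and their concordance: hierarchical clustering of compression
distances, neighbour-joining trees with bootstrap for alignable sectors,
and comparison of sector-wise groupings.

Hierarchical clustering (single / complete linkage) is the published
route for the STR compression distances; neighbour joining on
p-distances stands in for the alignable sectors (model-based distance
estimation is out of scope).  Bootstrap supports are percentages of
column-resampled replicates containing each bipartition; groups at or
above 70% are treated as supported.  Concordance between two groupings
is quantified by shared (support-filtered) bipartitions and by the
adjusted Rand index of k-cut clusterings.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj
from sklearn.metrics import adjusted_rand_score

from .distances import DistanceMatrix

SUPPORT_THRESHOLD_DEFAULT = 70.0


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Labelled binary merge tree from agglomerative clustering."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) linkage
    linkage: str  # single | complete

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering with k clusters (label -> cluster id)."""
        assignment = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal merge nodes (including the root)."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for i, (a, b, _h, _c) in enumerate(self.linkage_matrix):
            merged = members[int(a)] | members[int(b)]
            members[n + i] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Rooted ultrametric-style Newick; leaf depth = merge height / 2."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def node_height(node) -> float:
            return 0.0 if node.is_leaf() else node.dist / 2.0

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            h = node_height(node)
            parts = [
                f"{render(ch)}:{h - node_height(ch):.10g}"
                for ch in (node.left, node.right)
            ]
            return "(" + ",".join(parts) + ")"

        return render(tree) + ";"


def hclust(matrix: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering (Lance-Williams single/complete updates)."""
    if linkage not in ("single", "complete"):
        raise ValueError(f"linkage must be 'single' or 'complete', got '{linkage}'")
    if len(matrix.labels) < 2:
        raise ValueError("need at least 2 labels")
    Z = hierarchy.linkage(matrix.condensed(), method=linkage)
    return Dendrogram(labels=matrix.labels, linkage_matrix=Z, linkage=linkage)


# ---------------------------------------------------------------------------
# p-distance and neighbour joining
# ---------------------------------------------------------------------------

def p_distance_matrix(alignment) -> DistanceMatrix:
    """Proportion of differing comparable (gap-free in both) columns."""
    labels = tuple(rec.id for rec in alignment)
    mat = np.array([list(str(rec.seq).upper()) for rec in alignment])
    n = len(labels)
    values = np.zeros((n, n))
    is_gap = mat == "-"
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(is_gap[i] | is_gap[j])
            m = int(ok.sum())
            d = float((mat[i][ok] != mat[j][ok]).mean()) if m else 1.0
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, metric="p-distance", mode="alignment")


@dataclass
class SupportTree:
    """Unrooted tree with branch lengths and optional bootstrap supports."""

    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)
    support_threshold: float = SUPPORT_THRESHOLD_DEFAULT

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(t.name for t in self.tree.tips())

    def bipartitions(self, supported_only: bool = False) -> set[frozenset]:
        splits = tree_bipartitions(self.tree)
        if supported_only and self.supports:
            splits = {
                s for s in splits if self.supports.get(s, 0.0) >= self.support_threshold
            }
        return splits

    def to_newick(self) -> str:
        return to_newick(self)


def nj_tree(matrix: DistanceMatrix) -> SupportTree:
    """Canonical neighbour joining (Q-criterion agglomeration).

    Exact on additive distance matrices: tip-to-tip path lengths of the
    returned tree reproduce the input distances.
    """
    if len(matrix.labels) < 3:
        raise ValueError("neighbour joining needs at least 3 labels")
    dm = _SkbioDM(matrix.values, ids=list(matrix.labels))
    return SupportTree(tree=_skbio_nj(dm))


def tree_bipartitions(tree: TreeNode, collapse_tol: float = 1e-12) -> set[frozenset]:
    """Non-trivial splits as frozensets of the two leaf-name sides.

    Internal edges of (numerically) zero length are collapsed: they
    carry no grouping signal, so e.g. a star-like NJ tree from equal
    distances contributes no bipartitions.
    """
    all_leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        if node.length is not None and abs(node.length) <= collapse_tol:
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset([side, all_leaves - side]))
    return splits


def bootstrap_support(
    alignment,
    tree_builder=None,
    n: int = 1000,
    seed: int = 0,
    support_threshold: float = SUPPORT_THRESHOLD_DEFAULT,
) -> SupportTree:
    """NJ tree with bootstrap supports from column resampling.

    ``tree_builder`` maps a DistanceMatrix to a SupportTree; the default
    is NJ on p-distances.  Support of a bipartition is the percentage of
    successful replicates whose tree contains it; replicates on which
    the builder fails are skipped with a warning.
    """
    if len(alignment) < 4:
        raise ValueError("bootstrap needs an alignment with at least 4 rows")
    if n < 1:
        raise ValueError("need at least 1 replicate")
    if tree_builder is None:
        tree_builder = nj_tree
    rng = np.random.default_rng(seed)
    ncol = alignment.get_alignment_length()

    main = tree_builder(p_distance_matrix(alignment))
    counts: dict[frozenset, int] = {s: 0 for s in tree_bipartitions(main.tree)}
    done = 0
    for rep in range(n):
        cols = np.sort(rng.integers(0, ncol, size=ncol))
        try:
            sub = _take_columns(alignment, cols)
            rep_tree = tree_builder(p_distance_matrix(sub))
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            warnings.warn(f"bootstrap replicate {rep} failed ({exc}); skipped")
            continue
        done += 1
        for s in tree_bipartitions(rep_tree.tree):
            if s in counts:
                counts[s] += 1
    if done == 0:
        raise RuntimeError("all bootstrap replicates failed")
    supports = {s: 100.0 * c / done for s, c in counts.items()}
    _annotate_supports(main.tree, supports)
    return SupportTree(tree=main.tree, supports=supports, support_threshold=support_threshold)


def _take_columns(alignment, cols):
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    mat = np.array([list(str(rec.seq)) for rec in alignment])
    sub = mat[:, cols]
    return MultipleSeqAlignment(
        SeqRecord(Seq("".join(row)), id=rec.id, description="")
        for rec, row in zip(alignment, sub)
    )


def _annotate_supports(tree: TreeNode, supports: dict[frozenset, float]) -> None:
    all_leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        split = frozenset([side, all_leaves - side])
        if split in supports:
            node.name = f"{supports[split]:.0f}"


# ---------------------------------------------------------------------------
# grouping comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupingComparison:
    """Concordance summary between two groupings on the same leaf set."""

    shared_bipartitions: int
    n_bipartitions_a: int
    n_bipartitions_b: int
    ari: float
    k: int
    ari_a_truth: float | None
    ari_b_truth: float | None
    fused_groups: tuple[tuple[str, ...], ...]
    split_groups: tuple[str, ...]


def _grouping_leaves(g) -> frozenset[str]:
    if isinstance(g, Dendrogram):
        return frozenset(g.labels)
    return g.leaf_names


def _grouping_splits(g, supported_only: bool) -> set[frozenset]:
    if isinstance(g, Dendrogram):
        leaves = frozenset(g.labels)
        return {
            frozenset([c, leaves - c])
            for c in g.clades()
            if 1 < len(c) < len(leaves) - 1
        }
    return g.bipartitions(supported_only=supported_only)


def _grouping_cut(g, k: int) -> dict[str, int]:
    if isinstance(g, Dendrogram):
        return g.cut(k)
    return tree_cut(g.tree, k)


def tree_cut(tree: TreeNode, k: int) -> dict[str, int]:
    """k groups from a tree by removing the k-1 longest internal edges."""
    leaves = [t.name for t in tree.tips()]
    if k >= len(leaves):
        return {name: i + 1 for i, name in enumerate(sorted(leaves))}
    internal = [
        node
        for node in tree.non_tips(include_self=False)
        if node.length is not None
    ]
    internal.sort(key=lambda nd: -(nd.length or 0.0))
    removed = set(id(nd) for nd in internal[: k - 1])
    # union-find over leaves through non-removed edges
    parent_of: dict[str, int] = {}
    comp = 0
    assigned: dict[int, int] = {}

    def component_root(node):
        cur = node
        while cur.parent is not None and id(cur) not in removed:
            cur = cur.parent
        return cur

    for tip in tree.tips():
        root = component_root(tip)
        if id(root) not in assigned:
            comp += 1
            assigned[id(root)] = comp
        parent_of[tip.name] = assigned[id(root)]
    return parent_of


def compare_groupings(
    a,
    b,
    truth: dict[str, str] | None = None,
    k: int | None = None,
    supported_only: bool = False,
) -> GroupingComparison:
    """Compare two groupings (Dendrogram or SupportTree) on one leaf set."""
    leaves_a, leaves_b = _grouping_leaves(a), _grouping_leaves(b)
    if leaves_a != leaves_b:
        raise ValueError("leaf sets differ between the two groupings")
    if k is None:
        if truth is None:
            raise ValueError("k is required when no truth labels are given")
        k = len(set(truth.values()))

    splits_a = _grouping_splits(a, supported_only)
    splits_b = _grouping_splits(b, supported_only)
    shared = len(splits_a & splits_b)

    cut_a = _grouping_cut(a, k)
    cut_b = _grouping_cut(b, k)
    order = sorted(leaves_a)
    ari = float(
        adjusted_rand_score([cut_a[x] for x in order], [cut_b[x] for x in order])
    )

    ari_a_truth = ari_b_truth = None
    fused: list[tuple[str, ...]] = []
    split_lineages: list[str] = []
    if truth is not None:
        t = [truth[x] for x in order]
        ari_a_truth = float(adjusted_rand_score(t, [cut_a[x] for x in order]))
        ari_b_truth = float(adjusted_rand_score(t, [cut_b[x] for x in order]))
        # lineages sharing a cluster in BOTH groupings are reported fused;
        # lineages scattered over >1 cluster in both are reported split
        fused_pairs = None
        for cut in (cut_a, cut_b):
            clusters: dict[int, set[str]] = {}
            for x in order:
                clusters.setdefault(cut[x], set()).add(truth[x])
            pairs = set()
            for lin_set in clusters.values():
                if len(lin_set) > 1:
                    pairs.add(tuple(sorted(lin_set)))
            fused_pairs = pairs if fused_pairs is None else (fused_pairs & pairs)
        fused = sorted(fused_pairs or set())
        for lin in sorted(set(truth.values())):
            members = [x for x in order if truth[x] == lin]
            if len({cut_a[x] for x in members}) > 1 and len({cut_b[x] for x in members}) > 1:
                split_lineages.append(lin)
    return GroupingComparison(
        shared_bipartitions=shared,
        n_bipartitions_a=len(splits_a),
        n_bipartitions_b=len(splits_b),
        ari=ari,
        k=k,
        ari_a_truth=ari_a_truth,
        ari_b_truth=ari_b_truth,
        fused_groups=tuple(tuple(f) for f in fused),
        split_groups=tuple(split_lineages),
    )


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------

def to_newick(obj) -> str:
    """Serialise a SupportTree (supports as internal labels) or Dendrogram."""
    if isinstance(obj, Dendrogram):
        return obj.to_newick()
    buf = io.StringIO()
    obj.tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> SupportTree:
    """Parse Newick into a SupportTree, recovering internal-label supports."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    all_leaves = frozenset(t.name for t in tree.tips())
    supports: dict[frozenset, float] = {}
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            try:
                val = float(node.name)
            except ValueError:
                continue
            side = frozenset(t.name for t in node.tips())
            supports[frozenset([side, all_leaves - side])] = val
    return SupportTree(tree=tree, supports=supports)
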