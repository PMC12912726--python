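"""Tree handling: Newick I/O, consensus, ultrametricization, fossil grafting, VCV.

Trees are rooted :class:`dendropy.Tree` objects with branch lengths in
time units (millions of years throughout the pipeline; rescaling to unit
height happens only inside the trait-model fitting).

The phylogenetic variance-covariance matrix (VCV) of a rooted tree has
entry (i, j) equal to the root-to-MRCA path length of tips i and j — the
shared evolutionary time of the pair — and tip depths on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import dendropy

__all__ = [
    "read_newick",
    "write_newick",
    "tree_height",
    "node_depths",
    "majority_consensus",
    "force_ultrametric",
    "FossilSpec",
    "graft_fossil_tips",
    "phylo_vcv",
    "patristic_matrix",
]


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree from a path or a Newick string."""
    is_path = isinstance(source, Path)
    if not is_path and isinstance(source, str) and "(" not in source:
        try:
            is_path = Path(source).is_file()
        except OSError:
            is_path = False
    if is_path:
        tree = dendropy.Tree.get(path=str(source), schema="newick", rooting="force-rooted")
    else:
        tree = dendropy.Tree.get(data=str(source), schema="newick", rooting="force-rooted")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def _check_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length < 0:
            raise ValueError(f"edge above {edge.head_node} has invalid length {edge.length}")


def node_depths(tree: dendropy.Tree) -> dict:
    """Root-to-node path length for every node (root at depth 0)."""
    depths = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
        else:
            depths[nd] = depths[nd.parent_node] + float(nd.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# consensus

def _clade_sets(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map clade (frozenset of tip labels) -> subtending branch length."""
    out = {}
    below = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
        else:
            below[nd] = frozenset().union(*(below[ch] for ch in nd.child_nodes()))
        length = float(nd.edge.length) if nd.edge.length is not None else 0.0
        out[below[nd]] = length
    return out


def majority_consensus(
    trees: Sequence[dendropy.Tree], min_freq: float = 0.5, strict: bool = False
) -> dendropy.Tree:
    """Majority-rule consensus of rooted trees sharing one tip set.

    Clades present in more than ``min_freq`` of the trees (all trees when
    ``strict``) are retained; each retained branch gets the mean length
    over the trees containing the clade. Majority clades (>50%) are
    pairwise compatible, so the nesting is well defined.
    """
    if not trees:
        raise ValueError("no trees given")
    tipsets = [frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees]
    if len(set(tipsets)) != 1:
        raise ValueError("all trees must share the same tip set")
    n = len(trees)
    counts: dict[frozenset, int] = {}
    length_sums: dict[frozenset, float] = {}
    for tree in trees:
        for clade, length in _clade_sets(tree).items():
            counts[clade] = counts.get(clade, 0) + 1
            length_sums[clade] = length_sums.get(clade, 0.0) + length
    all_tips = tipsets[0]
    if strict:
        kept = {c for c, k in counts.items() if k == n}
    else:
        kept = {c for c, k in counts.items() if k > min_freq * n}
    kept |= {frozenset([t]) for t in all_tips}
    kept.add(all_tips)

    taxon_ns = dendropy.TaxonNamespace(sorted(all_tips))
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    by_size = sorted(kept, key=len, reverse=True)
    nodes: dict[frozenset, dendropy.Node] = {all_tips: tree.seed_node}
    for clade in by_size[1:]:
        parent = min(
            (c for c in nodes if clade < c), key=len
        )  # smallest kept clade strictly containing this one
        nd = dendropy.Node()
        if counts.get(clade, 0):
            nd.edge.length = length_sums[clade] / counts[clade]
        else:  # tip never seen with a length (cannot happen for shared tip sets)
            nd.edge.length = 0.0
        nodes[parent].add_child(nd)
        nodes[clade] = nd
    for clade, nd in nodes.items():
        if len(clade) == 1:
            nd.taxon = taxon_ns.get_taxon(next(iter(clade)))
    # insertion order was by size, so parents existed before children
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# ultrametricity and fossil grafting

def force_ultrametric(tree: dendropy.Tree) -> dendropy.Tree:
    """Extend terminal branches so every tip reaches the maximal depth.

    Internal branches are untouched; returns a modified clone.
    """
    tree = tree.clone(depth=1)
    _check_lengths(tree)
    depths = node_depths(tree)
    height = max(depths[l] for l in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = float(leaf.edge.length or 0.0) + (height - depths[leaf])
    return tree


@dataclass(frozen=True)
class FossilSpec:
    """A fossil tip to graft: name, tip age (Ma), attachment clade, stem age.

    ``attachment`` is a tip label or a tuple of tip labels whose MRCA's
    stem branch receives the fossil; ``stem_age`` defaults to the
    midpoint of the permissible interval along that branch.
    """

    name: str
    tip_age: float
    attachment: str | tuple[str, ...]
    stem_age: float | None = None


def read_fossil_specs(path: str | Path) -> list["FossilSpec"]:
    """Fossil specs from delimited text: name, tip_age_Ma, clade, stem_age_Ma.

    ``clade`` is one tip label or several joined with '+'; an empty
    ``stem_age_Ma`` cell requests the midpoint default.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"name", "tip_age_Ma", "clade"}
    if not required <= set(df.columns):
        raise ValueError(f"fossil table needs columns {sorted(required)}")
    specs = []
    for row in df.to_dict("records"):
        labels = tuple(s.strip() for s in str(row["clade"]).split("+"))
        stem = row.get("stem_age_Ma")
        stem = None if stem is None or (isinstance(stem, float) and np.isnan(stem)) else float(stem)
        specs.append(FossilSpec(str(row["name"]), float(row["tip_age_Ma"]),
                                labels if len(labels) > 1 else labels[0], stem))
    return specs


def _find_mrca(tree: dendropy.Tree, labels: Iterable[str]):
    """MRCA by direct ancestor walks (robust to structural edits)."""
    labels = [labels] if isinstance(labels, str) else list(labels)
    leaf_by_label = {l.taxon.label: l for l in tree.leaf_node_iter()}
    missing = [lab for lab in labels if lab not in leaf_by_label]
    if missing:
        raise ValueError(f"tip(s) {missing} not present in tree")
    first = leaf_by_label[labels[0]]
    lineage = []  # first leaf's ancestors, tipward to rootward
    nd = first
    while nd is not None:
        lineage.append(nd)
        nd = nd.parent_node
    rank = {nd: i for i, nd in enumerate(lineage)}
    deepest = 0
    for lab in labels[1:]:
        nd = leaf_by_label[lab]
        while nd not in rank:
            nd = nd.parent_node
        deepest = max(deepest, rank[nd])
    return lineage[deepest]


def graft_fossil_tips(tree: dendropy.Tree, fossil_specs: Sequence[FossilSpec]) -> dendropy.Tree:
    """Attach fossil tips on the stems of named clades.

    Ages are measured back from the present (the depth of the extant
    tips, which must be contemporaneous). Each fossil's terminal branch
    has length ``stem_age - tip_age``, so extinct tips end above the
    present; all pre-existing pairwise distances are preserved.
    """
    tree = tree.clone(depth=1)
    for spec in fossil_specs:
        depths = node_depths(tree)
        height = max(depths[l] for l in tree.leaf_node_iter())
        node = _find_mrca(tree, spec.attachment)
        if node.parent_node is None:
            raise ValueError(f"fossil {spec.name!r}: cannot graft on the root stem")
        node_age = height - depths[node]
        parent_age = height - depths[node.parent_node]
        stem_age = spec.stem_age
        if stem_age is None:
            stem_age = 0.5 * (max(node_age, spec.tip_age) + parent_age)
        if not (node_age < stem_age < parent_age):
            raise ValueError(
                f"fossil {spec.name!r}: stem age {stem_age} outside the attachment branch "
                f"({node_age:.4g}, {parent_age:.4g})"
            )
        if stem_age <= spec.tip_age:
            raise ValueError(
                f"fossil {spec.name!r}: stem age {stem_age} not older than tip age {spec.tip_age}"
            )
        parent = node.parent_node
        new = dendropy.Node()
        new.edge.length = parent_age - stem_age
        parent.remove_child(node)
        parent.add_child(new)
        node.edge.length = stem_age - node_age
        new.add_child(node)
        taxon = tree.taxon_namespace.new_taxon(spec.name)
        fossil = dendropy.Node(taxon=taxon)
        fossil.edge.length = stem_age - spec.tip_age
        new.add_child(fossil)
    return tree


# ---------------------------------------------------------------------------
# covariance structure

def _leaf_index(tree: dendropy.Tree, order: Sequence[str] | None):
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    if order is None:
        order = sorted(labels)
    missing = set(order) - set(labels)
    if missing:
        raise ValueError(f"tips {sorted(missing)} not in tree")
    index = {lab: i for i, lab in enumerate(order)}
    return list(order), index


def phylo_vcv(
    tree: dendropy.Tree,
    order: Sequence[str] | None = None,
    regimes: Mapping | None = None,
):
    """Phylogenetic VCV: shared root-to-MRCA path length per tip pair.

    With ``regimes`` (a node -> regime-label mapping covering every
    non-root node, keyed by the node whose subtending edge is painted),
    additionally returns one path-length matrix per regime; these sum to
    the plain VCV and drive the multi-rate Brownian model.
    """
    _check_lengths(tree)
    order, index = _leaf_index(tree, order)
    n = len(order)
    depths = node_depths(tree)
    regime_labels = sorted(set(regimes.values()), key=str) if regimes is not None else []

    # per-node cumulative per-regime depth from the root
    regdepth: dict = {}
    if regimes is not None:
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                regdepth[nd] = {r: 0.0 for r in regime_labels}
            else:
                if nd not in regimes:
                    raise ValueError(f"no regime painted on the edge above {nd}")
                acc = dict(regdepth[nd.parent_node])
                acc[regimes[nd]] += float(nd.edge.length or 0.0)
                regdepth[nd] = acc

    C = np.zeros((n, n))
    Cr = {r: np.zeros((n, n)) for r in regime_labels}
    below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            if nd.taxon.label in index:
                i = index[nd.taxon.label]
                below[nd] = [i]
                C[i, i] = depths[nd]
                for r in regime_labels:
                    Cr[r][i, i] = regdepth[nd][r]
            else:
                below[nd] = []
        else:
            groups = [below[ch] for ch in nd.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = depths[nd]
                            for r in regime_labels:
                                Cr[r][i, j] = Cr[r][j, i] = regdepth[nd][r]
            below[nd] = [i for g in groups for i in g]
    if regimes is None:
        return order, C
    return order, C, Cr


def patristic_matrix(C: np.ndarray) -> np.ndarray:
    """Pairwise tip-to-tip path lengths from a VCV matrix."""
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2.0 * C
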