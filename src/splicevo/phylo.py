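"""Neighbour-Joining trees, bootstrap supports, gene concatenation.

The tree builder is the classic Saitou-Nei agglomeration with the
Studier-Keppler Q-criterion: at each step the pair (i, j) minimising

    Q(i, j) = (m - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined (m = number of active nodes), branch lengths follow the
standard formulas, and the last three nodes are attached to a
trifurcating root, so the result is an unrooted tree. Ties are broken by
the smallest (i, j) index pair in the current node ordering; negative
branch lengths are clamped to zero with the deficit moved to the sibling
edge, so the i-j path length through the new node is preserved.

Bootstrap support for an internal edge is the percentage of
column-resampled replicates whose NJ tree contains the same leaf
bipartition; supports are mapped onto the point-estimate tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from splicevo.errors import AlignmentError, LabelError, SaturationError, SplicevoError
from splicevo.evolution import DistanceMatrix, distance_matrix
from splicevo.seqio import SeqRecord


@dataclass
class TreeNode:
    """One node of a phylogenetic tree (leaf iff no children)."""

    label: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self):
        return [n for n in self.walk() if n.is_leaf]


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary (trifurcating) root."""

    root: TreeNode
    n_failed_replicates: int = 0

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, one per internal edge.

        Each bipartition is canonicalised as the side NOT containing the
        lexicographically smallest leaf label, so the set is comparable
        across differently rooted representations of the same tree.
        """
        all_leaves = set(self.leaf_labels())
        ref = min(all_leaves)
        out = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(leaf.label for leaf in node.leaves())
            if ref in side:
                side = frozenset(all_leaves - side)
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def internal_edges(self) -> list[TreeNode]:
        """Child nodes subtending internal (non-trivial) edges."""
        n = len(self.leaf_labels())
        return [
            node
            for node in self.root.walk()
            if node is not self.root
            and not node.is_leaf
            and 2 <= len(node.leaves()) <= n - 2
        ]

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.6f}"
            inner = ",".join(render(c) for c in node.children)
            label = "" if node.support is None else str(int(node.support))
            return f"({inner}){label}:{node.length:.6f}"

        children = ",".join(render(c) for c in self.root.children)
        return f"({children});"

    def rooted_on(self, outgroup_label: str) -> "PhyloTree":
        """A display re-rooting on the edge leading to ``outgroup_label``.

        The stored tree stays unrooted; this returns a new tree whose
        root bisects the outgroup's pendant edge.
        """
        edges = _edge_list(self.root)
        nodes = {id(n): n for n in self.root.walk()}
        target = next(
            (n for n in nodes.values() if n.is_leaf and n.label == outgroup_label), None
        )
        if target is None:
            raise LabelError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
        adjacency: dict[int, list[tuple[int, float, int | None]]] = {}
        for a, b, length, support in edges:
            adjacency.setdefault(a, []).append((b, length, support))
            adjacency.setdefault(b, []).append((a, length, support))

        (neighbor, length, _sup) = adjacency[id(target)][0]

        def build(node_id: int, parent_id: int, edge_len: float, edge_sup) -> TreeNode:
            src = nodes[node_id]
            out = TreeNode(label=src.label, length=edge_len, support=edge_sup)
            for other, olen, osup in adjacency[node_id]:
                if other != parent_id:
                    out.children.append(build(other, node_id, olen, osup))
            return out

        root = TreeNode()
        root.children.append(
            TreeNode(label=target.label, length=length / 2.0)
        )
        root.children.append(build(neighbor, id(target), length / 2.0, None))
        return PhyloTree(root, self.n_failed_replicates)


def _edge_list(root: TreeNode):
    edges = []

    def visit(node: TreeNode):
        for child in node.children:
            edges.append((id(node), id(child), child.length, child.support))
            visit(child)

    visit(root)
    return edges


# ---------------------------------------------------------------------------
# Neighbour-Joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbour-Joining tree from a distance matrix.

    Requires at least 3 taxa and finite entries (a saturated distance
    raises :class:`SaturationError`).
    """
    n = len(dm.taxa)
    if n < 3:
        raise SplicevoError("Neighbour-Joining needs at least 3 taxa")
    if not np.isfinite(dm.d).all():
        raise SaturationError("distance matrix contains saturated (non-finite) entries")

    nodes: list[TreeNode] = [TreeNode(label=t) for t in dm.taxa]
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.empty((m - 1, m - 1))
        d_next[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d_next[: m - 2, m - 2] = d_next[m - 2, : m - 2] = dnew[keep]
        d_next[m - 2, m - 2] = 0.0
        d = d_next
        nodes = [nodes[k] for k in keep] + [new]

    # attach the last three nodes to a trifurcating root
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(0.0, length)
    return PhyloTree(TreeNode(children=list(nodes)))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj = max(0.0, lj + li)
        li = 0.0
    elif lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_nj(
    alignment: list[SeqRecord],
    model: str = "tn93",
    replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement (same
    length), recomputes the distance matrix and the NJ tree; an internal
    edge's support is the percentage of successful replicates containing
    its leaf bipartition. Replicates whose distance matrix is saturated
    are excluded from the denominator (``n_failed_replicates`` on the
    returned tree, plus a warning).
    """
    labels = [rec.id for rec in alignment]
    if len(set(labels)) != len(labels):
        raise LabelError("duplicate taxon labels in alignment")
    rows = [rec.sequence for rec in alignment]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise AlignmentError("ragged alignment")

    point = nj_tree(distance_matrix(alignment, model=model))

    chars = np.array([list(r) for r in rows])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in point.bipartitions()}
    ok = failed = 0
    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        resampled = ["".join(row) for row in chars[:, cols]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dm = distance_matrix(
                    [SeqRecord(lab, seq, mode=alignment[0].mode) for lab, seq in zip(labels, resampled)],
                    model=model,
                )
            rep_tree = nj_tree(dm)
        except SaturationError:
            failed += 1
            continue
        ok += 1
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if failed:
        warnings.warn(
            f"{failed} bootstrap replicate(s) had saturated distances and were excluded",
            stacklevel=2,
        )
    all_leaves = set(labels)
    ref = min(all_leaves)
    for node in point.internal_edges():
        side = frozenset(leaf.label for leaf in node.leaves())
        if ref in side:
            side = frozenset(all_leaves - side)
        if ok:
            node.support = round(100.0 * counts.get(side, 0) / ok)
    point.n_failed_replicates = failed
    return point


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concatenate(
    alignments: list[list[SeqRecord]],
) -> tuple[list[SeqRecord], list[tuple[int, int]]]:
    """Concatenate gene alignments over a shared taxon set.

    All alignments must cover exactly the same taxon labels (order may
    differ); a taxon present in one gene only raises
    :class:`LabelError` — there is no silent gap-filling. Returns the
    concatenated rows (taxon order of the first alignment) and the
    0-based half-open column span of each gene.
    """
    if not alignments:
        raise AlignmentError("no alignments given")
    reference = [rec.id for rec in alignments[0]]
    ref_set = set(reference)
    if len(ref_set) != len(reference):
        raise LabelError("duplicate taxon labels")
    spans: list[tuple[int, int]] = []
    parts: dict[str, list[str]] = {t: [] for t in reference}
    offset = 0
    for idx, aln in enumerate(alignments):
        by_taxon = {rec.id: rec.sequence for rec in aln}
        if set(by_taxon) != ref_set:
            missing = ref_set.symmetric_difference(by_taxon)
            raise LabelError(
                f"gene {idx}: taxon set mismatch (symmetric difference: {sorted(missing)})"
            )
        width = len(next(iter(by_taxon.values())))
        if any(len(s) != width for s in by_taxon.values()):
            raise AlignmentError(f"gene {idx}: ragged alignment")
        for t in reference:
            parts[t].append(by_taxon[t])
        spans.append((offset, offset + width))
        offset += width
    mode = alignments[0][0].mode
    rows = [SeqRecord(t, "".join(parts[t]), mode=mode) for t in reference]
    return rows, spans
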