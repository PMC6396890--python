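"""Independent brute-force oracles used to check the implementations.

These deliberately re-derive results by exhaustive enumeration or direct
simulation and stay independent of the code paths they validate.
"""

from itertools import product

import numpy as np


def enumerate_exon_chains(cds: str, genomic: str, min_exon: int, min_intron: int):
    """All exact-match exon chains spelling out ``cds`` on ``genomic``.

    Returns a list of (exons, canonical_count, donor_positions); each
    exon list partitions the CDS into segments of >= min_exon nt placed
    in order with gaps of >= min_intron nt.
    """
    L = len(cds)
    results = []

    def rec(c, gmin, chain, canon, donors):
        if c == L:
            results.append((list(chain), canon, tuple(donors)))
            return
        for c2 in range(c + min_exon, L + 1):
            seg = cds[c:c2]
            start = gmin if not chain else gmin + min_intron
            g = genomic.find(seg, start)
            while g != -1:
                extra_canon = 0
                if chain:
                    prev_end = chain[-1][1]
                    donor = genomic[prev_end : prev_end + 2]
                    acceptor = genomic[g - 2 : g]
                    extra_canon = 1 if (donor == "GT" and acceptor == "AG") else 0
                    donors.append(prev_end)
                chain.append((g, g + len(seg)))
                rec(c2, g + len(seg), chain, canon + extra_canon, donors)
                chain.pop()
                if chain:
                    donors.pop()
                g = genomic.find(seg, g + 1)

    rec(0, 0, [], 0, [])
    return results


def best_exact_chain(cds: str, genomic: str, min_exon: int, min_intron: int):
    """The optimal chain under the mapper's objective: most canonical
    introns, then leftmost donor positions, enumerated exhaustively."""
    chains = enumerate_exon_chains(cds, genomic, min_exon, min_intron)
    if not chains:
        return None
    return min(chains, key=lambda t: (-t[1], t[2]))[0]


def brute_force_scan(elements, peptide: str):
    """All matches of a compiled PROSITE pattern by enumerating every
    start position and every repeat assignment."""
    matches = []
    ranges = [range(e.min_repeat, e.max_repeat + 1) for e in elements]
    for start in range(len(peptide) + 1):
        found_end = None
        for takes in product(*ranges):
            pos = start
            ok = True
            for elem, take in zip(elements, takes):
                if pos + take > len(peptide) or not all(
                    elem.matches(peptide[pos + k]) for k in range(take)
                ):
                    ok = False
                    break
                pos += take
            if ok:
                found_end = pos if found_end is None else max(found_end, pos)
        if found_end is not None:
            matches.append((start, found_end - start))
    return matches


def sliding_window_identity(query: str, subject: str):
    """Best gap-free sliding-window identity of ``query`` within
    ``subject`` (an indel-free local-alignment stand-in)."""
    best = 0.0
    n = len(query)
    for g in range(len(subject) - n + 1):
        window = subject[g : g + n]
        ident = sum(1 for a, b in zip(query, window) if a == b) / n
        best = max(best, ident)
    return best


def path_length_matrix(tree_root):
    """Leaf-to-leaf path-sum distances of a phylogenetic tree (additive
    matrix), computed by explicit traversal."""
    leaves = tree_root.leaves()
    labels = [leaf.label for leaf in leaves]

    parents = {}

    def index(node, parent):
        parents[id(node)] = (parent, node.length)
        for child in node.children:
            index(child, node)

    index(tree_root, None)

    def path_to_root(node):
        out = []
        total = 0.0
        while node is not None:
            out.append((id(node), total))
            parent, length = parents[id(node)]
            total += length
            node = parent
        return dict(out), total

    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        up_i, _ = path_to_root(leaves[i])
        for j in range(i + 1, n):
            node = leaves[j]
            total = 0.0
            while id(node) not in up_i:
                parent, length = parents[id(node)]
                total += length
                node = parent
            d[i, j] = d[j, i] = total + up_i[id(node)]
    return labels, d


def random_binary_tree(labels, rng, min_len=0.05, max_len=0.3):
    """A random binary tree over ``labels`` built by random joins."""
    from splicevo.phylo import PhyloTree, TreeNode

    nodes = [TreeNode(label=l, length=float(rng.uniform(min_len, max_len))) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new = TreeNode(
            length=float(rng.uniform(min_len, max_len)),
            children=[nodes[i], nodes[j]],
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    return PhyloTree(TreeNode(children=nodes))
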