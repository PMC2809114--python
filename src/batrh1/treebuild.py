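"""Neighbor-Joining trees, bootstrap support, Newick I/O and topology queries.

Trees are :class:`dendropy.Tree` objects throughout.  NJ is the standard
Saitou-Nei agglomeration with a deterministic tie-break (the pair whose
cluster labels are lexicographically smallest); negative branch-length
estimates are clamped to zero with the deficit moved onto the sister branch
so path lengths are preserved.
"""

from __future__ import annotations

import io
from typing import Iterable

import dendropy
import numpy as np

from . import lwl85
from .codonseq import CodonAlignment, GeneticCode, standard_code
from .lwl85 import DistanceMatrix

PhyloTree = dendropy.Tree

_TIE_TOL = 1e-12


class TreeError(ValueError):
    pass


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-Joining tree from a finite distance matrix (unrooted).

    Deterministic: among joins whose Q values tie within 1e-12, the pair
    with the lexicographically smallest (label, label) key is chosen, where
    a cluster is keyed by its smallest member taxon.
    """
    n = len(dm.taxa)
    if n < 3:
        raise TreeError("need at least 3 taxa for NJ")
    if not dm.is_finite:
        i, j = map(int, np.argwhere(~np.isfinite(dm.d))[0])
        raise TreeError(
            f"non-finite distance between {dm.taxa[i]!r} and {dm.taxa[j]!r}"
        )
    ns = dendropy.TaxonNamespace(list(dm.taxa))
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for taxon in ns:
        nd = dendropy.Node(taxon=taxon)
        nodes.append(nd)
    keys = [t.label for t in ns]  # lexicographic cluster keys
    D = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                ka, kb = keys[active[ai]], keys[active[aj]]
                key = (min(ka, kb), max(ka, kb))
                if best is None or q < best[0] - _TIE_TOL or (
                    abs(q - best[0]) <= _TIE_TOL and key < best[1]
                ):
                    best = (q, key, ai, aj)
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives to 0, transferring the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new cluster to the remaining ones
        newrow = np.empty(D.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = newrow[k]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    root = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        length = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        nodes[a].edge.length = max(length, 0.0)
        root.add_child(nodes[a])
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def leaf_labels(tree: PhyloTree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartitions(tree: PhyloTree) -> frozenset:
    """Non-trivial splits of the unrooted topology.

    Each split is represented canonically by the side that does NOT contain
    the lexicographically smallest leaf label.
    """
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return frozenset(out)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise TreeError(
            f"leaf sets differ; only in first: {sorted(l1 - l2)}, "
            f"only in second: {sorted(l2 - l1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def check_clade(tree: PhyloTree, taxa: Iterable[str], outgroup: Iterable[str]) -> bool:
    """True iff some edge splits exactly ``taxa`` from the rest of the leaves
    when the tree is rooted on ``outgroup`` (which must be disjoint)."""
    taxa = frozenset(taxa)
    outgroup = frozenset(outgroup)
    leaves = leaf_labels(tree)
    unknown = (taxa | outgroup) - leaves
    if unknown:
        raise TreeError(f"unknown leaf labels: {sorted(unknown)}")
    if taxa & outgroup:
        raise TreeError("taxa and outgroup overlap")
    if len(taxa) <= 1 or len(taxa) >= len(leaves) - 1:
        return True  # trivial splits always present in an unrooted tree
    ref = min(leaves)
    side = taxa if ref not in taxa else leaves - taxa
    return side in bipartitions(tree)


def _resample_codon_columns(aln: CodonAlignment, rng: np.random.Generator) -> CodonAlignment:
    cols = rng.integers(0, aln.n_codons, size=aln.n_codons)
    seqs = [
        "".join(seq[3 * c : 3 * c + 3] for c in cols) for seq in aln.sequences
    ]
    return CodonAlignment(list(aln.taxa), seqs)


def bootstrap_support(
    aln: CodonAlignment,
    mode: str,
    n_reps: int,
    seed: int,
    code: GeneticCode | None = None,
    max_dropped_frac: float = 0.10,
) -> PhyloTree:
    """NJ tree with nonparametric bootstrap supports on internal edges.

    Codon columns are resampled with replacement (for amino-acid distances a
    residue column coincides with a codon column, so the resampling unit is
    the same); support is the percentage of replicate trees containing each
    split of the full-data tree.  Replicates with undefined distances are
    dropped and counted; more than ``max_dropped_frac`` dropped is an error.
    Reproducible given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    code = code or standard_code()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", lwl85.UndefinedDistanceWarning)
        base_dm = lwl85.distance_matrix(aln, mode, code)
        tree = nj_tree(base_dm)
        splits = bipartitions(tree)
        counts = {s: 0 for s in splits}
        rng = np.random.default_rng(seed)
        dropped = 0
        for _ in range(n_reps):
            rep = _resample_codon_columns(aln, rng)
            dm = lwl85.distance_matrix(rep, mode, code)
            if not dm.is_finite:
                dropped += 1
                continue
            rep_splits = bipartitions(nj_tree(dm))
            for s in splits:
                if s in rep_splits:
                    counts[s] += 1
    if dropped > max_dropped_frac * n_reps:
        raise TreeError(
            f"{dropped}/{n_reps} bootstrap replicates had undefined distances"
        )
    used = n_reps - dropped
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else all_leaves - below
        if side in counts and used > 0:
            node.label = str(int(round(100.0 * counts[side] / used)))
    return tree


def read_newick(source) -> PhyloTree:
    """Read a Newick tree from a path or a string."""
    text = source
    if "(" not in str(source):
        with open(source) as fh:
            text = fh.read()
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )


def write_newick(tree: PhyloTree, path=None) -> str:
    """Newick with 6-decimal branch lengths and internal labels as supports."""
    s = tree.as_string(
        schema="newick",
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
        suppress_rooting=True,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
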