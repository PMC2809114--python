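"""Marginal maximum-likelihood reconstruction of ancestral codon sequences.

For every internal node of a fixed, rooted species tree the posterior
distribution over the 61 sense codons is computed site by site with the
standard inside-outside (up-down) pruning recursion under a fitted
single-omega (M0) codon model.  The MAP codon per node and site is the
reconstructed ancestral state.  For a reversible model the posteriors at
named internal nodes do not depend on where the tree is rooted, because the
equilibrium frequencies are stationary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

from .codonseq import CodonAlignment, GeneticCode, standard_code
from .codonmodel import (
    ModelError,
    ModelFit,
    Propagator,
    PruningEngine,
    build_q,
)


class AncestralError(ValueError):
    pass


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "node") -> dendropy.Tree:
    """Assign labels to unlabeled internal nodes (preorder numbering)."""
    k = 0
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and not nd.label:
            nd.label = f"{prefix}{k}"
        k += 1
    return tree


def transfer_branch_lengths(tree: dendropy.Tree, fit: ModelFit) -> dendropy.Tree:
    """Copy fitted branch lengths onto a (possibly rooted) clone of ``tree``.

    Edges are matched by the leaf set below them.  A bifurcating root's two
    edges correspond to one merged edge of the derooted fitting tree; the
    fitted length is split equally between them (root marginals are
    root-position dependent only through this split; all other nodes are
    unaffected under reversibility).
    """
    fitted = {}
    for nd in fit.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        ls = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        fitted[ls] = nd.edge.length
    out = tree.clone(depth=1)
    all_leaves = frozenset(lf.taxon.label for lf in out.leaf_node_iter())
    root_children = out.seed_node.child_nodes()
    merged = len(root_children) == 2
    for nd in out.preorder_node_iter():
        if nd.parent_node is None:
            continue
        ls = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if merged and nd.parent_node is out.seed_node:
            # both root edges map to the single merged edge of the derooted
            # fit tree; split its fitted length equally
            key = ls if ls in fitted else all_leaves - ls
            if key not in fitted:
                raise AncestralError(
                    f"no fitted length for root edge above {sorted(ls)[:3]}..."
                )
            nd.edge.length = 0.5 * fitted[key]
        elif ls in fitted:
            nd.edge.length = fitted[ls]
        else:
            raise AncestralError(
                f"no fitted length for edge above {sorted(ls)[:3]}..."
            )
    return out


@dataclass
class AncestralStates:
    """Posterior codon distributions and MAP sequences for every node."""

    tree: dendropy.Tree
    node_labels: list
    #: label -> (n_sites, n_support) posterior over support codons
    posteriors: Mapping[str, np.ndarray]
    support_codons: list
    code: GeneticCode
    map_codons: Mapping[str, list]
    map_posterior: Mapping[str, np.ndarray]
    leaf_labels: frozenset

    def posterior(self, label: str, codon_site: int) -> dict:
        """Posterior over codons at a node and 1-based codon site."""
        row = self.posteriors[label][codon_site - 1]
        return {c: float(p) for c, p in zip(self.support_codons, row) if p > 0}

    def map_codon(self, label: str, codon_site: int) -> str:
        return self.map_codons[label][codon_site - 1]

    def map_sequence(self, label: str) -> str:
        return "".join(self.map_codons[label])

    def map_protein(self, label: str) -> str:
        return "".join(
            self.code.translate_codon(c) for c in self.map_codons[label]
        )


def marginal_ancestral(
    aln: CodonAlignment,
    species_tree: dendropy.Tree,
    fit: ModelFit,
    code: GeneticCode | None = None,
    use_fitted_lengths: bool = True,
) -> AncestralStates:
    """Marginal ancestral reconstruction under a fitted M0 model.

    The species tree is used as provided (typically rooted); it is never
    inferred here.  Posteriors at each node are proportional to the product
    of the partial likelihoods of all incident subtrees, weighted by the
    equilibrium frequencies.
    """
    if fit.omega is None:
        raise ModelError("ancestral reconstruction uses a single-omega (M0) fit")
    code = code or standard_code()
    tree = (
        transfer_branch_lengths(species_tree, fit)
        if use_fitted_lengths
        else species_tree.clone(depth=1)
    )
    label_internal_nodes(tree)
    engine = PruningEngine(aln, tree, fit.pi, code)
    idx = engine.idx
    t = np.array([idx.lengths0[i] for i in idx.edge_nodes], dtype=float)
    prop = Propagator(build_q(fit.kappa, fit.omega, fit.pi, code), fit.pi)
    edge_P = [prop.expm(te) for te in t]

    _, partials, _, subs = engine.site_loglikes(edge_P, return_partials=True)
    n_pat = engine.patterns.shape[1]
    m = engine.m
    pi_sub = engine.pi_sub

    # downward messages: for node c, D_c(s_parent) = sum_s P_c(s_parent, s) L_c(s)
    down_msg = [None] * len(idx.nodes)
    for i in idx.edge_nodes:
        sp = subs[idx.edge_of_node[i]]  # (m+1, m), row = child state
        if not idx.children[i]:
            down_msg[i] = sp[engine.patterns[idx.leaf_row[i]]]
        else:
            down_msg[i] = partials[i] @ sp[:-1]

    # outside pass: up[i](s_i) including pi at the root
    up = [None] * len(idx.nodes)
    up[idx.root] = np.tile(pi_sub, (n_pat, 1))
    parent_of = {}
    for p, kids in enumerate(idx.children):
        for c in kids:
            parent_of[c] = p
    order = [idx.index[id(nd)] for nd in idx.nodes[idx.root].preorder_iter()]
    for i in order:
        if i == idx.root:
            continue
        parent = parent_of[i]
        # parent's outside * messages from siblings
        acc = up[parent].copy()
        for c in idx.children[parent]:
            if c != i:
                acc *= down_msg[c]
        P = edge_P[idx.edge_of_node[i]][np.ix_(engine.support, engine.support)]
        msg = acc @ P  # sum over parent states
        s = msg.max(axis=1, keepdims=True)
        s[s == 0] = 1.0
        up[i] = msg / s

    support_codons = [code.sense_codons[k] for k in engine.support]
    posteriors = {}
    map_codons = {}
    map_post = {}
    node_labels = []
    n_sites = aln.n_codons
    s2p = engine.site_to_pattern
    for i, nd in enumerate(idx.nodes):
        label = (nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label)
        node_labels.append(label)
        if nd.is_leaf():
            obs = engine.patterns[idx.leaf_row[i]]  # support index or m
            post = np.zeros((n_pat, m))
            seen = obs < m
            post[np.flatnonzero(seen), obs[seen]] = 1.0
            if np.any(~seen):  # missing data: posterior from the outside pass
                miss = np.flatnonzero(~seen)
                w = up[i][miss]
                post[miss] = w / w.sum(axis=1, keepdims=True)
        else:
            w = up[i] * partials[i]
            tot = w.sum(axis=1, keepdims=True)
            if np.any(tot <= 0):
                pat = int(np.flatnonzero(tot.ravel() <= 0)[0])
                site = int(np.flatnonzero(s2p == pat)[0]) + 1
                raise AncestralError(f"zero posterior mass at codon site {site}")
            post = w / tot
        sites_post = post[s2p]
        posteriors[label] = sites_post
        best = sites_post.argmax(axis=1)
        map_codons[label] = [support_codons[k] for k in best]
        map_post[label] = sites_post[np.arange(n_sites), best]
    return AncestralStates(
        tree=tree,
        node_labels=node_labels,
        posteriors=posteriors,
        support_codons=support_codons,
        code=code,
        map_codons=map_codons,
        map_posterior=map_post,
        leaf_labels=frozenset(
            lf.taxon.label for lf in tree.leaf_node_iter()
        ),
    )


def map_sequences(anc: AncestralStates):
    """(codon sequences, protein sequences) per node label."""
    codons = {lab: anc.map_sequence(lab) for lab in anc.node_labels}
    prots = {lab: anc.map_protein(lab) for lab in anc.node_labels}
    return codons, prots
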