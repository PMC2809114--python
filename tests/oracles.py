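"""Independent reference implementations used only as test oracles.

Everything here is written straight from the defining formulas in plain
Python (no shared code with the package beyond the genetic-code table), so
the package's vectorised implementations can be checked against them.
"""

import itertools
import math

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
STOPS = set(_TABLE.stop_codons)
NTS = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def degeneracy(codon):
    """Fold class of each codon position by direct mutation enumeration."""
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        syn = sum(
            1
            for nt in NTS
            if nt != codon[pos]
            and CODON_TO_AA.get(codon[:pos] + nt + codon[pos + 1 :]) == aa
        )
        out.append(4 if syn == 3 else (0 if syn == 0 else 2))
    return tuple(out)


def lwl85(seq1, seq2):
    """LWL85 Ks/Ka from first principles.

    Returns dict with L, P, Q per class and Ks/Ka (None when undefined).
    Codons that are not sense codons in either sequence are skipped.
    """
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    ts = {0: 0.0, 2: 0.0, 4: 0.0}
    tv = {0: 0.0, 2: 0.0, 4: 0.0}
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k : k + 3], seq2[k : k + 3]
        if c1 not in CODON_TO_AA or c2 not in CODON_TO_AA:
            continue
        d1, d2 = degeneracy(c1), degeneracy(c2)
        for pos in range(3):
            L[d1[pos]] += 0.5
            L[d2[pos]] += 0.5
            a, b = c1[pos], c2[pos]
            if a != b:
                bucket = ts if (a, b) in TRANSITIONS else tv
                bucket[d1[pos]] += 0.5
                bucket[d2[pos]] += 0.5

    def k2p_parts(cls):
        if L[cls] == 0:
            return None, None
        P = ts[cls] / L[cls]
        Q = tv[cls] / L[cls]
        wa = 1.0 - 2.0 * P - Q
        wb = 1.0 - 2.0 * Q
        B = 0.5 * math.log(1.0 / wb) if wb > 0 else None
        A = (
            0.5 * math.log(1.0 / wa) - 0.25 * math.log(1.0 / wb)
            if (wa > 0 and wb > 0)
            else None
        )
        return A, B

    A0, B0 = k2p_parts(0)
    A2, B2 = k2p_parts(2)
    A4, B4 = k2p_parts(4)
    Ks = Ka = None
    ks_den = L[2] / 3.0 + L[4]
    ka_den = 2.0 * L[2] / 3.0 + L[0]
    if ks_den > 0:
        terms = 0.0
        ok = True
        if L[2] > 0:
            ok &= A2 is not None
            terms += L[2] * A2 if A2 is not None else 0.0
        if L[4] > 0:
            ok &= A4 is not None and B4 is not None
            terms += L[4] * (A4 + B4) if ok else 0.0
        if ok:
            Ks = terms / ks_den
    if ka_den > 0:
        terms = 0.0
        ok = True
        if L[2] > 0:
            ok &= B2 is not None
            terms += L[2] * B2 if B2 is not None else 0.0
        if L[0] > 0:
            ok &= A0 is not None and B0 is not None
            terms += L[0] * (A0 + B0) if ok else 0.0
        if ok:
            Ka = terms / ka_den
    return {"L": L, "ts": ts, "tv": tv, "Ks": Ks, "Ka": Ka}


def enumerate_tree_loglike(tree_spec, P, pi, leaf_states):
    """Site log-likelihood by explicit summation over internal-node states.

    ``tree_spec``: nested structure: a leaf is a string label; an internal
    node is a tuple of (child, branch_label) pairs.  ``P[branch_label]`` is
    the transition matrix for the edge above that child; ``pi`` is the root
    distribution; ``leaf_states`` maps leaf label -> observed state index.

    Internal nodes are enumerated explicitly (the root included), so this is
    exponential in the number of internal nodes and independent of the
    pruning recursion.
    """
    internals = []

    def collect(node):
        if isinstance(node, str):
            return
        internals.append(node)
        for child, _ in node:
            collect(child)

    collect(tree_spec)
    n_states = len(pi)
    total = 0.0
    for assignment in itertools.product(range(n_states), repeat=len(internals)):
        state_of = dict(zip(map(id, internals), assignment))

        def prob(node, parent_state):
            if isinstance(node, str):
                return 1.0  # leaf factors handled by the edge below
            p = 1.0
            s = state_of[id(node)]
            for child, blab in node:
                if isinstance(child, str):
                    p *= P[blab][s][leaf_states[child]]
                else:
                    p *= P[blab][s][state_of[id(child)]] * prob(child, s)
            return p

        root_state = state_of[id(tree_spec)]
        total += pi[root_state] * prob(tree_spec, None)
    return math.log(total)


def rf_bruteforce(splits1, splits2):
    """Symmetric-difference count of two split collections (pre-canonicalised)."""
    return len(set(splits1) ^ set(splits2))


def splits_of_newick(newick):
    """All non-trivial splits of a newick string by naive parsing with dendropy."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    leaves = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    ref = min(leaves)
    out = set()
    for nd in t.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = below if ref not in below else leaves - below
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out
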