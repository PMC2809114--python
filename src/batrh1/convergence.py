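"""Per-branch substitution events, parallel/convergent/reversal replacements,
site-exclusion topology scans and structural-domain mapping.

A branch is identified by its child node (leaf label or internal-node
label).  Events are inferred by comparing the MAP ancestral codon sequences
of parent and child at every site; a codon differing at more than one
nucleotide still counts as a single event, classified synonymous or
nonsynonymous by the amino-acid pair.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import yaml

from . import lwl85, treebuild
from .ancestral import AncestralStates
from .codonseq import CodonAlignment, GeneticCode, standard_code


@dataclass(frozen=True)
class SubstitutionEvent:
    """One inferred codon change on one branch."""

    branch: tuple  # (parent label, child label)
    codon_site: int  # 1-based alignment codon index
    reference_site: int  # codon_site + offset (reference numbering)
    parent_codon: str
    child_codon: str
    parent_aa: str
    child_aa: str

    @property
    def kind(self) -> str:
        return "synonymous" if self.parent_aa == self.child_aa else "nonsynonymous"


@dataclass
class ParallelGroup:
    """The same derived amino acid arising on >= 2 disjoint branches."""

    reference_site: int
    codon_site: int
    derived_aa: str
    branches: list  # child labels
    ancestral_aas: list

    @property
    def classification(self) -> str:
        return "parallel" if len(set(self.ancestral_aas)) == 1 else "convergent"


@dataclass
class Reversal:
    """An a->b replacement on an outer branch undone (b->a) on a branch
    strictly inside the outer branch's subtree."""

    reference_site: int
    codon_site: int
    outer_branch: str
    inner_branch: str
    aa_from: str
    aa_to: str


def _node_tables(tree: dendropy.Tree):
    """label -> leaf set below, for every node (branch = child label)."""
    leafsets = {}
    parents = {}
    for nd in tree.preorder_node_iter():
        label = nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label
        leafsets[label] = frozenset(
            lf.taxon.label for lf in nd.leaf_iter()
        )
        if nd.parent_node is not None:
            p = nd.parent_node
            parents[label] = p.taxon.label if p.is_leaf() and p.taxon else p.label
    return leafsets, parents


def enumerate_events(
    anc: AncestralStates,
    species_tree: dendropy.Tree | None = None,
    offset: int = 0,
):
    """All substitution events plus per-branch (N, S) counts.

    ``offset`` maps 1-based alignment codon sites to the reference
    (bovine-rhodopsin-style) numbering: reference_site = codon_site + offset.
    """
    tree = species_tree if species_tree is not None else anc.tree
    events = []
    counts = {}
    code = anc.code
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        child = nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label
        p = nd.parent_node
        parent = p.taxon.label if p.is_leaf() and p.taxon else p.label
        pseq = anc.map_codons[parent]
        cseq = anc.map_codons[child]
        N = S = 0
        for s, (pc, cc) in enumerate(zip(pseq, cseq), start=1):
            if pc == cc:
                continue
            ev = SubstitutionEvent(
                branch=(parent, child),
                codon_site=s,
                reference_site=s + offset,
                parent_codon=pc,
                child_codon=cc,
                parent_aa=code.translate_codon(pc),
                child_aa=code.translate_codon(cc),
            )
            events.append(ev)
            if ev.kind == "nonsynonymous":
                N += 1
            else:
                S += 1
        counts[child] = (N, S)
    return events, counts


def classify_shared(events: Sequence[SubstitutionEvent], tree: dendropy.Tree):
    """Group shared replacements into parallel/convergent groups and find
    reversals.

    Branches of a group must be pairwise disjoint (neither an ancestor of
    the other on the tree); sister branches are allowed.  Output is
    invariant to the order of the event list.
    """
    leafsets, _ = _node_tables(tree)

    def nested(b1, b2):
        l1, l2 = leafsets[b1], leafsets[b2]
        return l1 < l2 or l2 < l1

    nonsyn = sorted(
        (e for e in events if e.kind == "nonsynonymous"),
        key=lambda e: (e.codon_site, e.child_aa, -len(leafsets[e.branch[1]]), e.branch[1]),
    )
    by_key = defaultdict(list)
    for e in nonsyn:
        by_key[(e.codon_site, e.child_aa)].append(e)
    groups = []
    for (site, aa), evs in sorted(by_key.items()):
        kept = []
        for e in evs:  # greedy, larger clades first: keep pairwise disjoint set
            if all(not nested(e.branch[1], k.branch[1]) for k in kept):
                kept.append(e)
        if len(kept) >= 2:
            groups.append(
                ParallelGroup(
                    reference_site=kept[0].reference_site,
                    codon_site=site,
                    derived_aa=aa,
                    branches=[e.branch[1] for e in kept],
                    ancestral_aas=[e.parent_aa for e in kept],
                )
            )
    reversals = []
    by_site = defaultdict(list)
    for e in events:
        if e.kind == "nonsynonymous":
            by_site[e.codon_site].append(e)
    for site, evs in sorted(by_site.items()):
        for outer in evs:
            for inner in evs:
                if outer is inner:
                    continue
                if (
                    outer.parent_aa == inner.child_aa
                    and outer.child_aa == inner.parent_aa
                    and leafsets[inner.branch[1]] < leafsets[outer.branch[1]]
                ):
                    reversals.append(
                        Reversal(
                            reference_site=outer.reference_site,
                            codon_site=site,
                            outer_branch=outer.branch[1],
                            inner_branch=inner.branch[1],
                            aa_from=outer.parent_aa,
                            aa_to=outer.child_aa,
                        )
                    )
    return groups, reversals


@dataclass
class ExclusionResult:
    """One row of a site-exclusion scan."""

    excluded_sites: tuple
    tree: dendropy.Tree
    rf_to_reference: int
    clade_checks: Mapping[str, bool] = field(default_factory=dict)


def site_exclusion_scan(
    aln: CodonAlignment,
    reference_tree: dendropy.Tree,
    site_sets: Sequence[Iterable[int]],
    mode: str = "nt_k2p",
    code: GeneticCode | None = None,
    clade_checks: Mapping | None = None,
) -> list:
    """Rebuild the NJ tree after dropping codon-site sets; compare topologies.

    For each set of 1-based codon sites: drop those codon columns, rebuild
    the NJ tree under ``mode``, report the Robinson-Foulds distance to the
    reference tree and the configured clade checks
    (name -> (taxa, outgroup)).
    """
    code = code or standard_code()
    results = []
    for sites in site_sets:
        sites = tuple(sorted({int(s) for s in sites}))
        if len(sites) >= aln.n_codons:
            raise ValueError("cannot exclude every codon site")
        sub = aln.drop_codon_columns(sites) if sites else aln
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", lwl85.UndefinedDistanceWarning)
            dm = lwl85.distance_matrix(sub, mode, code)
        tree = treebuild.nj_tree(dm)
        rf = treebuild.rf_distance(tree, reference_tree)
        checks = {}
        for name, (taxa, outgroup) in (clade_checks or {}).items():
            checks[name] = treebuild.check_clade(tree, taxa, outgroup)
        results.append(ExclusionResult(sites, tree, rf, checks))
    return results


# ---------------------------------------------------------------------------
# structural domains


@dataclass
class DomainTable:
    """Ordered, non-overlapping reference-position intervals with labels in
    {transmembrane, intradiscal, cytoplasmic}."""

    intervals: list  # (start, end, label), inclusive bounds
    source: str = ""

    def __post_init__(self):
        ivs = sorted(self.intervals)
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError("domain intervals overlap")
        self.intervals = ivs

    def label_of(self, site: int) -> str | None:
        for s, e, lab in self.intervals:
            if s <= site <= e:
                return lab
        return None


def load_domain_table(path=None) -> DomainTable:
    """Load a domain table from YAML; default is the bundled approximate
    bovine-rhodopsin topology."""
    if path is None:
        ref = resources.files("batrh1").joinpath("data/rhodopsin_domains.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    ivs = [(int(d["start"]), int(d["end"]), str(d["label"])) for d in doc["intervals"]]
    return DomainTable(intervals=ivs, source=str(doc.get("source", path or "bundled")))


def map_to_domain(sites: Iterable[int], table: DomainTable):
    """Label each reference position; tally per label; report uncovered sites.

    Returns (labels: site -> label, tally: Counter, uncovered: sorted list).
    """
    labels = {}
    uncovered = []
    tally = Counter()
    for site in sites:
        lab = table.label_of(int(site))
        if lab is None:
            uncovered.append(int(site))
        else:
            labels[int(site)] = lab
            tally[lab] += 1
    return labels, tally, sorted(uncovered)
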