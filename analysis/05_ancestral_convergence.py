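#!/usr/bin/env python
"""Ancestral reconstruction and the convergence census.

Fits M0 on the species tree, reconstructs the codon sequence at every
internal node, enumerates the substitutions on each branch (N and S
counts), groups shared derived amino acids on disjoint branches into
parallel/convergent replacements, scans for reversals, and maps the
replacement sites onto the rhodopsin secondary-structure domains.
"""

import argparse
import warnings
from pathlib import Path

from batrh1 import synthetic_data as synth
from batrh1.ancestral import map_sequences, marginal_ancestral
from batrh1.codonmodel import fit_model
from batrh1.codonseq import read_alignment
from batrh1.convergence import (
    classify_shared,
    enumerate_events,
    load_domain_table,
    map_to_domain,
)
from batrh1.treebuild import read_newick

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fasta", type=Path,
                    default=ROOT / "results" / "fixture" / "rh1_fixture.fasta")
    ap.add_argument("--tree", type=Path,
                    default=ROOT / "results" / "fixture" / "species_tree.nwk")
    ap.add_argument("--offset", type=int, default=synth.FIXTURE_OFFSET)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "convergence")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    warnings.simplefilter("ignore")

    aln = read_alignment(args.fasta)
    sptree = read_newick(args.tree)
    fit = fit_model(aln, sptree, "M0", n_starts=1, seed=args.seed)
    print(f"M0 on species tree: omega = {fit.omega:.4f}, "
          f"kappa = {fit.kappa:.2f}")

    anc = marginal_ancestral(aln, sptree, fit)
    codons, prots = map_sequences(anc)
    with open(args.out / "ancestral_proteins.fasta", "w") as fh:
        for lab in anc.node_labels:
            fh.write(f">{lab}\n{prots[lab]}\n")

    events, counts = enumerate_events(anc, offset=args.offset)
    rows = ["branch\tN\tS"]
    rows += [f"{b}\t{n}\t{s}" for b, (n, s) in sorted(counts.items())]
    (args.out / "branch_counts.tsv").write_text("\n".join(rows) + "\n")
    n_tot = sum(n for n, _ in counts.values())
    s_tot = sum(s for _, s in counts.values())
    print(f"{len(events)} substitutions on the tree: {n_tot} nonsynonymous, "
          f"{s_tot} synonymous")

    groups, reversals = classify_shared(events, anc.tree)
    grows = ["reference_site\tderived_aa\tclassification\tbranches\tancestral_aas"]
    for g in groups:
        grows.append(f"{g.reference_site}\t{g.derived_aa}\t{g.classification}\t"
                     f"{','.join(g.branches)}\t{','.join(g.ancestral_aas)}")
        print(f"shared replacement at site {g.reference_site}: "
              f"{'/'.join(g.ancestral_aas)} -> {g.derived_aa} "
              f"({g.classification}) on {', '.join(g.branches)}")
    (args.out / "parallel_groups.tsv").write_text("\n".join(grows) + "\n")

    rrows = ["reference_site\touter_branch\tinner_branch\taa_from\taa_to"]
    for r in reversals:
        rrows.append(f"{r.reference_site}\t{r.outer_branch}\t{r.inner_branch}"
                     f"\t{r.aa_from}\t{r.aa_to}")
        print(f"reversal at site {r.reference_site}: {r.aa_from}->{r.aa_to} "
              f"on {r.outer_branch}, undone on {r.inner_branch}")
    (args.out / "reversals.tsv").write_text("\n".join(rrows) + "\n")
    if not reversals:
        print("no reversals detected")

    table = load_domain_table()
    sites = sorted({e.reference_site for e in events
                    if e.kind == "nonsynonymous"})
    labels, tally, uncovered = map_to_domain(sites, table)
    drows = ["label\tcount"]
    for lab in ("transmembrane", "intradiscal", "cytoplasmic"):
        drows.append(f"{lab}\t{tally.get(lab, 0)}")
    drows.append(f"uncovered\t{len(uncovered)}")
    (args.out / "domain_tally.tsv").write_text("\n".join(drows) + "\n")
    print(f"replacement sites by rhodopsin domain: "
          f"{dict(tally)} (uncovered: {len(uncovered)})")
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    main()
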