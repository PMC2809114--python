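#!/usr/bin/env python
"""Codon-model selection tests on the fixture: M0, branch models on the
fruit-bat stem, and the site-model pairs M1a/M2a and M8a/M8, with LRTs.

Produces a table of the same shape as a codeml selection analysis: model,
parameter count, log-likelihood, estimates; plus the LRT comparisons.
Under strong purifying selection none of the tests should indicate
positive selection.  Site models are run on a 12-taxon subset to keep the
mixture fits quick; the branch models use the full 23 taxa.
"""

import argparse
import warnings

import numpy as np
from pathlib import Path

from batrh1 import synthetic_data as synth
from batrh1.codonmodel import fit_model, lrt
from batrh1.codonseq import CodonAlignment, read_alignment
from batrh1.treebuild import read_newick

ROOT = Path(__file__).resolve().parent.parent


def subset(aln, tree, keep):
    keep = set(keep)
    taxa, seqs = [], []
    for t, s in zip(aln.taxa, aln.sequences):
        if t in keep:
            taxa.append(t)
            seqs.append(s)
    sub = CodonAlignment(taxa, seqs)
    t2 = tree.clone(depth=1)
    t2.retain_taxa_with_labels(list(keep))
    return sub, t2


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fasta", type=Path,
                    default=ROOT / "results" / "fixture" / "rh1_fixture.fasta")
    ap.add_argument("--tree", type=Path,
                    default=ROOT / "results" / "fixture" / "species_tree.nwk")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--starts", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "selection")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    warnings.simplefilter("ignore")

    aln = read_alignment(args.fasta)
    sptree = read_newick(args.tree)
    clades = synth.fixture_clades()

    rows = ["model\tn_params\tlnL\testimates"]
    fits = {}

    m0 = fit_model(aln, sptree, "M0", n_starts=args.starts, seed=args.seed)
    fits["M0"] = m0
    rows.append(f"M0\t{m0.n_params}\t{m0.lnL:.6f}\t"
                f"omega={m0.omega:.4f} kappa={m0.kappa:.4f}")
    print(f"M0: omega = {m0.omega:.4f} (strong purifying selection), "
          f"kappa = {m0.kappa:.2f}, lnL = {m0.lnL:.3f}")

    # branch models: foreground = the fruit-bat (megabat) stem
    fg = [frozenset(clades["pteropodidae"])]
    for name, fixed in (("two_ratio", None),
                        ("two_ratio", {"omega_fg": 1.0})):
        tag = "two_ratio" if fixed is None else "two_ratio_fg1"
        f = fit_model(aln, sptree, name, foreground_branches=fg,
                      fixed_params=fixed, n_starts=args.starts,
                      seed=args.seed, init=m0)
        fits[tag] = f
        om_fg = f.params.get("omega_fg", 1.0)
        rows.append(f"{tag}\t{f.n_params}\t{f.lnL:.6f}\t"
                    f"omega0={f.omega:.4f} omega_fg={om_fg:.4f}")

    # site models on a 12-taxon subset
    keep = (clades["pteropodidae"][:3] + clades["rhinolophoidea"][:3]
            + clades["miniopterus"][:2] + clades["yangochiroptera_other"][:3]
            + clades["tombbat"])
    sub_aln, sub_tree = subset(aln, sptree, keep)
    m1a = fit_model(sub_aln, sub_tree, "M1a", n_starts=args.starts,
                    seed=args.seed)
    m2a = fit_model(sub_aln, sub_tree, "M2a", n_starts=args.starts,
                    seed=args.seed, init=m1a)
    m8a = fit_model(sub_aln, sub_tree, "M8a", n_starts=args.starts,
                    seed=args.seed)
    m8 = fit_model(sub_aln, sub_tree, "M8", n_starts=args.starts,
                   seed=args.seed, init=m8a)
    for tag, f in (("M1a", m1a), ("M2a", m2a), ("M8a", m8a), ("M8", m8)):
        fits[tag] = f
        est = " ".join(
            f"p{i}={p:.4f}/w{i}={w:.4f}"
            for i, (p, w) in enumerate(zip(f.proportions, f.site_class_omegas))
        )
        rows.append(f"{tag}\t{f.n_params}\t{f.lnL:.6f}\t{est[:160]}")

    (args.out / "model_fits.tsv").write_text("\n".join(rows) + "\n")

    def positive_class(fit):
        """A rejection only indicates positive selection when the favoured
        omega actually exceeds 1 with non-negligible weight (a significant
        omega < 1 on the foreground is strong purifying selection)."""
        if fit.model_name == "two_ratio":
            return fit.params.get("omega_fg", 1.0) > 1.0
        if fit.site_class_omegas is not None:
            w = np.asarray(fit.site_class_omegas)
            p = np.asarray(fit.proportions)
            return bool(np.any((w > 1.0) & (p > 1e-4)))
        return False

    lrt_rows = ["null\talt\t2dlnL\tdf\tp_value\tpositive_selection"]
    for null, alt in (("two_ratio_fg1", "two_ratio"), ("M1a", "M2a"),
                      ("M8a", "M8")):
        r = lrt(fits[null], fits[alt])
        verdict = "yes" if (r.p_value < 0.05 and positive_class(fits[alt])) else "no"
        lrt_rows.append(f"{null}\t{alt}\t{r.two_delta_lnL:.4f}\t{r.df}\t"
                        f"{r.p_value:.4g}\t{verdict}")
        print(f"LRT {null} vs {alt}: 2dlnL = {r.two_delta_lnL:.3f}, "
              f"df = {r.df}, p = {r.p_value:.3g} -> positive selection: {verdict}")
    (args.out / "lrt.tsv").write_text("\n".join(lrt_rows) + "\n")
    print(f"tables in {args.out}")


if __name__ == "__main__":
    main()
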