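# batrh1 — molecular convergence in the bat dim-light vision gene

Bats are nocturnal, but their reliance on vision varies enormously: Old-World
fruit bats (Pteropodidae) navigate by sight, while most echolocating
microbats have reduced eyes — with conspicuous exceptions such as the tomb
bat.  The rod opsin gene *RH1*, which underlies dim-light vision, shows a
striking anomaly in this group: its gene tree unites the fruit bats with
Yangochiroptera instead of with their true relatives (Rhinolophoidea),
because a handful of amino-acid sites evolved the **same derived residue in
parallel** on independent branches.

This package re-implements that analysis end to end as a tested pipeline,
for molecular evolutionists who want to dissect gene-tree/species-tree
conflict into its synonymous and nonsynonymous components:

* **Codon alignments** — reading, validation, translation, summary
  statistics (`batrh1.codonseq`).
* **Partitioned distances** — Li–Wu–Luo (1985) synonymous (*Ks*) and
  nonsynonymous (*Ka*) distances with per-class Kimura two-parameter
  correction, plus Poisson amino-acid and K2P nucleotide distances
  (`batrh1.lwl85`).  Each codon position is a 0-fold, 2-fold or 4-fold
  degenerate site; 1/3 of 2-fold and all 4-fold sites are synonymous:

      Ks = (L2·A2 + L4·(A4+B4)) / (L2/3 + L4)
      Ka = (L2·B2 + L0·(A0+B0)) / (2·L2/3 + L0)

* **Trees** — deterministic Neighbor-Joining, codon-column bootstrap,
  Robinson–Foulds distances and clade queries (`batrh1.treebuild`).
* **Selection tests** — GY94 codon models (ω = dN/dS, κ, F3x4 frequencies)
  with Felsenstein-pruning likelihoods: M0, two-ratio, free-ratio, M1a/M2a,
  M8/M8a and branch-site model A, likelihood-ratio tests, and naive
  empirical-Bayes site posteriors (`batrh1.codonmodel`).
* **Ancestral sequences** — marginal ML reconstruction at every internal
  node of the species tree (`batrh1.ancestral`).
* **Convergence census** — per-branch N/S substitution counts,
  parallel/convergent/reversal classification of shared replacements,
  site-exclusion topology scans, and mapping of replacement sites onto the
  rhodopsin transmembrane/intradiscal/cytoplasmic domains
  (`batrh1.convergence`).
* **Synthetic data** — an exact (event-by-event) GY94 simulator with
  plantable parallel replacements and full ground-truth recording, including
  a 23-taxon, 278-codon bat-like fixture (`batrh1.synthetic_data`).

## Worked example

The `analysis/` scripts run the full study on the synthetic fixture; each
writes its tables under `results/`:

```
python analysis/01_simulate_fixture.py --seed 1
python analysis/02_alignment_stats.py
python analysis/03_partition_trees.py
python analysis/04_selection_models.py
python analysis/05_ancestral_convergence.py
python analysis/06_site_exclusion.py
```

With seed 1 this prints (abridged):

```
23 taxa; 834 nt sites; 203 variable; 17 change the amino acid
       syn: RF to species tree =  0; fruit bats group with tomb bat: False
    nonsyn: RF to species tree = 14; fruit bats group with tomb bat: True
M0 on species tree: omega = 0.0210, kappa = 3.79
shared replacement at site 104: V/V -> I (parallel) on rhino_stem, minio_stem
shared replacement at site 183: M/M -> L (parallel) on rhino_stem, minio_stem
shared replacement at site 270: G/G -> S (parallel) on yango_rad, rhino_stem
 nonsyn excluding  none: RF = 14; fruit bats with tomb bat: True
 nonsyn excluding   270: RF = 14; fruit bats with tomb bat: False; Yinpterochiroptera: True
```

Reading: of 834 aligned nucleotides only 17 sites change the protein, and
the fitted ω ≈ 0.02 confirms strong purifying selection.  Synonymous sites
recover the species tree exactly (RF = 0) while nonsynonymous sites unite
the fruit bats with the tomb bat — the planted convergence.  The census
finds a shared replacement at each planted site (at site 270 the
reconstruction reports the mirror polarity G→S on the complementary
branches, an inherent ambiguity of root-symmetric reconstruction without an
outgroup; see `docs/methods.md`).  Excluding site 270 alone dissolves the
false clade and restores Yinpterochiroptera.

The same stages are available as a CLI (`batrh1 stats|trees|fit|ancestors|
convergence|exclude|simulate|all`) for user-supplied FASTA/Newick inputs.

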