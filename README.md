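# nsltpkit

Sequence–structure–function analysis toolkit for the plant non-specific
lipid transfer protein (nsLTP) superfamily.

Plant nsLTPs are small secreted proteins built on a conserved scaffold of
eight cysteines, the 8CM motif `C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C`, forming four
disulfide bridges around a hydrophobic ligand cavity.  The family is highly
divergent in sequence but conserved in fold, which makes it a natural target
for statistics that separate *globally conserved* positions (the structural
core) from *subfamily-specific* positions (candidate determinants of
function).  This package implements that analysis chain for researchers
studying protein families from Python:

* **`seqdef`** — strict family-membership filtering: precursor length within
  60–150 residues, exactly eight cysteines, the 8CM arrangement; plus the
  CXC fold hint (hydrophilic central residue → type I fold, apolar → type II).
* **`msa`** — alignment model, most-frequent-residue consensus with the
  majority-gap rule (a column becomes a gap only when *more than half* of the
  sequences are deleted there), and column↔residue-number mapping.
* **`fast`** — per-column clade-specificity and conservation.  For symbol
  cluster `A(a(i), i)` (the sequences sharing residue `a` at column `i`), the
  specificity score is `-log10 FP`, where `FP` is the smallest one-sided
  Fisher (hypergeometric upper-tail) probability of the cluster's overlap
  with any monophyletic group of the guide tree.  Conservation is
  `1 - H/ln 21` with `H` the Shannon entropy over 20 amino acids + gap.
  Both render into an HSV-coloured alignment (hue = tree position of the
  cluster's median member, saturation = specificity, darkness = conservation)
  exported as SVG/TSV.
* **`structclass`** — Kabsch least-squares superposition and RMSD over
  residue correspondences, pairwise RMSD matrices, neighbor-joining distance
  trees, complete-linkage cutoff clustering (default sweep 11.5 → 0.5 Å, so
  every member pair of a cluster is within the cutoff), medoid
  representatives, and keyword-annotation enrichment per cluster.
* **`trace`** — real-valued evolutionary trace:
  `rho_i = 1 + sum_{n=1}^{N-1} (1/n) sum_g H(g, i)`, the partitions obtained
  by cutting the grouping tree below its `n-1` highest nodes.  Invariant
  columns score exactly 1.  Residues of a reference structure are ranked
  with tie-aware ranks, coverage and variability strings, and traces of
  different structural clusters are compared at shared alignment positions.
* **`synth`** — generators for all of the above with planted ground truth:
  SDP alignments, helix-bundle structure families, annotation tables.

## Worked example

```sh
python examples/trace_ranking.py
```

prints the head of a trace over a 43-sequence alignment whose reference has
90 residues:

```
 Rank  Residue number  Alignment position Residue  Coverage Variability  rvET score
    1               1                   0       C   0.10000           C        1.00
    ...eight more rank-1 rows...
   10              10                   9       A   0.13333          VA        1.66
   10              11                  10       S   0.13333          GS        1.66
   10              12                  11       V   0.13333          IV        1.66
   13              13                  12       F   0.14444         LFY        2.66

top-30% of 90 residues -> 27 selected
```

The nine invariant columns (the eight cysteines of the scaffold plus one
invariant aspartate) score exactly 1.00, share rank 1, and jointly cover
9/90 = 0.10000 of the reference; the next three-way tied block covers
12/90 = 0.13333; the 30% rule selects 27 residues.  Other capabilities have
their own narrative scripts under `examples/` (membership filtering,
consensus + SDP scanning, structure clustering with enrichment).

A thin CLI wraps the same functions:

```sh
nsltp synth --outdir fixtures --seed 1
nsltp fast fixtures/alignment.fasta --tree fixtures/tree.nwk --outdir fast_out
nsltp trace fixtures/alignment.fasta --reference c0s0
```

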