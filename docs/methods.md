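# Methods

This note documents the models and procedures implemented by nsltpkit, the
parameters that matter, the numerical choices made where conventions differ,
and what the synthetic generators do and do not emulate.

## Family membership and the 8CM motif

A candidate mature sequence passes the family filter when three rules hold:

1. **length_bounds** — the precursor (mature chain + signal peptide) is
   60–150 residues long.  The toolkit operates on mature sequences, so the
   precursor length is an optional annotation; when absent the rule is
   skipped and reported as not evaluated rather than silently passed.
2. **cys_count** — the mature chain contains exactly eight cysteines.
3. **pattern** — those cysteines form `C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C`:
   the 3rd/4th cysteines adjacent, the 5th/6th separated by exactly one
   residue, and every other spacer non-empty.

The minimum spacer length `n >= 1` is a configurable default (`min_spacer`).
The motif notation leaves the spacer bounds open, but the CC and CXC groups
are explicitly distinguished from separated cysteines, so allowing
zero-length spacers elsewhere would create ambiguous double patterns.
Terminal cysteines at either sequence end are allowed; no flanking-residue
requirement exists.  The CXC fold hint classifies the single residue between
the 5th and 6th cysteines: hydrophilic (S T N Q D E K R H) suggests the
type I fold, where that residue is solvent-exposed; apolar (A V L I F M W)
suggests the type II fold, where it is buried toward the ligand cavity;
G P C Y are left indeterminate.  The class membership is configuration, not
biology carved in stone: the hydrophilic/apolar dichotomy is the family
observation, the exact sets are defaults.

## Consensus

Per column, the consensus symbol is the most frequent amino acid with gaps
excluded from the vote; the consensus becomes a gap only when *more than
half* of the sequences carry a deletion (exactly half is not enough).  Ties
among equally frequent amino acids break alphabetically — the data give no
reason to prefer one residue, so the choice is made deterministic and
documented.  Subsetting an alignment never re-compacts columns: column
indices must remain comparable across sub-alignments extracted from one
master alignment, which is what makes cross-cluster trace comparison by
alignment position meaningful.

## Clade specificity (FAST)

At column `i`, the cluster of symbol `a` is the set of sequences carrying
`a` there — identity grouping; a physicochemical grouping can be supplied
via `symbol_classes`.  The gap counts as a 21st symbol and forms clusters
like any residue (deletions can be clade-specific).  For each monophyletic
group `C` of the guide tree (one clade per internal node, excluding
singletons and the full leaf set), the overlap `k` of the cluster (size `n`)
with `C` (size `K`) in `N` sequences is scored by the one-sided
hypergeometric upper tail `P(X >= k)` — the Fisher exact enrichment
probability.  The cell's specificity is the *minimum* over clades (the
enrichment direction is the only one under which "lowest probability"
semantics make sense), ties broken by smaller clade then tree pre-order, and
the score is `-log10 p`.  No multiple-testing correction is applied: the
p-values are ranking scores, not inferential claims, and correcting them
would only rescale the ranking.

Conservation is `1 - H/ln 21` with `H` the natural-log Shannon entropy of
the 21-symbol column distribution: 1 for invariant columns, 0 for a column
uniform over the full alphabet.  The formula is a strategy option
(`column_conservation`); majority frequency would be a drop-in alternative.

Colouring: sequences ordered by the guide tree get base hues spanning 270°
(red → violet); a cell inherits the base hue of the *median* member of its
symbol cluster in tree order (lower median on even counts — "median by tree
order" is the chosen reading of the median-sequence rule), saturation is
`min(1, score/cap)` with the cap defaulting to the 99th percentile of
observed scores, and value is `1 - 0.8 * conservation` (floor 0.2), so
conserved columns render dark and clade-specific clusters render saturated.
All three constants (hue span, value floor, cap percentile) are arguments.

## Structural classification

Superposition is the closed-form Kabsch solution: centroid alignment, SVD of
the cross-covariance of the paired atoms, reflection corrected to a proper
rotation (det +1).  At least three non-collinear pairs are required.
Residue correspondences are *inputs* (TSV, or derived from the shared
non-gap columns of a structure-based alignment); sequence-independent
structure matching is deliberately out of scope — the data flow consumes a
precomputed structural alignment, and all supplied pairs are used.

The pairwise RMSD matrix feeds two consumers:

* a neighbor-joining distance tree (via dendropy) for display.  NJ is exact
  on additive matrices — leaf-to-leaf path lengths reproduce the input to
  numerical precision — which is the property the tests pin down; it stands
  in for balanced minimum evolution, whose output plays the same
  visual-clustering role.
* complete-linkage agglomerative clustering cut at a distance cutoff.  This
  operationalises "sub-tree whose members are all within the cutoff":
  complete linkage is the linkage whose merge height *is* the maximum
  pairwise distance, so every cluster satisfies the guarantee by
  construction.  Merges proceed by smallest linkage distance with
  lexicographic tie-breaking; the default sweep runs 11.5 Å (one cluster
  containing everything, for typical fold families) down to 0.5 Å in 0.5 Å
  steps.  Cutting the NJ tree instead is possible but the matrix-based
  partition is the primary strategy because its guarantee is exact.

Each cluster is represented by its **medoid**, the member minimising the
summed RMSD to all other members (ties lexicographic).  Annotation
enrichment reports, per cluster and keyword list: size, annotated member
count, the annotated fraction of the cluster, and the fraction of all
annotated ids captured by the cluster.  Fractions are reported exactly;
rounding (e.g. to integer percent) is left to presentation.

## Real-valued evolutionary trace

The grouping tree defaults to a UPGMA tree on pairwise fractional-mismatch
distances over shared non-gap columns (lexicographic tie-breaking, equal
leaf depths); a user-supplied rooted tree — e.g. the family phylogeny —
overrides it.  Internal nodes are ordered by height (maximal distance to a
descendant leaf; missing edge lengths default to 1; ties broken by
pre-order) and dissolved from the top.  Each partition into `n <= N-1`
groups contributes `(1/n) * sum_g H(g, i)` to column `i`'s score, `H` again
the natural-log 21-state entropy, and the score is 1 plus the sum.  An
invariant column therefore scores exactly 1 — the anchor that fixes both the
entropy base and the weighting.  On a binary tree this is the exact
`n = 1..N-1` schedule; a multifurcating node adds several groups in one
step, and the skipped group counts simply contribute nothing.

Ranking: residues of the reference sequence sort by ascending score; exact
ties share the minimal rank of their block; coverage is
`#(score <= own)/L`.  Scores are held exact internally and rounded only for
display (2 decimals for scores, 5 for coverage).  Two residues may display
the same rounded score yet hold distinct ranks — that is the intended
behaviour of min-rank-on-*exact*-ties, and matches trace tables in which
equal printed scores carry consecutive ranks.  The top-fraction rule selects
`round(fraction * L)` residues (banker's rounding), boundary ties resolved
by score then residue number.  Cross-cluster comparison matches rows by
alignment position; positions missing from another cluster's trace (gapped
reference there) are flagged as missing rather than silently dropped.

## Synthetic generators

All generators are pure functions of parameters and seed.

* `make_sdp_alignment` — uniform random background over the 20 amino acids,
  planted invariant columns, and SDP columns in which every clade receives
  its own fixed symbol.  Defaults (2 clades of 4, 60 columns, 5 SDPs,
  10 conserved, noise 0) make a perfectly clade-specific cluster reach the
  hypergeometric floor 1/70 per column.  Uniform background is a deliberate
  simplification: no substitution-matrix realism, no indel process, no
  phylogenetic autocorrelation in the background.  Passing tests on these
  fixtures shows the *statistics* behave as designed, not that real nsLTP
  alignments are this clean.
* `make_helix_bundle` — a common helical CA trace (2.3 Å radius, 1.5 Å
  rise), cluster-specific rigid displacement of the middle third of residues
  (`between_shift`, default 5 Å — comfortably above intra-family structural
  noise), and per-member isotropic jitter (`within_sigma`, default 0.3 Å).
  Intra-cluster RMSD scales like `sigma * sqrt(6)`; the planted partition is
  recoverable by any cutoff between the two scales (the tests use 1.5 Å,
  a typical tight-cluster cutoff for fold families).
* `make_annotations` — samples exactly the requested number of annotated ids
  inside and outside a target cluster, emulating sparse curated keyword
  tables.
* `make_trace_benchmark` — a deterministic 43-sequence, 90-column, gapless
  alignment with a caterpillar grouping tree, engineered so the trace
  exhibits a controlled tie structure: nine invariant columns (eight
  cysteine-like, one aspartate-like — the family's conserved scaffold
  pattern), three columns with one identical single-divergence pattern (an
  exact three-way tie), and 78 background columns with pairwise distinct
  two-symbol divergence compositions, so background scores are distinct and
  the residue at rank 27 is untied.  The sizes mirror a small, tightly
  annotated structural cluster (43 members) traced over a 90-residue
  reference.

## Problem sizes and determinism

Tests and the acceptance script run on the generator defaults above
(alignments up to 43×90, bundles of 8 structures × 40 residues, enrichment
universes of ~450 ids) — sizes at which every oracle (exhaustive
hypergeometric enumeration, rotation-search superposition, brute-force
medoids) is itself computable, which is the point of desk-scale validation.
All randomness flows through `numpy.random.default_rng(seed)`; hypothesis
profiles are seeded by the harness.  Workflow runs can write a manifest
(tool version, configuration, input digests) so identical inputs reproduce
identical outputs.

## Known limitations

* Membership filtering cannot evaluate the precursor-length rule without the
  precursor annotation (signal-peptide prediction is out of scope).
* Correspondences must be supplied; there is no structure-matching search,
  so the RMSD between two structures is conditional on the given pairing.
* The synthetic background is uniform and i.i.d.; real families carry
  phylogenetic correlation that inflates apparent specificity, so thresholds
  tuned on fixtures are not transferable to real data without calibration.
* Trace scores depend on the grouping tree; with the default identity-based
  UPGMA tree, clusters of near-identical sequences produce many zero-height
  ties, resolved deterministically (pre-order) but not uniquely — an
  alternative tree can reorder mid-table ranks.
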