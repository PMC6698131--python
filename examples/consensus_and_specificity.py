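"""Consensus building and clade-specificity scanning on a planted alignment.

Generates an alignment of two 4-sequence clades with planted conserved
columns and specificity-determining positions (SDPs), builds the
most-frequent-residue consensus, and scans every column for clade-specific
residue clusters with the one-sided Fisher (hypergeometric) test.
"""

from nsltpkit import fast, msa, synth

aln, tree, truth = synth.make_sdp_alignment(
    n_clades=2, seqs_per_clade=4, n_columns=30, n_sdp=3, n_conserved=5, seed=42
)
print("consensus:", msa.build_consensus(aln).symbols)
print("planted conserved columns:", truth.conserved_columns)
print("planted SDPs (column, clade, symbol):", truth.sdp_columns)
print()

clades = fast.enumerate_tree_clusters(tree, aln.ids)
cells = fast.specificity_table(aln, clades)
cons = fast.conservation_profile(aln)
core, sdp = fast.report_positions(
    cells, cons, conservation_threshold=1.0, specificity_threshold=1.5
)
print("conserved core columns:", sorted(core["column"]))
print()
print("SDP table (spec_score = -log10 of the best Fisher p):")
print(sdp.to_string(index=False))
print()
print("With 4-vs-4 clades a perfectly clade-specific symbol reaches")
print("p = 1/70 ~ 0.0143, i.e. spec_score ~ 1.845; both planted clusters")
print("of each SDP column (one per clade) reach that floor.")
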