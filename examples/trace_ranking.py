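"""Real-valued evolutionary-trace ranking with tie-aware coverage.

Uses the deterministic 43-sequence, 90-residue benchmark alignment whose
grouping tree is a caterpillar: nine invariant columns (eight cysteine-like
plus one aspartate-like) score exactly 1.00 and share rank 1 at coverage
0.10000; three identically-varying columns tie at rank 10 (coverage
0.13333); the untied residue at rank 27 sits at coverage 0.30000, and the
top-30% rule selects exactly 27 residues.
"""

from nsltpkit import synth, trace

aln, tree = synth.make_trace_benchmark(n_seqs=43, n_residues=90)
scores = trace.rvet_scores(aln, tree)
result = trace.rank_coverage(aln, aln.ids[0], scores)

print(result.to_dataframe().head(14).to_string(index=False))
top = trace.top_fraction(result, 0.30)
print(f"\ntop-30% of {result.length} residues -> {len(top)} selected")
print("lowest rvET score = most conserved; coverage is the fraction of")
print("reference residues scoring at or below the row's score.")
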