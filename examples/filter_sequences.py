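"""Family-membership filtering on the eight-cysteine motif.

Builds three candidate mature sequences, applies the three membership
criteria (precursor length 60-150, exactly eight cysteines, 8CM pattern),
and prints the report table.  The fold hint comes from the chemistry of the
residue between the 5th and 6th cysteines: hydrophilic points to the type I
fold, apolar to type II.
"""

from nsltpkit.seqdef import MatureSequence, filter_report

candidates = [
    # a compact valid scaffold: C.C..CC..CXC..C..C with hydrophilic X
    MatureSequence("candidate_ok", "AACLDCAKLCCDNACSCAPKACDLAC", precursor_length=100),
    # nine cysteines: fails the strict count criterion
    MatureSequence("nine_cys", "CACACCACACACACAC", precursor_length=100),
    # valid motif but too-short precursor
    MatureSequence("short_precursor", "CACACCACACACAC", precursor_length=55),
]

report = filter_report(candidates)
print(report.to_string(index=False))
print()
print("passed = all three criteria hold; reasons name the failing rules;")
print("fold_hint classifies the CXC central residue (here S -> type1_like).")
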