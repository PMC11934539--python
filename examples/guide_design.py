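"""Enumerate and filter SpCas9 guide candidates on a synthetic locus.

All 20-nt spacers next to an NGG PAM are listed on both strands, then
filtered: GC must be 30-70%, the spacer must have no self-pairing stem of
4+ nt, and no other genomic NGG site may lie within 1 mismatch of the
spacer.  Surviving guides are then off-target-scanned up to 3 mismatches,
the report a screening experiment would review.
"""

from ispcr.fixtures import FixtureSpec, make_locus
from ispcr.guides import enumerate_guides, filter_guides, scan_offtargets

template, planted = make_locus(FixtureSpec(seed=7, locus_length=3000, planted_guides=2))
cands = enumerate_guides(template)
passing, reasons = filter_guides(cands, [template])

print(f"template {template.id}: {template.length} bp, {len(cands)} NGG candidates")
print(f"{len(passing)} pass the default filters "
      f"(GC 30-70%, no self-complementarity, no 1-mismatch near-site)")
from collections import Counter

for reason, n in Counter(reasons.values()).most_common():
    print(f"  rejected {n:4d} for {reason}")
g = passing[0]
hits = scan_offtargets(g.spacer, [template], max_mm=3)
print(f"example guide {g.spacer} ({g.strand} strand, cut after base {g.cut_site}): "
      f"{len(hits)} genomic site(s) within 3 mismatches (1 expected: its own target)")
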