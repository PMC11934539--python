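"""Design an indel-selective PCR assay for a single-base insertion.

Builds a synthetic 900-bp locus carrying a clean-context single-base indel,
designs the primer trio (wild-type-specific, mutant-specific, common), and
prints the assay sheet.  The two allele primers differ only around the
indel, which sits 3 nt from their 3' ends; each shows 3 terminal mismatches
against the wrong allele, which is what blocks extension and makes the
assay allele-selective.
"""

from ispcr.design import design_assay
from ispcr.fixtures import make_clean_indel_locus

wt, edit = make_clean_indel_locus(seed=0)
assay = design_assay(wt, edit)

print(f"locus {edit.target_id}: {edit.label} at position {edit.pos} "
      f"(REF {edit.ref_allele} -> ALT {edit.alt_allele})")
print(f"orientation: {assay.orientation}")
for name, primer in (("WT-specific", assay.wt_primer), ("mut-specific", assay.mut_primer)):
    print(f"{name:12s} 5'-{primer.sequence}-3'  Tm {primer.physical.tm_celsius:5.2f} C  "
          f"GC {primer.physical.gc_percent:4.1f}%  terminal mismatches vs other allele: "
          f"{primer.terminal_mismatches_vs_other}")
cp = assay.common_primer
print(f"{'common':12s} 5'-{cp.sequence}-3'  Tm {cp.physical.tm_celsius:5.2f} C  strand {cp.strand}")
print(f"expected products: WT tube {assay.wt_amplicon_bp} bp, mutant tube {assay.mut_amplicon_bp} bp")
print("the 1-bp size difference is invisible on a gel; zygosity is read from "
      "which tube(s) amplify, not from product size")
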