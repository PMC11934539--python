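"""Simulate the two-tube gel readout for the three possible genotypes.

Runs the designed assay through virtual PCR on a homozygous wild type, a
heterozygote (both alleles in the template mix) and a homozygous mutant.
The band pattern — which of the two tubes shows a product — is the
genotype call.
"""

from ispcr.design import design_assay
from ispcr.fixtures import make_clean_indel_locus
from ispcr.insilico import predict_assay_bands
from ispcr.seqio import apply_edit

wt, edit = make_clean_indel_locus(seed=0)
assay = design_assay(wt, edit)
mut = apply_edit(wt, assay.locus)

for genotype, alleles in (("hom. wild type", [wt]), ("heterozygote", [wt, mut]),
                          ("hom. mutant", [mut])):
    table = predict_assay_bands(assay, alleles)
    bands = table.groupby("sub_assay")["amplifies"].any()
    wt_lane = "band" if bands["wild_type"] else "  - "
    mut_lane = "band" if bands["mutant"] else "  - "
    print(f"{genotype:15s} WT tube: {wt_lane}   mutant tube: {mut_lane}")
print("a band in only one tube is a homozygote; bands in both tubes mean "
      "the sample carries both alleles (heterozygous)")
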