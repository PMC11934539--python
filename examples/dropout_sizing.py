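"""Size a two-guide drop-out deletion from cut-site geometry.

Uses the built-in drop-out locus: a PCR assay whose wild-type product is
900 bp spans two SpCas9 cut sites 40 bp apart.  When both guides cut and
the ends re-join, the intervening 40 bp are lost, so the edited allele
amplifies 40 bp shorter — a size shift easily read on an agarose gel.
"""

from ispcr.fixtures import make_dropout_locus
from ispcr.guides import predict_dropout
from ispcr.insilico import virtual_pcr

fx = make_dropout_locus(seed=1)
pred = predict_dropout(fx.guide_a, fx.guide_b, fx.fwd_start, fx.rev_end)
print(f"guide A cuts after base {fx.guide_a.cut_site}, guide B after base {fx.guide_b.cut_site}")
print(f"predicted deletion: {pred.deletion_bp} bp")
print(f"wild-type product {pred.wt_amplicon_bp} bp -> edited product {pred.edited_amplicon_bp} bp")

wt = virtual_pcr(fx.fwd_primer, fx.rev_primer, fx.template)[0].size_bp
ed = virtual_pcr(fx.fwd_primer, fx.rev_primer, fx.dropout_allele)[0].size_bp
print(f"virtual PCR confirms: {wt} bp on wild type, {ed} bp on the drop-out allele")
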