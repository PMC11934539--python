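# ispcr — indel-selective PCR assay design for CRISPR genotyping

CRISPR/Cas9 editing of plant genomes mostly produces single-base insertions
or deletions at the cut site. Screening the large segregating populations
that follow (hundreds to thousands of plants) by Sanger sequencing is slow
and expensive; a plain PCR cannot see a 1-bp change on an agarose gel.
**Indel-selective PCR (IS-PCR)** solves this with allele-specific primers:
the single-base indel is placed **three nucleotides from the 3′ end** of
each allele-specific primer, so the primer perfectly matches its own allele
but presents three 3′-terminal mismatches against the other allele — the
indel itself plus the two register-shifted bases. Three terminal mismatches
prevent polymerase extension even when the rest of the primer anneals, so
each tube amplifies only one allele. With a common opposing primer shared
by both tubes, band presence reads out zygosity directly:

| WT tube | mutant tube | call |
|---|---|---|
| band | – | homozygous reference |
| – | band | homozygous edited |
| band | band | heterozygous |
| – | – | no amplification |

`ispcr` is a library (plus a thin CLI) for designing and validating these
assays end to end:

- **seqio** — FASTA/TSV/VCF-subset I/O, VCF-style left-alignment of indels
  (placement inside a repeat run is ambiguous until normalized), mutant
  allele construction with coordinate maps.
- **thermo** — GC content, unified nearest-neighbor melting temperature
  (Allawi & SantaLucia parameters, monovalent-salt correction), and a
  self-complementarity stem count used as a hairpin/homodimer proxy.
- **design** — the IS-PCR core: allele-specific primer placement at the
  −3 rule, terminal-mismatch verification over every equivalent indel
  placement, reverse-orientation fallback when the forward strand cannot
  discriminate, and common-primer selection (18–22 nt, Tm 52–60 °C,
  target 58 °C, 250–600 bp products by default).
- **insilico** — virtual PCR: binding-site search with a binary extension
  rule (3′-terminal 3 bases perfect, ≤ 2 internal mismatches), amplicon
  prediction, and two-tube gel simulation.
- **genotype** — the zygosity truth table above, batch calling, per-locus
  counts and chi-square segregation statistics.
- **guides** — SpCas9 guide enumeration (20-nt spacer + NGG), GC /
  self-complementarity / off-target filters with a paralog allowlist,
  exhaustive Hamming off-target scanning, and drop-out deletion sizing
  from blunt cut sites (3 bp 5′ of the PAM).
- **fixtures** — seeded generators for loci, indel alleles, a 900-bp
  drop-out locus and whole genotyping campaigns with known truth.

## Worked example

```sh
python examples/design_assay.py
```

```
locus locus_seed0: -1C at position 319 (REF AC -> ALT A)
orientation: forward
WT-specific  5'-GTAGGCGAAGACACCTGACAC-3'  Tm 57.01 C  GC 57.1%  terminal mismatches vs other allele: 3
mut-specific 5'-GTAGGCGAAGACACCTGAACG-3'  Tm 57.36 C  GC 57.1%  terminal mismatches vs other allele: 3
common       5'-TTCTGGTCGATTGCAATCCGC-3'  Tm 57.93 C  strand -
expected products: WT tube 420 bp, mutant tube 419 bp
```

The two allele primers are identical up to the indel neighborhood; the
terminal-mismatch count of 3 against the wrong allele is the selectivity
guarantee, and the ~420-bp products are sized for easy gel visualization.
Zygosity is read from which tubes amplify, not from product size.

Other examples, one per capability: `virtual_gel.py` (two-tube readout for
the three genotypes), `dropout_sizing.py` (a 40-bp two-guide deletion turns
a 900-bp product into 860 bp), `guide_design.py` (guide filtering and
off-target report), `genotyping_campaign.py` (400-plant screen, chi-square
vs 1:2:1, 100% concordance on readable lanes).

The same workflows are available as a CLI:
`ispcr design|validate|genotype|guides|dropout|fixtures` (see `--help`;
every run writes a provenance JSON with inputs, config hash and seed).

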