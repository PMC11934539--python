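# Methods

## The assay model

An indel-selective PCR assay genotypes one single-base indel (|Δ| = 1 bp)
with three primers. The two allele-specific primers are substrings of their
own allele whose 3′ terminus sits exactly `indel_offset` (default 3) bases
past the indel: position −3 carries the indel itself and, because a 1-bp
indel shifts the register of everything downstream, positions −2 and −1
mismatch the other allele wherever adjacent template bases differ. In a
repeat-free context this yields exactly 3 terminal mismatches in each
direction; the model assumes — and the virtual-PCR engine encodes — that
three 3′-terminal mismatches abolish polymerase extension while distal
mismatches merely destabilize annealing.

Two consequences of the register-shift mechanism shape the design space:

1. **Repeat runs cap selectivity.** A shifted window mismatches at offset
   *i* only where base *i* differs from base *i+1*. An indel inside or next
   to a homopolymer run therefore cannot reach 3 terminal mismatches at
   every placement, and some contexts (run flanked by repeats on both
   sides) cannot reach 3 in either orientation at all.
2. **Placement is ambiguous inside runs.** All equivalent indel placements
   produce the same mutant molecule but different terminal-mismatch
   patterns. The designer enumerates every equivalent placement (by direct
   string equality against the mutant sequence) in both the forward frame
   and the reverse-complement frame, scores each candidate pair by the
   min-over-alleles terminal mismatch count, and keeps the best; ties are
   broken by Tm closeness to the target. Note this means a locus whose
   forward placements top out at 2 mismatches can still be rescued by a
   right-aligned placement in the reverse frame — the orientation fallback
   is per-placement, not merely per-strand.

Edits are stored VCF-style (anchored REF/ALT) and left-aligned before
design; left-alignment is what makes "the indel position" well defined.
Coordinates are 1-based inclusive in all user-facing records, 0-based
half-open internally.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| primer length | 18–22 | nt | standard assay practice for this method |
| Tm window / target | 52–60 / 58 | °C | the annealing regime the assay runs at; 58 °C works best in hand |
| indel offset | 3 | nt from 3′ end | the core placement rule |
| min terminal mismatches | 3 | count in 3-nt window | the extension-blocking threshold; configurable down to 2 for repeat-context loci that provably cannot reach 3 |
| common-primer ΔTm | ≤ 3 | °C vs allele primers | keeps both tubes runnable in one program |
| amplicon window | 250–600 | bp | easy agarose resolution |
| virtual-PCR stringency | 3 terminal perfect, ≤ 2 internal mm, ≤ 5 kb | — | binary encoding of the extension rule |
| guide filters | GC 30–70%, self-comp 0, no site ≤ 1 mm | — | screening-grade guide quality with a paralog allowlist |
| off-target report cap | 3 | mismatches | the depth a screening report reviews |
| cut site | 3 | bp 5′ of PAM | blunt SpCas9 cut; drop-out arithmetic presumes a definite position |

Both allele primers of a pair share one length, chosen to minimize the
larger of their two deviations from the Tm target: their 3′ ends are
homologous, so sharing the 5′ extension keeps the two tubes thermally
matched and makes the mutant−wild-type product size difference exactly the
edit's Δ.

## Melting temperature

Unified nearest-neighbor model (Allawi & SantaLucia 1997 duplex
parameters with terminal initiation terms), monovalent-salt entropy
correction 0.368·(N−1)·ln[Na⁺], duplex concentration term R·ln(C_T/4);
defaults 50 mM monovalent, 250 nM primer. The implementation is
cross-checked in the test suite against an independent evaluation of the
same published table (biopython's `Tm_NN` with matched conventions) to
10⁻⁶ °C. "Self-complementarity" is operationalized as the count of
ungapped reverse-complement window pairs of length ≥ 4 within the
sequence — a documented hairpin/homodimer proxy, not a free-energy fold;
the guide filter requires it to be 0.

## Virtual PCR

A primer binds a site iff its 3′-terminal 3 bases match exactly and at
most 2 mismatches occur elsewhere; both strands are scanned at every
offset. Products pair each plus-strand forward site with every downstream
minus-strand reverse site within 5 kb; the readout is binary presence, as
on a gel — no extension-probability or band-intensity model. Real 3′
mismatch tolerance varies by polymerase and mismatch identity, so the
binary rule is a deliberate idealization; assays that pass it can still
fail at the bench.

## Guide scan

Off-target scanning is an exhaustive Hamming comparison of the 20-nt
spacer against every NGG-adjacent window on both strands, vectorized with
numpy sliding windows. At the scales this package targets (assay loci and
context genomes up to a few hundred kb) exhaustive scanning is fast and
provably identical to the brute-force definition, so no seed-and-extend
heuristic is used. Mismatches are counted over the spacer only (the PAM's
N is free); PAM-proximal weighting and alternative PAMs (NAG) are out of
scope. The "no off-target within 1 mismatch" filter exempts the
candidate's own site and any allowlisted location, which is how a guide
deliberately targeting a conserved site across paralogs is kept.

## Synthetic data

Generators use `numpy.random.default_rng` seeded explicitly; identical
seeds give byte-identical outputs. Sequences are drawn with exact base
composition (realized GC equals the target up to rounding, before guide
planting). The fixture set emulates: kilobase assay loci at 50% GC;
clean-context indels (unique placement, repeat-free shifted window — the
fully designable case); homopolymer-context indels (runs ≥ 3, the
fallback/failure case); a 1100-bp locus whose designated primer pair gives
a 900-bp wild-type product and an 860-bp product on a 40-bp two-cut
drop-out allele; and genotyping campaigns whose band tables are produced
by actually running the designed assay through virtual PCR per sample,
with an optional independent per-lane failure rate. What the generators do
*not* emulate: real base composition structure (isochores, repeats beyond
planted runs), polymerase-dependent partial extension, band intensity,
sample cross-contamination, and linkage between loci — so passing tests
demonstrate the logic of the method, not its wet-lab success rate.

Test and acceptance problem sizes are chosen to be desk-scale while still
exercising the claims: ≥ 1000 seeded loci for geometry and
allele-exclusivity sweeps, 20–50 kb genomes for scan/filter checks,
200–2000-sample campaigns for calling statistics.

## Degenerate inputs and tie-breaks

Substitutions are storable but rejected by the designer (nothing shifts
register). Templates may contain N, but any primer or spacer window
containing N is rejected. A primer extending past the template end counts
the overhang as mismatched (nothing to pair with). Orientation search
order is forward then reverse; among equal-mismatch pairs, smaller maximal
|Tm − target| wins; the common-primer search walks outward from mid-sized
amplicons and stops early within 0.5 °C of the target. (absent, absent)
band observations are reported as `no_amplification`, never as a genotype,
because a failed prep and a novel allele are indistinguishable on a gel;
any `failed` lane makes the call `indeterminate`.

## Known limitations

- No heterodimer/hairpin free-energy model for primer pairs; the stem
  count is a proxy.
- The extension rule is binary and polymerase-agnostic.
- Multi-locus genotypes are treated as independent columns; linked loci
  (e.g. tandem paralogs) are not jointly inferred.
- Guide on-target efficiency scoring is out of scope; filters are
  screening-grade design criteria only.
- Off-target scanning is exact Hamming, not an alignment-based search: it
  will not find bulged (gapped) off-target sites.
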