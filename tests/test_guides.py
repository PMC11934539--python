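"""Guide enumeration, filters, off-target scan, drop-out arithmetic."""

import re

import numpy as np
import pytest

from ispcr.fixtures import FixtureSpec, make_locus, make_dropout_locus
from ispcr.guides import (
    GuideFilterConfig,
    enumerate_guides,
    filter_guides,
    predict_dropout,
    scan_offtargets,
)
from ispcr.seqio import ReferenceSequence, ValidationError, reverse_complement


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def oracle_enumerate(seq):
    """Regex-style positional scan of both strands."""
    hits = []
    for m in re.finditer(r"(?=([ACGT]{20})[ACGT]GG)", seq):
        hits.append((m.start() + 1, "+", m.group(1)))
    for m in re.finditer(r"(?=CC[ACGT]([ACGT]{20}))", seq):
        hits.append((m.start() + 4, "-", reverse_complement(m.group(1))))
    return sorted(hits)


def oracle_offtargets(spacer, seq, max_mm):
    """Exhaustive Hamming comparison at every NGG-adjacent window."""
    hits = []
    for start, strand, site in oracle_enumerate(seq):
        if strand == "+":
            window = seq[start - 1 : start + 19]
        else:
            window = reverse_complement(seq[start - 1 : start + 19])
        mm = sum(a != b for a, b in zip(spacer, window))
        if mm <= max_mm:
            hits.append((start, strand, mm))
    return sorted(hits)


class TestEnumerateGuides:
    def test_no_gg_means_no_guides(self):
        assert enumerate_guides(ReferenceSequence("t", "A" * 30)) == []

    def test_single_planted_plus_strand_site(self):
        rng = np.random.default_rng(0)
        spacer = random_dna(rng, 20)
        template = ReferenceSequence("t", "AT" * 15 + spacer + "AGG" + "AT" * 15)
        cands = enumerate_guides(template)
        planted = [c for c in cands if c.spacer == spacer]
        assert len(planted) == 1
        c = planted[0]
        assert (c.strand, c.protospacer_start, c.pam) == ("+", 31, "AGG")
        assert c.cut_site == 31 + 20 - 3 - 1  # blunt cut 3 bp 5' of the PAM

    @pytest.mark.parametrize("seed", [1, 2])
    def test_count_matches_positional_scan_on_random_template(self, seed):
        rng = np.random.default_rng(seed)
        template = ReferenceSequence("t", random_dna(rng, 10_000))
        cands = enumerate_guides(template)
        got = sorted((c.protospacer_start, c.strand, c.spacer) for c in cands)
        assert got == oracle_enumerate(template.sequence)

    def test_spacer_matches_template_at_recorded_coordinates(self):
        rng = np.random.default_rng(3)
        template = ReferenceSequence("t", random_dna(rng, 2000))
        for c in enumerate_guides(template):
            window = template.sequence[c.protospacer_start - 1 : c.protospacer_start + 19]
            assert c.spacer == (window if c.strand == "+" else reverse_complement(window))


class TestScanOfftargets:
    def test_exact_protospacer_single_hit(self):
        rng = np.random.default_rng(4)
        spacer = random_dna(rng, 20)
        genome = ReferenceSequence("g", "TA" * 20 + spacer + "TGG" + "TA" * 20)
        hits = scan_offtargets(spacer, [genome])
        assert len(hits) == 1 and hits[0].mismatches == 0 and hits[0].start == 41

    def test_planted_mismatch_ladder_respects_cap(self):
        rng = np.random.default_rng(5)
        spacer = random_dna(rng, 20)
        parts = []
        for k in range(6):  # plant sites at 0..5 mismatches
            site = list(spacer)
            positions = rng.choice(20, size=k, replace=False)
            for p in positions:
                site[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[p]]
            parts.append("TTAATT" + "".join(site) + "AGG")
        genome = ReferenceSequence("g", "AT" * 10 + "".join(parts) + "AT" * 10)
        hits = scan_offtargets(spacer, [genome], max_mm=3)
        assert len(hits) == 4
        assert sorted(h.mismatches for h in hits) == [0, 1, 2, 3]

    @pytest.mark.parametrize("seed", [6, 7])
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genome = ReferenceSequence("g", random_dna(rng, 20_000))
        spacer = genome.sequence[500:520]
        got = sorted((h.start, h.strand, h.mismatches) for h in scan_offtargets(spacer, [genome], 3))
        assert got == oracle_offtargets(spacer, genome.sequence, 3)

    def test_invariant_under_genome_reverse_complement(self):
        rng = np.random.default_rng(8)
        genome = ReferenceSequence("g", random_dna(rng, 5000))
        spacer = genome.sequence[100:120]
        fwd = scan_offtargets(spacer, [genome], 3)
        rc = scan_offtargets(spacer, [ReferenceSequence("g", reverse_complement(genome.sequence))], 3)
        n = len(genome.sequence)
        remapped = sorted(
            (n - (h.start + 19) + 1, "+" if h.strand == "-" else "-", h.mismatches) for h in rc
        )
        assert sorted((h.start, h.strand, h.mismatches) for h in fwd) == remapped


class TestFilterGuides:
    def _one_candidate_genome(self, spacer, extra=""):
        seq = "TA" * 15 + spacer + "AGG" + "TA" * 15 + extra
        return ReferenceSequence("g", seq)

    def test_low_gc_rejected_with_reason(self):
        spacer = "ATATATATATATTATAGTAT"  # GC 5%
        genome = self._one_candidate_genome(spacer)
        cands = [c for c in enumerate_guides(genome) if c.spacer == spacer]
        passing, reasons = filter_guides(cands, [genome])
        assert passing == [] and reasons[spacer] == "gc_below_min"

    def test_one_mismatch_site_rejects_then_allowlist_keeps(self):
        rng = np.random.default_rng(9)
        while True:  # need a filter-clean spacer so only the planted site decides
            spacer = random_dna(rng, 20)
            from ispcr.thermo import gc_content, self_complementarity

            if 30 <= gc_content(spacer) <= 70 and self_complementarity(spacer) == 0:
                break
        near = list(spacer)
        near[7] = {"A": "C", "C": "A", "G": "T", "T": "G"}[near[7]]
        extra = "TTAATTAATT" + "".join(near) + "TGG" + "TTAATT"
        genome = self._one_candidate_genome(spacer, extra)
        cands = [c for c in enumerate_guides(genome) if c.spacer == spacer]
        assert len(cands) == 1
        passing, reasons = filter_guides(cands, [genome])
        assert passing == [] and reasons[spacer] == "offtarget_near_match"
        near_start = len("TA" * 15 + spacer + "AGG" + "TA" * 15) + 11
        passing, _ = filter_guides(cands, [genome], allowlist=[("g", near_start, "+")])
        assert passing == cands

    def test_allowlist_location_absent_rejected(self):
        genome = self._one_candidate_genome("ACGT" * 5)
        with pytest.raises(ValidationError, match="allowlist"):
            filter_guides([], [genome], allowlist=[("missing", 10, "+")])

    def test_passing_candidates_satisfy_all_predicates_independently(self):
        from ispcr.thermo import gc_content, self_complementarity

        rng = np.random.default_rng(10)
        genome = ReferenceSequence("g", random_dna(rng, 8000))
        cands = enumerate_guides(genome)[:200]
        passing, _ = filter_guides(cands, [genome])
        cfg = GuideFilterConfig()
        for c in passing:
            assert cfg.gc_min <= gc_content(c.spacer) <= cfg.gc_max
            assert self_complementarity(c.spacer) == 0
            others = [
                h
                for h in scan_offtargets(c.spacer, [genome], cfg.offtarget_max_mm)
                if (h.sequence_id, h.start, h.strand)
                != (c.target_id, c.protospacer_start, c.strand)
            ]
            assert others == []


class TestPredictDropout:
    def test_40bp_deletion_in_900bp_amplicon(self, dropout_locus):
        pred = predict_dropout(dropout_locus.guide_a, dropout_locus.guide_b, dropout_locus.fwd_start, dropout_locus.rev_end)
        assert (pred.wt_amplicon_bp, pred.deletion_bp, pred.edited_amplicon_bp) == (900, 40, 860)

    def test_387bp_loss_gives_513bp_product(self, dropout_locus):
        from dataclasses import replace

        ga = dropout_locus.guide_a
        gb = replace(dropout_locus.guide_b, cut_site=ga.cut_site + 387, protospacer_start=ga.cut_site + 371)
        pred = predict_dropout(ga, gb, dropout_locus.fwd_start, dropout_locus.rev_end)
        assert pred.deletion_bp == 387
        assert pred.edited_amplicon_bp == 900 - 387 == 513

    def test_degenerate_same_guide(self, dropout_locus):
        pred = predict_dropout(dropout_locus.guide_a, dropout_locus.guide_a, dropout_locus.fwd_start, dropout_locus.rev_end)
        assert pred.deletion_bp == 0 and pred.edited_amplicon_bp == pred.wt_amplicon_bp

    def test_cut_outside_amplicon_rejected(self, dropout_locus):
        from dataclasses import replace

        outside = replace(dropout_locus.guide_b, cut_site=dropout_locus.rev_end + 50)
        with pytest.raises(ValidationError, match="cut not spanned"):
            predict_dropout(dropout_locus.guide_a, outside, dropout_locus.fwd_start, dropout_locus.rev_end)

    def test_sum_invariant(self, dropout_locus):
        pred = predict_dropout(dropout_locus.guide_a, dropout_locus.guide_b, dropout_locus.fwd_start, dropout_locus.rev_end)
        assert pred.deletion_bp + pred.edited_amplicon_bp == pred.wt_amplicon_bp
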