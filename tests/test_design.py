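"""Allele-specific primer placement, terminal selectivity, assay assembly."""

import pytest

from ispcr.design import (
    DesignConfig,
    DesignError,
    UndesignableLocusError,
    candidate_allele_primers,
    choose_common_primer,
    design_assay,
    equivalent_placements,
    terminal_mismatch_count,
)
from ispcr.fixtures import make_clean_indel_locus
from ispcr.seqio import (
    EditSpec,
    ReferenceSequence,
    ValidationError,
    apply_edit,
    normalize_edit,
)


def oracle_terminal_mm(primer: str, other: str, anchor5: int, window: int = 3) -> int:
    """Brute-force ungapped alignment: lay the primer on the other allele at
    its 5' anchor and count mismatches among the 3'-terminal window bases."""
    aligned = other[anchor5 - 1 : anchor5 - 1 + len(primer)]
    aligned = aligned + "!" * (len(primer) - len(aligned))  # overhang never pairs
    return sum(p != t for p, t in zip(primer[-window:], aligned[-window:]))


class TestCandidatePrimers:
    def test_toy_insertion_primers_and_offsets(self, toy_wt, toy_mut, toy_edit, toy_cfg):
        cands = candidate_allele_primers(toy_wt, toy_mut, toy_edit, "forward", toy_cfg)
        by_allele = {c.allele: c for c in cands}
        assert by_allele["mutant"].sequence == "AAACGTCGAT"
        assert by_allele["wild_type"].sequence == "AAACGTCATG"
        assert all(c.indel_offset_observed == 3 for c in cands)

    def test_toy_terminal_mismatches_are_three_each_way(self, toy_wt, toy_mut, toy_edit, toy_cfg):
        cands = candidate_allele_primers(toy_wt, toy_mut, toy_edit, "forward", toy_cfg)
        for c in cands:
            other = toy_wt.sequence if c.allele == "mutant" else toy_mut.sequence
            assert c.terminal_mismatches_vs_other == 3
            assert c.terminal_mismatches_vs_other == oracle_terminal_mm(
                c.sequence, other, c.frame_start
            )

    def test_primers_perfectly_match_own_allele(self, toy_wt, toy_mut, toy_edit, toy_cfg):
        for c in candidate_allele_primers(toy_wt, toy_mut, toy_edit, "forward", toy_cfg):
            own = toy_mut.sequence if c.allele == "mutant" else toy_wt.sequence
            assert own[c.frame_start - 1 : c.frame_end] == c.sequence

    def test_homopolymer_best_forward_candidate_reaches_only_two(self):
        wt = ReferenceSequence("y", "ACGTCAAATTGGCA")
        edit = EditSpec("y", 5, "C", "CA", "+1A")  # insertion into the AAA run
        mut = apply_edit(wt, normalize_edit(edit, wt))
        cfg = DesignConfig(min_len=8, max_len=8, tm_min=0, tm_max=100, tm_target=25,
                           amplicon_min=5, amplicon_max=20, tm_pair_tolerance=100)
        cands = candidate_allele_primers(wt, mut, edit, "forward", cfg)
        best = max(
            min(
                c.terminal_mismatches_vs_other
                for c in cands
                if c.placement_pos == q
            )
            for q in {c.placement_pos for c in cands}
        )
        assert best == 2
        for c in cands:  # agrees with the exhaustive alignment oracle everywhere
            other = wt.sequence if c.allele == "mutant" else mut.sequence
            assert c.terminal_mismatches_vs_other == oracle_terminal_mm(
                c.sequence, other, c.frame_start
            )

    def test_substitution_rejected(self, toy_wt, toy_cfg):
        sub = EditSpec("toy", 7, "C", "G")
        with pytest.raises(DesignError, match="not an indel"):
            candidate_allele_primers(toy_wt, apply_edit(toy_wt, sub), sub, "forward", toy_cfg)

    def test_insufficient_flank(self, toy_cfg):
        wt = ReferenceSequence("s", "ACGTA")
        edit = EditSpec("s", 2, "C", "CT")
        with pytest.raises(DesignError, match="insufficient flank"):
            candidate_allele_primers(wt, apply_edit(wt, edit), edit, "forward", toy_cfg)


class TestEquivalentPlacements:
    def test_clean_insertion_has_unique_placement(self, toy_wt, toy_edit):
        edit = normalize_edit(toy_edit, toy_wt)
        assert equivalent_placements(toy_wt.sequence, edit) == [7]

    def test_homopolymer_insertion_spans_the_run(self):
        wt = ReferenceSequence("y", "ACGTCAAATTGGCA")
        edit = normalize_edit(EditSpec("y", 5, "C", "CA"), wt)
        assert equivalent_placements(wt.sequence, edit) == [5, 6, 7, 8]


class TestTerminalMismatchCount:
    def test_three_against_other_allele(self, toy_wt):
        assert terminal_mismatch_count("AAACGTCGAT", toy_wt.sequence, 1) == 3

    def test_zero_against_own_allele(self, toy_mut):
        assert terminal_mismatch_count("AAACGTCGAT", toy_mut.sequence, 1) == 0

    def test_symmetric_wt_primer_vs_mutant(self, toy_mut):
        assert terminal_mismatch_count("AAACGTCATG", toy_mut.sequence, 1) == 3

    def test_anchor_outside_template_rejected(self):
        with pytest.raises(ValidationError, match="anchor"):
            terminal_mismatch_count("ACGTACGTAC", "ACGT", 10)


class TestCommonPrimer:
    def test_constraints_hold_on_synthetic_template(self):
        wt, edit = make_clean_indel_locus(seed=2)
        assay = design_assay(wt, edit)
        cp = assay.common_primer
        cfg = DesignConfig()
        assert cfg.tm_min <= cp.physical.tm_celsius <= cfg.tm_max
        assert abs(cp.physical.tm_celsius - assay.wt_primer.physical.tm_celsius) <= cfg.tm_pair_tolerance
        assert cfg.amplicon_min <= assay.wt_amplicon_bp <= cfg.amplicon_max

    def test_common_primer_matches_both_alleles(self):
        from ispcr.seqio import reverse_complement

        wt, edit = make_clean_indel_locus(seed=2)
        assay = design_assay(wt, edit)
        mut = apply_edit(wt, assay.locus)
        site = reverse_complement(assay.common_primer.sequence)
        assert site in wt.sequence and site in mut.sequence

    def test_template_too_short_downstream(self, toy_wt, toy_edit, toy_mut, toy_cfg):
        cfg = DesignConfig(min_len=10, max_len=10, tm_min=0, tm_max=100, tm_target=30,
                           amplicon_min=500, amplicon_max=600, tm_pair_tolerance=100)
        pair_cands = candidate_allele_primers(toy_wt, toy_mut, toy_edit, "forward", cfg)
        pair = (pair_cands[0], pair_cands[1])
        with pytest.raises(DesignError, match="common primer"):
            choose_common_primer(toy_wt.sequence, normalize_edit(toy_edit, toy_wt), pair, cfg)


class TestDesignAssay:
    def test_clean_insertion_yields_forward_assay_at_three_mismatches(self):
        wt, edit = make_clean_indel_locus(seed=0)
        assay = design_assay(wt, edit)
        assert assay.orientation == "forward"
        assert assay.wt_primer.terminal_mismatches_vs_other >= 3
        assert assay.mut_primer.terminal_mismatches_vs_other >= 3

    def test_amplicon_delta_bookkeeping(self, designed_batch):
        for _, edit, assay in designed_batch[:200]:
            assert assay.mut_amplicon_bp - assay.wt_amplicon_bp == assay.locus.delta

    def test_homopolymer_fallback_rescues_via_right_aligned_reverse_placement(self):
        # insertion into the AAA run of ACGTC-AAA-TT...: every forward
        # placement is capped at 2 terminal mismatches by the repeats, but
        # the right-aligned placement in the reverse frame faces the
        # non-repeating GTC context and recovers all 3
        core = "ACGTCAAATTGGCA"
        wt = ReferenceSequence("y", "GCTA" * 6 + core + "TAGC" * 6)
        edit = EditSpec("y", 24 + 5, "C", "CA", "+1A")
        cfg = dict(min_len=8, max_len=8, tm_min=0, tm_max=100, tm_target=25,
                   amplicon_min=10, amplicon_max=40, tm_pair_tolerance=100)
        assay = design_assay(wt, edit, DesignConfig(min_terminal_mm=3, **cfg))
        assert assay.orientation == "reverse"
        assert assay.wt_primer.terminal_mismatches_vs_other == 3
        assert assay.mut_primer.terminal_mismatches_vs_other == 3
        assert any("forward" in d for d in assay.diagnostics)

    def test_homopolymer_run_undesignable_at_default_threshold(self):
        # run flanked by repeats on both sides (CCC-AAA-CCA): forward tops
        # out at 2 mismatches and reverse at 1, so the default threshold of
        # 3 fails in both orientations; relaxing to 2 recovers forward
        core = "CCCAAACCA"
        wt = ReferenceSequence("y", "GCTG" * 6 + core + "TCAG" * 6)
        edit = EditSpec("y", 24 + 3, "C", "CA", "+1A")
        cfg = dict(min_len=8, max_len=8, tm_min=0, tm_max=100, tm_target=25,
                   amplicon_min=10, amplicon_max=40, tm_pair_tolerance=100)
        with pytest.raises(UndesignableLocusError) as exc:
            design_assay(wt, edit, DesignConfig(min_terminal_mm=3, **cfg))
        assert exc.value.best_by_orientation["forward"] == 2
        assert exc.value.best_by_orientation["reverse"] == 1
        relaxed = design_assay(wt, edit, DesignConfig(min_terminal_mm=2, **cfg))
        assert relaxed.orientation == "forward"

    def test_relabeling_swaps_roles_not_sequences(self):
        wt, edit = make_clean_indel_locus(seed=4)
        assay = design_assay(wt, edit)
        mut = apply_edit(wt, assay.locus)
        # treat the mutant as the reference and the reverse edit as the change
        from ispcr.seqio import infer_edit

        flipped_ref = ReferenceSequence(wt.id, mut.sequence)
        flipped_edit = infer_edit(mut.sequence, wt.sequence, wt.id)
        flipped = design_assay(flipped_ref, flipped_edit, DesignConfig())
        assert {flipped.wt_primer.sequence, flipped.mut_primer.sequence} == {
            assay.wt_primer.sequence,
            assay.mut_primer.sequence,
        }
        assert flipped.wt_primer.sequence == assay.mut_primer.sequence

    def test_reverse_orientation_fallback_engages(self, designed_batch):
        # fallback exists for loci whose forward strand cannot discriminate;
        # over a large seeded batch at least one locus exercises it and its
        # assays obey the same invariants
        reverse = [a for _, _, a in designed_batch if a.orientation == "reverse"]
        for assay in reverse:
            assert assay.wt_primer.terminal_mismatches_vs_other >= 3
            assert assay.mut_primer.terminal_mismatches_vs_other >= 3
            assert any("forward" in d for d in assay.diagnostics)
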