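"""Seeded synthetic fixtures: loci, planted guides, indel alleles, campaigns.

Everything any other module needs to be exercised end-to-end is generated
here deterministically from an integer seed, so the whole package is
testable without downloading any sequence.  The generated material emulates
the shape of real assay loci for this method: kilobase-scale templates at
moderate GC, SpCas9 NGG target sites, single-base indel alleles in clean or
homopolymer context, a locus whose wild-type assay yields a 900-bp product
with a 40-bp two-cut drop-out allele, and plate-scale genotyping campaigns
segregating 1:2:1 as a selfed heterozygote would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import DEFAULT_CONFIG, DesignConfig, DesignError, IsPcrAssay, design_assay
from .guides import CUT_OFFSET, SPACER_LEN, GuideCandidate, _make_candidate
from .insilico import DEFAULT_STRINGENCY, predict_assay_bands
from .seqio import (
    AlleleSequence,
    EditSpec,
    ReferenceSequence,
    ValidationError,
    apply_edit,
    normalize_edit,
)

__all__ = [
    "EditTemplate",
    "FixtureSpec",
    "DropoutLocus",
    "Campaign",
    "make_locus",
    "make_edit",
    "make_clean_indel_locus",
    "make_dropout_locus",
    "make_campaign",
]


@dataclass(frozen=True)
class EditTemplate:
    """Recipe for planting one single-base indel."""

    kind: str = "insertion"       # "insertion" | "deletion"
    base: Optional[str] = None    # inserted base; None = random
    context: str = "clean"        # "clean" | "homopolymer"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; identical seed, identical bytes."""

    seed: int = 0
    locus_length: int = 1200
    gc_target: float = 50.0
    planted_guides: int = 2
    edits: tuple[EditTemplate, ...] = (EditTemplate(),)
    campaign_size: int = 96
    proportions: tuple[float, float, float] = (0.25, 0.5, 0.25)  # hom_ref, het, hom_alt (selfed 1:2:1)
    lane_failure_rate: float = 0.0


def _random_sequence(rng: np.random.Generator, length: int, gc_target: float) -> str:
    """Exact-composition random sequence: realized GC == target up to rounding."""
    n_gc = int(round(length * gc_target / 100.0))
    n_at = length - n_gc
    bases = (
        ["G"] * (n_gc // 2)
        + ["C"] * (n_gc - n_gc // 2)
        + ["A"] * (n_at // 2)
        + ["T"] * (n_at - n_at // 2)
    )
    return "".join(np.array(bases)[rng.permutation(length)])


def make_locus(spec: FixtureSpec) -> tuple[ReferenceSequence, list[GuideCandidate]]:
    """A random template with NGG guide sites planted at recorded coordinates."""
    if spec.locus_length < 500:
        raise ValidationError("locus_length must be >= 500")
    if spec.planted_guides > 0 and spec.gc_target in (0.0, 100.0):
        raise ValidationError("cannot plant NGG guide sites at GC 0% or 100%")
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_sequence(rng, spec.locus_length, spec.gc_target))

    planted: list[GuideCandidate] = []
    taken: list[tuple[int, int]] = []
    locus_id = f"locus_seed{spec.seed}"
    margin = 50
    attempts = 0
    while len(planted) < spec.planted_guides and attempts < 1000:
        attempts += 1
        start0 = int(rng.integers(margin, spec.locus_length - margin - SPACER_LEN - 3))
        span = (start0, start0 + SPACER_LEN + 3)
        if any(not (span[1] <= s or span[0] >= e) for s, e in taken):
            continue
        spacer = _random_sequence(rng, SPACER_LEN, spec.gc_target)
        seq[start0 : start0 + SPACER_LEN] = list(spacer)
        seq[start0 + SPACER_LEN : start0 + SPACER_LEN + 3] = list(
            rng.choice(list("ACGT")) + "GG"
        )
        taken.append(span)
        pam = "".join(seq[start0 + SPACER_LEN : start0 + SPACER_LEN + 3])
        planted.append(_make_candidate(locus_id, spacer, "+", start0 + 1, pam))
    if len(planted) < spec.planted_guides:
        raise ValidationError("could not place the requested number of guide sites")
    template = ReferenceSequence(locus_id, "".join(seq))
    planted.sort(key=lambda g: g.protospacer_start)
    return template, planted


def make_edit(
    template: ReferenceSequence,
    tmpl: EditTemplate = EditTemplate(),
    rng: Optional[np.random.Generator] = None,
    pos_range: Optional[tuple[int, int]] = None,
) -> EditSpec:
    """Plant one single-base indel of the requested context class.

    Clean context: the indel has a unique placement and the bases in the
    register-shifted 3' window are non-repeating, so all three terminal
    mismatches materialize (the fully designable case).  Homopolymer
    context: the indel sits inside a run of >= 3 identical bases,
    exercising the designer's fallback and failure paths.
    """
    rng = rng or np.random.default_rng(0)
    seq = template.sequence
    lo, hi = pos_range or (int(template.length * 0.25), int(template.length * 0.45))
    for _ in range(500):
        pos = int(rng.integers(lo, hi))  # 1-based anchor
        anchor = seq[pos - 1]
        nxt = seq[pos] if pos < template.length else ""
        if tmpl.context == "homopolymer":
            if tmpl.kind == "insertion":
                if seq[pos : pos + 3] == seq[pos] * 3:
                    edit = EditSpec(template.id, pos, anchor, anchor + seq[pos], "hp+1")
                else:
                    continue
            else:
                if seq[pos : pos + 3] == seq[pos] * 3:
                    edit = EditSpec(template.id, pos, anchor + seq[pos], anchor, "hp-1")
                else:
                    continue
        else:
            # a shifted register mismatches at offset i only where adjacent
            # bases differ, so 3 terminal mismatches need a repeat-free window
            if seq[pos] == seq[pos + 1] or seq[pos + 1] == seq[pos + 2]:
                continue
            if tmpl.kind == "insertion":
                choices = [b for b in "ACGT" if b != anchor and b != nxt]
                base = tmpl.base or str(rng.choice(choices))
                if base == anchor or base == nxt:
                    continue
                edit = EditSpec(template.id, pos, anchor, anchor + base, f"+1{base}")
            else:
                if not nxt or nxt == anchor or seq[pos + 2] == seq[pos + 3]:
                    continue
                edit = EditSpec(template.id, pos, anchor + nxt, anchor, f"-1{nxt}")
        return normalize_edit(edit, template)
    raise ValidationError("could not place an edit of the requested context class")


def make_clean_indel_locus(
    seed: int, length: int = 900, gc_target: float = 50.0
) -> tuple[ReferenceSequence, EditSpec]:
    """A random template plus one clean-context single-base indel."""
    rng = np.random.default_rng(seed)
    template = ReferenceSequence(
        f"locus_seed{seed}", _random_sequence(rng, length, gc_target)
    )
    kind = "insertion" if rng.integers(2) == 0 else "deletion"
    edit = make_edit(template, EditTemplate(kind=kind), rng)
    return template, edit


# ---------------------------------------------------------------------------
# The 900/860 drop-out locus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DropoutLocus:
    """A locus whose wild-type assay spans two cut sites 40 bp apart.

    The primer pair yields a 900-bp wild-type product; the drop-out allele
    (deletion joining the two blunt cuts) yields 860 bp.
    """

    template: ReferenceSequence
    fwd_primer: str
    rev_primer: str
    fwd_start: int       # 1-based first base of the wild-type amplicon
    rev_end: int         # 1-based last base of the wild-type amplicon
    guide_a: GuideCandidate
    guide_b: GuideCandidate
    dropout_allele: AlleleSequence
    wt_product_bp: int
    deletion_bp: int


def make_dropout_locus(seed: int = 0) -> DropoutLocus:
    """Template + assay layout with a 900-bp wild-type product and a 40-bp
    drop-out allele (860-bp edited product)."""
    from .insilico import find_binding_sites

    length = 1100
    fwd_start, rev_end = 101, 1000           # product = 1000 - 101 + 1 = 900
    cut_a, cut_b = 500, 540                  # deletion joins the blunt cuts: 40 bp
    for attempt in range(50):
        rng = np.random.default_rng((seed * 1009 + attempt) % 2**31)
        seq = list(_random_sequence(rng, length, 50.0))
        guides = []
        for cut in (cut_a, cut_b):
            start0 = cut - (SPACER_LEN - CUT_OFFSET)  # 0-based spacer start
            spacer = _random_sequence(rng, SPACER_LEN, 50.0)
            seq[start0 : start0 + SPACER_LEN] = list(spacer)
            seq[start0 + SPACER_LEN : start0 + SPACER_LEN + 3] = list("AGG")
            guides.append((spacer, start0 + 1))
        template = ReferenceSequence(f"dropout_locus_seed{seed}", "".join(seq))
        fwd = template.sequence[fwd_start - 1 : fwd_start + 19]
        rev_window = template.sequence[rev_end - 20 : rev_end]
        from .seqio import reverse_complement

        rev = reverse_complement(rev_window)
        # the assay must bind uniquely on the wild-type template
        f_sites = find_binding_sites(fwd, template.sequence, DEFAULT_STRINGENCY)
        r_sites = find_binding_sites(rev, template.sequence, DEFAULT_STRINGENCY)
        if len(f_sites) != 1 or len(r_sites) != 1:
            continue
        dropout_seq = template.sequence[:cut_a] + template.sequence[cut_b:]
        coord = tuple(range(1, cut_a + 1)) + tuple(range(cut_b + 1, length + 1))
        dropout = AlleleSequence(
            base_id=template.id,
            edit_label=f"dropout_{cut_b - cut_a}bp",
            sequence=dropout_seq,
            coord_map=coord,
        )
        ga = _make_candidate(template.id, guides[0][0], "+", guides[0][1],
                             template.sequence[guides[0][1] + SPACER_LEN - 1 : guides[0][1] + SPACER_LEN + 2])
        gb = _make_candidate(template.id, guides[1][0], "+", guides[1][1],
                             template.sequence[guides[1][1] + SPACER_LEN - 1 : guides[1][1] + SPACER_LEN + 2])
        return DropoutLocus(
            template=template,
            fwd_primer=fwd,
            rev_primer=rev,
            fwd_start=fwd_start,
            rev_end=rev_end,
            guide_a=ga,
            guide_b=gb,
            dropout_allele=dropout,
            wt_product_bp=rev_end - fwd_start + 1,
            deletion_bp=cut_b - cut_a,
        )
    raise ValidationError("could not build a uniquely-priming drop-out locus")


# ---------------------------------------------------------------------------
# Genotyping campaign
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Campaign:
    """A simulated screening campaign with known truth."""

    template: ReferenceSequence
    edit: EditSpec
    assay: IsPcrAssay
    observations: pd.DataFrame   # sample_id, locus_id, wt_band, mut_band
    truth: pd.DataFrame          # sample_id, locus_id, genotype
    seed: int


_GENOTYPE_ALLELES = {
    "hom_ref": ("wild_type", "wild_type"),
    "het": ("wild_type", "mutant"),
    "hom_alt": ("mutant", "mutant"),
}


def make_campaign(spec: FixtureSpec, cfg: DesignConfig = DEFAULT_CONFIG) -> Campaign:
    """Design an assay on a clean-context indel locus and screen a cohort.

    Genotypes are drawn at ``spec.proportions``; the band table is produced
    by running the designed assay through virtual PCR on each sample's
    allele pair, then optionally corrupting lanes at
    ``spec.lane_failure_rate`` (each tube independently unreadable).
    """
    if spec.campaign_size < 1:
        raise ValidationError("campaign_size must be >= 1")
    if abs(sum(spec.proportions) - 1.0) > 1e-9:
        raise ValidationError("genotype proportions must sum to 1")
    rng = np.random.default_rng(spec.seed)

    assay = None
    for attempt in range(25):
        template, _ = make_locus(
            FixtureSpec(seed=spec.seed * 131 + attempt, locus_length=spec.locus_length,
                        gc_target=spec.gc_target, planted_guides=0)
        )
        try:
            edit = make_edit(template, spec.edits[0], rng)
            assay = design_assay(template, edit, cfg)
            break
        except (ValidationError, DesignError):
            continue
    if assay is None:
        raise ValidationError("could not design an assay on any generated locus")
    edit = assay.locus
    wt_allele = template
    mut_allele = apply_edit(template, edit)
    allele_obj = {"wild_type": wt_allele, "mutant": mut_allele}

    # bands per genotype are deterministic; simulate each class once
    bands_by_genotype = {}
    for gt, alleles in _GENOTYPE_ALLELES.items():
        present = set(alleles)
        table = predict_assay_bands(assay, [allele_obj[a] for a in present])
        wt_band = "present" if table.query("sub_assay == 'wild_type'")["amplifies"].any() else "absent"
        mut_band = "present" if table.query("sub_assay == 'mutant'")["amplifies"].any() else "absent"
        bands_by_genotype[gt] = (wt_band, mut_band)

    classes = list(_GENOTYPE_ALLELES)
    draws = rng.choice(len(classes), size=spec.campaign_size, p=list(spec.proportions))
    rows, truth_rows = [], []
    for i, d in enumerate(draws):
        gt = classes[int(d)]
        wt_band, mut_band = bands_by_genotype[gt]
        if spec.lane_failure_rate > 0:
            if rng.random() < spec.lane_failure_rate:
                wt_band = "failed"
            if rng.random() < spec.lane_failure_rate:
                mut_band = "failed"
        sample = f"S{i + 1:04d}"
        rows.append(
            {"sample_id": sample, "locus_id": edit.target_id,
             "wt_band": wt_band, "mut_band": mut_band}
        )
        truth_rows.append({"sample_id": sample, "locus_id": edit.target_id, "genotype": gt})
    return Campaign(
        template=template,
        edit=edit,
        assay=assay,
        observations=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
        seed=spec.seed,
    )
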