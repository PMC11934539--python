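"""Indel-selective PCR assay design.

The design principle: a single-base indel is placed three nucleotides from
the 3' end of each allele-specific primer, so the primer perfectly matches
its own allele while presenting mismatches at the indel site *and* at the
two register-shifted bases 3' of it against the other allele.  Three
3'-terminal mismatches disable polymerase extension even when the rest of
the primer anneals, so each primer selectively amplifies one allele.  The
wild-type and mutant primers are paired with a single common primer on the
opposing strand that matches both alleles.

Inside a repeat run the indel placement is ambiguous (all placements give
the same mutant sequence but different terminal-mismatch patterns), so both
left- and right-aligned placements are tried and the one maximizing
selectivity wins.  When no forward-orientation pair reaches the required
terminal mismatches, the whole construction is retried in reverse
orientation on the bottom strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .seqio import (
    AlleleSequence,
    EditSpec,
    ReferenceSequence,
    ValidationError,
    apply_edit,
    infer_edit,
    normalize_edit,
    reverse_complement,
)
from .thermo import (
    DEFAULT_THERMO,
    PrimerPhysical,
    ThermoParams,
    melting_temperature,
    primer_physical,
)

__all__ = [
    "DesignConfig",
    "AlleleSpecificPrimer",
    "CommonPrimer",
    "IsPcrAssay",
    "DesignError",
    "UndesignableLocusError",
    "equivalent_placements",
    "candidate_allele_primers",
    "terminal_mismatch_count",
    "choose_common_primer",
    "design_assay",
]


class DesignError(ValidationError):
    """A locus/configuration combination that cannot yield an assay."""


class UndesignableLocusError(DesignError):
    """Both orientations failed; carries the best mismatch count achieved."""

    def __init__(self, message: str, best_by_orientation: dict[str, int]):
        super().__init__(message)
        self.best_by_orientation = best_by_orientation


@dataclass(frozen=True)
class DesignConfig:
    """Primer design constraints.

    Defaults encode standard assay practice for this method: 18–22 nt
    primers, Tm window 52–60 °C with a 58 °C optimum, the indel three bases
    from the 3' end, three required terminal mismatches against the
    non-target allele, and gel-friendly 250–600 bp products.
    """

    min_len: int = 18
    max_len: int = 22
    tm_min: float = 52.0
    tm_max: float = 60.0
    tm_target: float = 58.0
    indel_offset: int = 3
    min_terminal_mm: int = 3
    terminal_window: int = 3
    amplicon_min: int = 250
    amplicon_max: int = 600
    tm_pair_tolerance: float = 3.0
    thermo: ThermoParams = DEFAULT_THERMO

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValidationError("min_len > max_len")
        if not (self.tm_min <= self.tm_target <= self.tm_max):
            raise ValidationError("tm_target must lie within [tm_min, tm_max]")
        if self.terminal_window < min(self.min_terminal_mm, 3):
            raise ValidationError("terminal_window too small for min_terminal_mm")
        if self.amplicon_min > self.amplicon_max:
            raise ValidationError("amplicon_min > amplicon_max")


DEFAULT_CONFIG = DesignConfig()

# Thermocycling block used with these assays, for lab handoff.
PCR_PROTOCOL = {
    "initial_denaturation": "95 C 30 s",
    "cycles": 35,
    "denaturation": "95 C 30 s",
    "annealing": "58 C 30 s",
    "extension": "68 C 30 s",
    "final_extension": "68 C 10 min",
}


@dataclass(frozen=True)
class AlleleSpecificPrimer:
    """One allele-specific primer, written 5'->3' as it would be ordered."""

    sequence: str
    allele: str          # "wild_type" | "mutant"
    orientation: str     # "forward" | "reverse"
    anchor: int          # 1-based plus-strand reference coord of the 3' terminus
    indel_offset_observed: int
    terminal_mismatches_vs_other: int
    physical: PrimerPhysical
    placement_pos: int = 0   # frame anchor of the indel placement used
    frame_start: int = 0     # 1-based own-allele coords in the design frame
    frame_end: int = 0


@dataclass(frozen=True)
class CommonPrimer:
    """The shared opposing-strand primer, matching both alleles perfectly."""

    sequence: str
    strand: str          # "+" | "-" on the original template
    anchor: int          # 1-based plus-strand reference coord of the 3' terminus
    physical: PrimerPhysical
    frame_start: int = 0
    frame_end: int = 0


@dataclass(frozen=True)
class IsPcrAssay:
    """A designed assay: two allele-specific primers plus a common primer."""

    locus: EditSpec
    wt_primer: AlleleSpecificPrimer
    mut_primer: AlleleSpecificPrimer
    common_primer: CommonPrimer
    orientation: str
    wt_amplicon_bp: int
    mut_amplicon_bp: int
    diagnostics: tuple[str, ...] = ()

    def sub_assays(self) -> list[tuple[str, str, str]]:
        """(name, forward primer, reverse primer) for the two tubes."""
        if self.orientation == "forward":
            return [
                ("wild_type", self.wt_primer.sequence, self.common_primer.sequence),
                ("mutant", self.mut_primer.sequence, self.common_primer.sequence),
            ]
        return [
            ("wild_type", self.common_primer.sequence, self.wt_primer.sequence),
            ("mutant", self.common_primer.sequence, self.mut_primer.sequence),
        ]


# ---------------------------------------------------------------------------
# Placement enumeration
# ---------------------------------------------------------------------------

def equivalent_placements(ref_seq: str, edit: EditSpec, window: int = 60) -> list[int]:
    """All 0-based edit points producing the same mutant sequence.

    For an insertion, an edit point q means inserting between ref[q-1] and
    ref[q]; for a deletion, removing ref[q] (0-based).  The normalized
    (left-aligned) record gives the smallest q; within a repeat run the
    edit can be shifted right without changing the mutant.
    """
    if edit.delta == 0:
        return [edit.pos - 1]
    mutant = (
        ref_seq[: edit.pos - 1] + edit.alt_allele + ref_seq[edit.pos - 1 + len(edit.ref_allele) :]
    )
    q0 = edit.pos  # 0-based edit point of the normalized record
    placements: list[int] = []
    if edit.delta > 0:
        ins = edit.alt_allele[len(edit.ref_allele):]
        for q in range(max(0, q0 - 1), min(len(ref_seq), q0 + window) + 1):
            cand_ins = mutant[q : q + len(ins)]
            if ref_seq[:q] + cand_ins + ref_seq[q:] == mutant:
                placements.append(q)
    else:
        ndel = -edit.delta
        for q in range(max(0, q0 - 1), min(len(ref_seq) - ndel, q0 + window) + 1):
            if ref_seq[:q] + ref_seq[q + ndel :] == mutant:
                placements.append(q)
    return placements


# ---------------------------------------------------------------------------
# Terminal mismatch counting
# ---------------------------------------------------------------------------

def terminal_mismatch_count(
    primer_seq: str,
    other_allele: str,
    anchor5: int,
    window: int = 3,
) -> int:
    """Mismatches within the primer's 3'-terminal ``window`` vs the other allele.

    The primer is anchored ungapped by its 5' end at 1-based position
    ``anchor5`` of ``other_allele`` (the homologous position, which lies in
    the sequence shared by both alleles).  Bases extending past the end of
    the template count as mismatched — there is nothing to pair with.
    """
    if anchor5 < 1 or anchor5 > len(other_allele):
        raise ValidationError(f"anchor {anchor5} outside template of length {len(other_allele)}")
    mm = 0
    w = min(window, len(primer_seq))
    for k in range(len(primer_seq) - w, len(primer_seq)):
        t_index = anchor5 - 1 + k
        if t_index >= len(other_allele) or primer_seq[k] != other_allele[t_index]:
            mm += 1
    return mm


# ---------------------------------------------------------------------------
# Candidate generation (single design frame; forward orientation semantics)
# ---------------------------------------------------------------------------

def _frame_candidates(
    wt_seq: str,
    mut_seq: str,
    edit: EditSpec,
    cfg: DesignConfig,
    orientation: str,
) -> list[tuple[AlleleSpecificPrimer, AlleleSpecificPrimer]]:
    """Enumerate (wt, mut) primer pairs in the current frame.

    Both primers of a pair share one length, chosen to bring both Tm values
    as close to ``tm_target`` as possible; their 3' termini sit
    ``indel_offset`` bases past the indel placement in each allele's own
    coordinates, so the primer always perfectly matches its own allele.
    """
    if abs(edit.delta) != 1:
        raise DesignError("not an indel: the designer targets single-base indels")
    pairs = []
    for q in equivalent_placements(wt_seq, edit):
        end = q + cfg.indel_offset  # 1-based 3' terminus in both allele frames
        if end > len(wt_seq) or end > len(mut_seq):
            continue
        best = None
        for length in range(cfg.min_len, cfg.max_len + 1):
            start = end - length + 1
            if start < 1 or start > q:  # 5' anchor must sit in the shared prefix
                continue
            wt_p = wt_seq[start - 1 : end]
            mut_p = mut_seq[start - 1 : end]
            if "N" in wt_p or "N" in mut_p:
                continue
            tm_wt = melting_temperature(wt_p, cfg.thermo)
            tm_mut = melting_temperature(mut_p, cfg.thermo)
            in_range = cfg.tm_min <= tm_wt <= cfg.tm_max and cfg.tm_min <= tm_mut <= cfg.tm_max
            dev = max(abs(tm_wt - cfg.tm_target), abs(tm_mut - cfg.tm_target))
            key = (not in_range, dev)
            if best is None or key < best[0]:
                best = (key, start, length, wt_p, mut_p)
        if best is None:
            continue
        _, start, length, wt_p, mut_p = best
        mm_wt = terminal_mismatch_count(wt_p, mut_seq, start, cfg.terminal_window)
        mm_mut = terminal_mismatch_count(mut_p, wt_seq, start, cfg.terminal_window)
        mk = lambda seq, allele, mm: AlleleSpecificPrimer(
            sequence=seq,
            allele=allele,
            orientation=orientation,
            anchor=end,  # frame coordinate; remapped by design_assay for reverse
            indel_offset_observed=cfg.indel_offset,
            terminal_mismatches_vs_other=mm,
            physical=primer_physical(seq, cfg.thermo),
            placement_pos=q,
            frame_start=start,
            frame_end=end,
        )
        pairs.append((mk(wt_p, "wild_type", mm_wt), mk(mut_p, "mutant", mm_mut)))
    if not pairs:
        raise DesignError("insufficient flank: template too short to host allele primers")
    return pairs


def candidate_allele_primers(
    wt: ReferenceSequence,
    mut: AlleleSequence,
    edit: EditSpec,
    orientation: str = "forward",
    cfg: DesignConfig = DEFAULT_CONFIG,
) -> list[AlleleSpecificPrimer]:
    """Allele-specific primer candidates for one orientation.

    For the reverse orientation the construction runs on the bottom strand
    (reverse complement frame); returned sequences are the actual 5'->3'
    oligos, with ``anchor`` mapped back to plus-strand coordinates.
    """
    edit = normalize_edit(edit, wt)
    if orientation == "forward":
        pairs = _frame_candidates(wt.sequence, mut.sequence, edit, cfg, "forward")
        return [p for pair in pairs for p in pair]
    wt_rc = reverse_complement(wt.sequence)
    mut_rc = reverse_complement(mut.sequence)
    edit_rc = infer_edit(wt_rc, mut_rc, target_id=edit.target_id, label=edit.label)
    pairs = _frame_candidates(wt_rc, mut_rc, edit_rc, cfg, "reverse")
    out = []
    for wt_p, mut_p in pairs:
        out.append(replace(wt_p, anchor=len(wt.sequence) - wt_p.frame_end + 1))
        out.append(replace(mut_p, anchor=len(mut.sequence) - mut_p.frame_end + 1))
    return out


# ---------------------------------------------------------------------------
# Common primer
# ---------------------------------------------------------------------------

def choose_common_primer(
    wt_seq: str,
    edit: EditSpec,
    pair: tuple[AlleleSpecificPrimer, AlleleSpecificPrimer],
    cfg: DesignConfig,
) -> CommonPrimer:
    """Pick the opposing-strand primer shared by both sub-assays (frame coords).

    The window must lie entirely 3' of the edited bases (so it matches both
    alleles), give a wild-type product within the configured size window,
    and have a Tm inside [tm_min, tm_max] within ``tm_pair_tolerance`` of
    both allele primers.  Preference goes to Tm closest to ``tm_target``;
    the search stops early on a near-perfect match.
    """
    wt_p, mut_p = pair
    fs = wt_p.frame_start
    lo_ce = fs + cfg.amplicon_min - 1
    hi_ce = min(len(wt_seq), fs + cfg.amplicon_max - 1)
    min_cs = max(
        edit.pos + max(len(edit.ref_allele), len(edit.alt_allele)) + 1,
        wt_p.frame_end + 1,
        mut_p.frame_end + 1,
    )
    blockers = set()
    if lo_ce > len(wt_seq):
        raise DesignError(
            "no common primer: template shorter than amplicon_min downstream of the allele primers"
        )
    allele_tms = (wt_p.physical.tm_celsius, mut_p.physical.tm_celsius)

    # walk candidate 3'-rev-primer windows from mid-sized amplicons outward
    centers = list(range(lo_ce, hi_ce + 1))
    mid = (lo_ce + hi_ce) // 2
    centers.sort(key=lambda c: abs(c - mid))
    best = None
    for ce in centers:
        for length in range(cfg.min_len, cfg.max_len + 1):
            cs = ce - length + 1
            if cs < min_cs:
                blockers.add("overlaps_edit_or_allele_primer")
                continue
            window = wt_seq[cs - 1 : ce]
            if "N" in window:
                blockers.add("ambiguous_bases")
                continue
            tm = melting_temperature(window, cfg.thermo)
            if not (cfg.tm_min <= tm <= cfg.tm_max):
                blockers.add("tm_out_of_range")
                continue
            if max(abs(tm - t) for t in allele_tms) > cfg.tm_pair_tolerance:
                blockers.add("tm_pairing_tolerance")
                continue
            dev = abs(tm - cfg.tm_target)
            if best is None or dev < best[0]:
                best = (dev, cs, ce, window)
            if dev <= 0.5:
                break
        if best is not None and best[0] <= 0.5:
            break
    if best is None:
        named = ", ".join(sorted(blockers)) or "no window in amplicon range"
        raise DesignError(f"no common primer (binding constraints: {named})")
    _, cs, ce, window = best
    seq = reverse_complement(window)
    return CommonPrimer(
        sequence=seq,
        strand="-",  # frame-relative; design_assay remaps for reverse orientation
        anchor=cs,
        physical=primer_physical(seq, cfg.thermo),
        frame_start=cs,
        frame_end=ce,
    )


# ---------------------------------------------------------------------------
# Full assay design
# ---------------------------------------------------------------------------

def design_assay(
    wt: ReferenceSequence,
    edit: EditSpec,
    cfg: DesignConfig = DEFAULT_CONFIG,
) -> IsPcrAssay:
    """Design a complete indel-selective assay for one single-base indel.

    Forward orientation is tried first; if no placement gives both allele
    primers at least ``min_terminal_mm`` 3'-terminal mismatches (or no
    common primer fits), the construction is retried on the bottom strand.
    Among viable pairs the one with the highest min-over-alleles terminal
    mismatch count wins, ties broken by Tm closeness to ``tm_target``.
    """
    edit = normalize_edit(edit, wt)
    if abs(edit.delta) != 1:
        raise DesignError("not an indel: the designer targets single-base indels")
    mut = apply_edit(wt, edit)

    diagnostics: list[str] = []
    best_by_orientation: dict[str, int] = {}

    for orientation in ("forward", "reverse"):
        if orientation == "forward":
            f_wt, f_mut, f_edit = wt.sequence, mut.sequence, edit
        else:
            f_wt = reverse_complement(wt.sequence)
            f_mut = reverse_complement(mut.sequence)
            f_edit = infer_edit(f_wt, f_mut, target_id=edit.target_id, label=edit.label)
        try:
            pairs = _frame_candidates(f_wt, f_mut, f_edit, cfg, orientation)
        except DesignError as exc:
            diagnostics.append(f"{orientation}: {exc}")
            best_by_orientation[orientation] = -1
            continue

        def pair_score(pair):
            wt_p, mut_p = pair
            mm = min(wt_p.terminal_mismatches_vs_other, mut_p.terminal_mismatches_vs_other)
            tm_dev = max(
                abs(wt_p.physical.tm_celsius - cfg.tm_target),
                abs(mut_p.physical.tm_celsius - cfg.tm_target),
            )
            return (-mm, tm_dev)

        pairs.sort(key=pair_score)
        best_mm = min(
            pairs[0][0].terminal_mismatches_vs_other,
            pairs[0][1].terminal_mismatches_vs_other,
        )
        best_by_orientation[orientation] = best_mm
        if best_mm < cfg.min_terminal_mm:
            diagnostics.append(
                f"{orientation}: best pair reaches only {best_mm} terminal mismatches "
                f"(need {cfg.min_terminal_mm})"
            )
            continue

        for pair in pairs:
            mm = min(pair[0].terminal_mismatches_vs_other, pair[1].terminal_mismatches_vs_other)
            if mm < cfg.min_terminal_mm:
                break
            try:
                common = choose_common_primer(f_wt, f_edit, pair, cfg)
            except DesignError as exc:
                diagnostics.append(f"{orientation}: {exc}")
                continue
            wt_p, mut_p = pair
            wt_amp = common.frame_end - wt_p.frame_start + 1
            mut_amp = wt_amp + edit.delta
            for p in pair:
                tm = p.physical.tm_celsius
                if not (cfg.tm_min <= tm <= cfg.tm_max):
                    diagnostics.append(
                        f"{p.allele} primer Tm {tm:.1f} C outside [{cfg.tm_min}, {cfg.tm_max}]"
                    )
            if orientation == "reverse":
                n_wt, n_mut = len(wt.sequence), len(mut.sequence)
                wt_p = replace(wt_p, anchor=n_wt - wt_p.frame_end + 1)
                mut_p = replace(mut_p, anchor=n_mut - mut_p.frame_end + 1)
                common = replace(common, strand="+", anchor=n_wt - common.frame_start + 1)
            return IsPcrAssay(
                locus=edit,
                wt_primer=wt_p,
                mut_primer=mut_p,
                common_primer=common,
                orientation=orientation,
                wt_amplicon_bp=wt_amp,
                mut_amplicon_bp=mut_amp,
                diagnostics=tuple(diagnostics),
            )
    raise UndesignableLocusError(
        "undesignable locus: best terminal mismatches "
        + ", ".join(f"{o}={m}" for o, m in best_by_orientation.items())
        + f" (need {cfg.min_terminal_mm}); " + "; ".join(diagnostics),
        best_by_orientation,
    )
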