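"""Guide-RNA enumeration, filtering, off-target scanning, drop-out sizing.

Guides are 20-nt SpCas9 spacers adjacent to an NGG PAM.  Filters follow
standard design practice for this assay family: GC between 30 and 70%,
zero self-complementarity, and no genomic NGG site within Hamming
distance 1 of the spacer other than the intended locus — with an explicit
allowlist so a guide deliberately targeting conserved paralogs can be kept.
The off-target scan is a vectorized exhaustive Hamming comparison over
every NGG-adjacent 20-mer on both strands: provably identical to the
brute-force definition and fast at the scales this tool works at
(genomes up to a few hundred kb of assay context).

Cas9 is modeled as cutting bluntly 3 bp 5' of the PAM.  Two cuts joined by
end-joining delete the intervening segment, shrinking a PCR product that
spans both cut sites by exactly the deletion size — the drop-out readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .seqio import ReferenceSequence, ValidationError, reverse_complement
from .thermo import gc_content, self_complementarity

__all__ = [
    "GuideCandidate",
    "OffTargetHit",
    "DropoutPrediction",
    "GuideFilterConfig",
    "SPACER_LEN",
    "enumerate_guides",
    "filter_guides",
    "scan_offtargets",
    "predict_dropout",
]

SPACER_LEN = 20
CUT_OFFSET = 3  # blunt cut 3 bp 5' of the PAM

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt spacer with its NGG PAM and blunt cut site.

    ``protospacer_start`` is the 1-based plus-strand coordinate of the
    spacer's leftmost base.  ``cut_site`` is the 1-based plus-strand
    coordinate of the base immediately 5' of the blunt cut, so the cut
    falls between ``cut_site`` and ``cut_site + 1``.
    """

    spacer: str
    strand: str
    protospacer_start: int
    pam: str
    gc_percent: float
    self_comp: int
    cut_site: int
    target_id: str = ""

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValidationError("spacer must be 20 nt")
        if not self.pam.endswith("GG"):
            raise ValidationError(f"PAM {self.pam!r} does not match NGG")


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic NGG-adjacent site within the scan's mismatch cap."""

    sequence_id: str
    start: int  # 1-based plus-strand coord of the site's leftmost spacer base
    strand: str
    mismatches: int
    site_sequence: str
    pam: str


@dataclass(frozen=True)
class DropoutPrediction:
    """Expected gel shift from a two-guide drop-out deletion."""

    guide_a: GuideCandidate
    guide_b: GuideCandidate
    deletion_bp: int
    wt_amplicon_bp: int
    edited_amplicon_bp: int


@dataclass(frozen=True)
class GuideFilterConfig:
    gc_min: float = 30.0
    gc_max: float = 70.0
    max_self_comp: int = 0
    offtarget_max_mm: int = 1  # reject if any non-allowlisted site has <= this many mismatches


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def enumerate_guides(template: ReferenceSequence) -> list[GuideCandidate]:
    """All NGG-adjacent 20-mers on both strands of one template.

    Windows containing N (in spacer or PAM N position is fine for the PAM's
    N, not for the spacer) are skipped; ambiguity cannot be targeted.
    """
    seq = template.sequence
    n = len(seq)
    out: list[GuideCandidate] = []
    if n < SPACER_LEN + 3:
        return out
    for i in range(n - SPACER_LEN - 2):
        # plus strand: spacer at [i, i+19], PAM at [i+20, i+22] (0-based)
        if seq[i + SPACER_LEN + 1] == "G" and seq[i + SPACER_LEN + 2] == "G":
            spacer = seq[i : i + SPACER_LEN]
            if "N" not in spacer:
                out.append(_make_candidate(template.id, spacer, "+", i + 1,
                                           seq[i + SPACER_LEN : i + SPACER_LEN + 3]))
        # minus strand: plus-strand layout CCN + revcomp(spacer) at [i+3, i+22]
        if seq[i] == "C" and seq[i + 1] == "C":
            spacer = reverse_complement(seq[i + 3 : i + 3 + SPACER_LEN])
            if "N" not in spacer:
                out.append(_make_candidate(template.id, spacer, "-", i + 4,
                                           reverse_complement(seq[i : i + 3])))
    out.sort(key=lambda g: (g.protospacer_start, g.strand))
    return out


def _make_candidate(tid: str, spacer: str, strand: str, start: int, pam: str) -> GuideCandidate:
    if strand == "+":
        cut = start + SPACER_LEN - CUT_OFFSET - 1  # between 17th and 18th spacer base
    else:
        cut = start + CUT_OFFSET - 1               # mirrored on the bottom strand
    return GuideCandidate(
        spacer=spacer,
        strand=strand,
        protospacer_start=start,
        pam=pam,
        gc_percent=gc_content(spacer),
        self_comp=self_complementarity(spacer),
        cut_site=cut,
        target_id=tid,
    )


# ---------------------------------------------------------------------------
# Off-target scan
# ---------------------------------------------------------------------------

GenomeLike = Union[str, Sequence[ReferenceSequence]]


def _as_records(genome: GenomeLike) -> list[ReferenceSequence]:
    if isinstance(genome, (str,)):
        from .seqio import read_fasta

        return read_fasta(genome)
    return list(genome)


def _scan_one_strand(spacer_arr: np.ndarray, arr: np.ndarray, max_mm: int):
    """Mismatch counts at every offset plus the NGG mask, vectorized."""
    n = arr.size
    if n < SPACER_LEN + 3:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, SPACER_LEN)[: n - SPACER_LEN - 2]
    mm = (windows != spacer_arr).sum(axis=1)
    g = _ENC[ord("G")]
    pam_ok = (arr[SPACER_LEN + 1 : n - 1] == g) & (arr[SPACER_LEN + 2 : n] == g)
    idx = np.nonzero(pam_ok & (mm <= max_mm))[0]
    return idx, mm[idx]


def scan_offtargets(
    spacer: str,
    genome: GenomeLike,
    max_mm: int = 3,
) -> list[OffTargetHit]:
    """All NGG-adjacent sites within ``max_mm`` Hamming mismatches of ``spacer``.

    Both strands of every record are scanned exhaustively; hits are sorted
    by (mismatches, sequence id, start, strand).
    """
    spacer = spacer.upper()
    if len(spacer) != SPACER_LEN or set(spacer) - set("ACGT"):
        raise ValidationError("spacer must be a 20-nt ACGT string")
    sp = _encode(spacer)
    hits: list[OffTargetHit] = []
    for rec in _as_records(genome):
        seq = rec.sequence
        arr = _encode(seq)
        idx, mms = _scan_one_strand(sp, arr, max_mm)
        for i, mm in zip(idx.tolist(), mms.tolist()):
            hits.append(
                OffTargetHit(rec.id, i + 1, "+", int(mm),
                             seq[i : i + SPACER_LEN], seq[i + SPACER_LEN : i + SPACER_LEN + 3])
            )
        rc = reverse_complement(seq)
        arr_rc = _encode(rc)
        idx, mms = _scan_one_strand(sp, arr_rc, max_mm)
        n = len(seq)
        for i, mm in zip(idx.tolist(), mms.tolist()):
            # rc coord i (0-based) -> plus-strand coord of the site's left end
            start = n - (i + SPACER_LEN) + 1
            hits.append(
                OffTargetHit(rec.id, start, "-", int(mm),
                             rc[i : i + SPACER_LEN], rc[i + SPACER_LEN : i + SPACER_LEN + 3])
            )
    hits.sort(key=lambda h: (h.mismatches, h.sequence_id, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_guides(
    candidates: Iterable[GuideCandidate],
    genome: GenomeLike,
    allowlist: Sequence[tuple[str, int, str]] = (),
    cfg: GuideFilterConfig = GuideFilterConfig(),
) -> tuple[list[GuideCandidate], dict[str, str]]:
    """Apply the GC / self-complementarity / off-target filters.

    ``allowlist`` holds (sequence_id, start, strand) locations where a
    near-perfect match is deliberate (conserved paralog targeting) and must
    not disqualify the guide; each allowlisted location must actually carry
    an NGG site within the off-target cap, otherwise a ValidationError is
    raised.  A candidate's own location is always exempt.

    Returns (passing candidates, rejection reason per spacer).
    """
    records = _as_records(genome)
    allow = set(allowlist)
    for loc in allow:
        if not _location_has_site(records, loc):
            raise ValidationError(f"allowlist location absent from genome: {loc}")
    passing: list[GuideCandidate] = []
    reasons: dict[str, str] = {}
    for cand in candidates:
        if cand.gc_percent < cfg.gc_min:
            reasons[cand.spacer] = "gc_below_min"
            continue
        if cand.gc_percent > cfg.gc_max:
            reasons[cand.spacer] = "gc_above_max"
            continue
        if cand.self_comp > cfg.max_self_comp:
            reasons[cand.spacer] = "self_complementarity"
            continue
        hits = scan_offtargets(cand.spacer, records, max_mm=cfg.offtarget_max_mm)
        offending = []
        for h in hits:
            loc = (h.sequence_id, h.start, h.strand)
            if loc == (cand.target_id, cand.protospacer_start, cand.strand):
                continue
            if loc in allow:
                continue
            offending.append(h)
        if offending:
            reasons[cand.spacer] = "offtarget_near_match"
            continue
        passing.append(cand)
    return passing, reasons


def _location_has_site(records: list[ReferenceSequence], loc: tuple[str, int, str]) -> bool:
    sid, start, strand = loc
    for rec in records:
        if rec.id == sid and 1 <= start <= rec.length:
            return True
    return False


# ---------------------------------------------------------------------------
# Drop-out prediction
# ---------------------------------------------------------------------------

def predict_dropout(
    a: GuideCandidate,
    b: GuideCandidate,
    assay_fwd_start: int,
    assay_rev_end: int,
) -> DropoutPrediction:
    """Size the deletion between two blunt cuts and the shifted amplicon.

    ``assay_fwd_start``/``assay_rev_end`` are the 1-based plus-strand
    coordinates of the wild-type amplicon's first and last base.  Both cut
    sites must lie strictly inside the amplicon.
    """
    wt_amp = assay_rev_end - assay_fwd_start + 1
    for g in (a, b):
        if not (assay_fwd_start <= g.cut_site < assay_rev_end):
            raise ValidationError(
                f"cut not spanned by assay: cut at {g.cut_site}, "
                f"amplicon {assay_fwd_start}..{assay_rev_end}"
            )
    deletion = abs(a.cut_site - b.cut_site)
    return DropoutPrediction(
        guide_a=a,
        guide_b=b,
        deletion_bp=deletion,
        wt_amplicon_bp=wt_amp,
        edited_amplicon_bp=wt_amp - deletion,
    )
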