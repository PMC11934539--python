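"""Virtual PCR: binding-site search, the 3'-extension rule, amplicon prediction.

The engine encodes the selectivity principle behind indel-selective PCR as a
binary annealing/extension rule: a primer binds a site only if its 3'-terminal
``terminal_perfect`` bases pair exactly, while up to ``max_internal_mm``
mismatches are tolerated further 5' (distal mismatches still anneal; terminal
ones block polymerase extension).  The readout is binary band presence, which
matches what an agarose gel reports — no thermodynamic extension-probability
model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd

from .seqio import AlleleSequence, ReferenceSequence, ValidationError, reverse_complement

__all__ = [
    "PcrStringency",
    "BindingSite",
    "AmpliconPrediction",
    "find_binding_sites",
    "virtual_pcr",
    "predict_assay_bands",
]


@dataclass(frozen=True)
class PcrStringency:
    """Knobs of the binary annealing/extension rule."""

    terminal_perfect: int = 3
    max_internal_mm: int = 2
    max_product_bp: int = 5000

    def __post_init__(self) -> None:
        if self.terminal_perfect < 1:
            raise ValidationError("terminal_perfect must be >= 1")
        if self.max_internal_mm < 0 or self.max_product_bp < 1:
            raise ValidationError("invalid stringency parameters")


DEFAULT_STRINGENCY = PcrStringency()


@dataclass(frozen=True)
class BindingSite:
    """One qualifying primer annealing site.

    ``start``/``end`` are 1-based inclusive plus-strand coordinates of the
    template window covered by the primer; on the minus strand the primer's
    3' terminus sits at ``start``.
    """

    start: int
    end: int
    strand: str  # "+" or "-"
    mismatches: int


@dataclass(frozen=True)
class AmpliconPrediction:
    """Outcome of virtual PCR of one primer pair on one template."""

    template_id: str
    allele_label: str
    fwd_site: BindingSite | None
    rev_site: BindingSite | None
    size_bp: int
    amplifies: bool
    failure_reason: str = ""


def find_binding_sites(
    primer: str,
    template: str,
    stringency: PcrStringency = DEFAULT_STRINGENCY,
) -> list[BindingSite]:
    """Scan both strands for sites satisfying the extension rule.

    A plus-strand site has the primer's 3' end at its right edge; a
    minus-strand site (primer annealing the plus strand shown) has the 3'
    end at its left edge.
    """
    primer = primer.upper()
    template = template.upper()
    lp, lt = len(primer), len(template)
    if lp > lt:
        raise ValidationError("primer longer than template")
    tp = min(stringency.terminal_perfect, lp)
    sites: list[BindingSite] = []

    tail = primer[-tp:]                      # 3' window, plus-strand sense
    head_rc = reverse_complement(tail)       # 3' window as seen on plus strand for minus sites
    primer_rc = reverse_complement(primer)

    for i in range(lt - lp + 1):
        # plus strand: template[i:i+lp] vs primer; 3' end at the right
        if template[i + lp - tp : i + lp] == tail:
            mm = sum(a != b for a, b in zip(primer[: lp - tp], template[i : i + lp - tp]))
            if mm <= stringency.max_internal_mm:
                sites.append(BindingSite(i + 1, i + lp, "+", mm))
        # minus strand: revcomp(primer) vs template window; 3' end at the left
        if template[i : i + tp] == head_rc:
            mm = sum(a != b for a, b in zip(primer_rc[tp:], template[i + tp : i + lp]))
            if mm <= stringency.max_internal_mm:
                sites.append(BindingSite(i + 1, i + lp, "-", mm))
    return sites


def _template_fields(template: Union[str, ReferenceSequence, AlleleSequence]) -> tuple[str, str, str]:
    if isinstance(template, ReferenceSequence):
        return template.sequence, template.id, "wild_type"
    if isinstance(template, AlleleSequence):
        return template.sequence, template.base_id, template.edit_label
    return template, "template", ""


def virtual_pcr(
    fwd: str,
    rev: str,
    template: Union[str, ReferenceSequence, AlleleSequence],
    stringency: PcrStringency = DEFAULT_STRINGENCY,
) -> list[AmpliconPrediction]:
    """Predict all products of a primer pair on one template.

    Pairs every plus-strand forward site with every downstream minus-strand
    reverse site within ``max_product_bp``.  An empty list means no band.
    """
    seq, tid, label = _template_fields(template)
    fwd_sites = [s for s in find_binding_sites(fwd, seq, stringency) if s.strand == "+"]
    rev_sites = [s for s in find_binding_sites(rev, seq, stringency) if s.strand == "-"]
    products: list[AmpliconPrediction] = []
    for f in fwd_sites:
        for r in rev_sites:
            size = r.end - f.start + 1
            if size >= max(f.end - f.start, r.end - r.start) + 1 and size <= stringency.max_product_bp:
                products.append(
                    AmpliconPrediction(
                        template_id=tid,
                        allele_label=label,
                        fwd_site=f,
                        rev_site=r,
                        size_bp=size,
                        amplifies=True,
                    )
                )
    return products


def predict_assay_bands(
    assay,
    alleles: Sequence[Union[ReferenceSequence, AlleleSequence]],
    stringency: PcrStringency = DEFAULT_STRINGENCY,
) -> pd.DataFrame:
    """Simulate the two-tube gel readout of an assay on a set of alleles.

    One row per (allele, sub-assay); a heterozygote is represented by
    passing both alleles and shows a band in both sub-assays.  Raises
    ValidationError when an allele comes from a different locus than the
    assay.
    """
    rows = []
    for allele in alleles:
        seq, tid, label = _template_fields(allele)
        if tid != assay.locus.target_id:
            raise ValidationError(
                f"allele {tid!r} does not belong to assay locus {assay.locus.target_id!r}"
            )
        for sub, fwd, rev in assay.sub_assays():
            prods = virtual_pcr(fwd, rev, seq, stringency)
            rows.append(
                {
                    "template_id": tid,
                    "allele": label or "wild_type",
                    "sub_assay": sub,
                    "amplifies": bool(prods),
                    "size_bp": prods[0].size_bp if prods else 0,
                    "n_products": len(prods),
                }
            )
    return pd.DataFrame(rows)
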