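"""Sequence and edit I/O.

Templates are plain uppercase DNA strings with stable identifiers; edits are
VCF-style anchored REF/ALT records.  Because a single-base indel inside a
repeat run has many equivalent placements, every edit is left-aligned to a
canonical minimal representation before any primer design happens — primer
placement is only well defined on the normalized record.

Coordinates are 1-based inclusive in all user-facing records (the
molecular-biology convention); internal slicing is 0-based half-open.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "ReferenceSequence",
    "EditSpec",
    "AlleleSequence",
    "ValidationError",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_edits_tsv",
    "write_edits_tsv",
    "read_vcf_edits",
    "normalize_edit",
    "apply_edit",
    "infer_edit",
]


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, name: str) -> str:
    up = seq.upper()
    for off, ch in enumerate(up):
        if ch not in VALID_BASES:
            raise ValidationError(
                f"illegal character {ch!r} in record {name!r} at offset {off}"
            )
    return up


@dataclass(frozen=True)
class ReferenceSequence:
    """A named wild-type DNA template (a gene or amplicon region)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_alphabet(self.sequence, self.id))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EditSpec:
    """A single-locus sequence change in VCF-style anchored form.

    ``pos`` is the 1-based position of the first base of ``ref_allele`` on
    the target.  A record with equal-length single-base alleles is a
    substitution: storable, but rejected by the indel-selective designer.
    """

    target_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValidationError("ref_allele and alt_allele must be non-empty")
        object.__setattr__(self, "ref_allele", _check_alphabet(self.ref_allele, self.label or self.target_id))
        object.__setattr__(self, "alt_allele", _check_alphabet(self.alt_allele, self.label or self.target_id))
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref_allele) > 1 and len(self.alt_allele) > 1:
            raise ValidationError(
                "complex records (both alleles longer than 1) are not supported"
            )

    @property
    def delta(self) -> int:
        """Net size change, |ALT| - |REF| (bases)."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def is_indel(self) -> bool:
        return self.delta != 0

    @property
    def ref_end(self) -> int:
        """1-based inclusive last reference base covered by ref_allele."""
        return self.pos + len(self.ref_allele) - 1


@dataclass(frozen=True)
class AlleleSequence:
    """A mutant (or wild-type) allele with a map back to reference coordinates.

    ``coord_map[i]`` gives the 1-based reference coordinate of mutant base
    ``i+1``, or ``None`` for inserted bases with no reference counterpart.
    """

    base_id: str
    edit_label: str
    sequence: str
    coord_map: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_alphabet(self.sequence, self.base_id))

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a (multi-)FASTA file into ReferenceSequence records, uppercased.

    Raises ValidationError for an empty file or a record containing a
    character outside A/C/G/T/N.
    """
    records = [
        ReferenceSequence(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValidationError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[ReferenceSequence | AlleleSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            name = rec.id if isinstance(rec, ReferenceSequence) else f"{rec.base_id}|{rec.edit_label}"
            fh.write(f">{name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Edit records: TSV dialect and VCF subset
# ---------------------------------------------------------------------------

EDITS_TSV_COLUMNS = ("target_id", "pos", "ref", "alt", "label")


def read_edits_tsv(path: str | Path) -> list[EditSpec]:
    """Read the 5-column edits dialect: target_id, pos, ref, alt, label.

    A header row matching the column names is permitted and skipped.
    """
    edits: list[EditSpec] = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "target_id":
                continue
            if len(row) < 4:
                raise ValidationError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            label = row[4] if len(row) > 4 else ""
            try:
                pos = int(row[1])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: pos is not an integer") from exc
            edits.append(EditSpec(row[0], pos, row[2], row[3], label))
    return edits


def write_edits_tsv(edits: Iterable[EditSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EDITS_TSV_COLUMNS) + "\n")
        for e in edits:
            fh.write(f"{e.target_id}\t{e.pos}\t{e.ref_allele}\t{e.alt_allele}\t{e.label}\n")


def read_vcf_edits(path: str | Path) -> list[EditSpec]:
    """Read SNV/indel records from a VCF 4.x file (CHROM/POS/REF/ALT; INFO ignored).

    Multi-allelic records contribute one EditSpec per ALT; symbolic and
    breakend ALTs are rejected.
    """
    import pysam

    edits: list[EditSpec] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if not set(alt.upper()) <= set("ACGTN"):
                    raise ValidationError(
                        f"unsupported ALT {alt!r} at {rec.chrom}:{rec.pos} (symbolic alleles rejected)"
                    )
                edits.append(
                    EditSpec(rec.chrom, rec.pos, rec.ref, alt, label=rec.id or "")
                )
    return edits


# ---------------------------------------------------------------------------
# Normalization and application
# ---------------------------------------------------------------------------

def _check_ref_match(edit: EditSpec, ref: ReferenceSequence) -> None:
    start = edit.pos - 1
    end = start + len(edit.ref_allele)
    if start < 0 or end > ref.length:
        raise ValidationError(
            f"edit {edit.label or edit.target_id} out of bounds on {ref.id}"
        )
    observed = ref.sequence[start:end]
    if observed != edit.ref_allele:
        raise ValidationError(
            f"REF mismatch at {ref.id}:{edit.pos}: record says {edit.ref_allele!r}, "
            f"template has {observed!r}"
        )


def normalize_edit(edit: EditSpec, ref: ReferenceSequence) -> EditSpec:
    """Left-align an edit to its canonical minimal VCF-style representation.

    Trailing bases shared by REF and ALT are trimmed, the record is shifted
    to the 5'-most equivalent placement within its repeat run, and leading
    shared bases beyond the single anchor are trimmed.  Idempotent; a
    substitution is returned trimmed but unshifted.
    """
    _check_ref_match(edit, ref)
    pos, ra, aa = edit.pos, edit.ref_allele, edit.alt_allele
    seq = ref.sequence

    while True:
        # trim shared trailing base
        while len(ra) > 1 and len(aa) > 1 and ra[-1] == aa[-1]:
            ra, aa = ra[:-1], aa[:-1]
        # shift left: if both alleles end in the same base, rotate in the
        # preceding reference base
        if len(ra) != len(aa) and ra[-1] == aa[-1] and pos > 1:
            prev = seq[pos - 2]
            ra, aa = prev + ra[:-1], prev + aa[:-1]
            pos -= 1
            continue
        break
    # trim shared leading bases beyond the anchor
    while len(ra) > 1 and len(aa) > 1 and ra[0] == aa[0]:
        ra, aa = ra[1:], aa[1:]
        pos += 1
    # re-anchor an unanchored indel (possible only at pos == 1 input)
    if len(ra) != len(aa) and (ra[0] != aa[0]) and pos > 1:
        prev = seq[pos - 2]
        ra, aa = prev + ra, prev + aa
        pos -= 1
        # anchoring may expose a shared trailing base again
        return normalize_edit(replace(edit, pos=pos, ref_allele=ra, alt_allele=aa), ref)
    return replace(edit, pos=pos, ref_allele=ra, alt_allele=aa)


def apply_edit(ref: ReferenceSequence, edit: EditSpec) -> AlleleSequence:
    """Construct the mutant allele carrying ``edit``, with a coordinate map.

    Inserted bases map to ``None``; all other mutant bases map to their
    1-based reference coordinate.
    """
    _check_ref_match(edit, ref)
    start = edit.pos - 1  # 0-based
    end = start + len(edit.ref_allele)
    mutant = ref.sequence[:start] + edit.alt_allele + ref.sequence[end:]

    coord: list[Optional[int]] = list(range(1, start + 1))
    # anchored alleles share their leading base; map shared prefix of the
    # alt allele onto the corresponding reference bases
    shared = 0
    while (
        shared < min(len(edit.ref_allele), len(edit.alt_allele))
        and edit.ref_allele[shared] == edit.alt_allele[shared]
    ):
        shared += 1
    coord.extend(range(start + 1, start + shared + 1))
    coord.extend([None] * (len(edit.alt_allele) - shared))
    coord.extend(range(end + 1, ref.length + 1))

    return AlleleSequence(
        base_id=ref.id,
        edit_label=edit.label or f"{edit.pos}{edit.ref_allele}>{edit.alt_allele}",
        sequence=mutant,
        coord_map=tuple(coord),
    )


def infer_edit(wt: str, mut: str, target_id: str = "", label: str = "") -> EditSpec:
    """Infer the anchored EditSpec relating two alleles differing by one
    contiguous substitution or indel.

    Used to re-express an edit in the reverse-complement frame.  Raises
    ValidationError if the alleles are identical or differ in more than one
    contiguous block.
    """
    if wt == mut:
        raise ValidationError("alleles are identical; no edit to infer")
    lp = 0
    while lp < min(len(wt), len(mut)) and wt[lp] == mut[lp]:
        lp += 1
    ls = 0
    while (
        ls < min(len(wt), len(mut)) - lp
        and wt[len(wt) - 1 - ls] == mut[len(mut) - 1 - ls]
    ):
        ls += 1
    ref_block = wt[lp : len(wt) - ls]
    alt_block = mut[lp : len(mut) - ls]
    if not ref_block or not alt_block:
        # pure indel: anchor on the preceding base (or following, at pos 1)
        if lp > 0:
            lp -= 1
            ref_block = wt[lp : len(wt) - ls]
            alt_block = mut[lp : len(mut) - ls]
        else:
            ref_block = wt[: len(wt) - ls + 1]
            alt_block = mut[: len(mut) - ls + 1]
    edit = EditSpec(target_id, lp + 1, ref_block, alt_block, label)
    return normalize_edit(edit, ReferenceSequence(id=target_id or "ref", sequence=wt))
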