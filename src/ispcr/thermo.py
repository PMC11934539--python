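"""Primer physical properties used as design filters.

Melting temperature follows the unified nearest-neighbor model
(Allawi & SantaLucia 1997 duplex parameters, SantaLucia 1998 monovalent-salt
entropy correction), evaluated for a non-self-complementary duplex at total
strand concentration C_T with the usual C_T/4 approximation:

    Tm = 1000 * dH / (dS + 0.368 * (N-1) * ln[Na+] + R * ln(C_T/4)) - 273.15

with dH in kcal/mol, dS in cal/(mol K), R = 1.987 cal/(mol K), [Na+] in M.
Defaults (50 mM monovalent, 250 nM primer) are standard PCR-design values.

Self-complementarity is operationalized as the number of ungapped
reverse-complement stem matches of a fixed window length within the
sequence — a hairpin/homodimer proxy; 0 means no stem of ``min_stem`` or
longer exists anywhere in the primer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from .seqio import ValidationError, reverse_complement

__all__ = [
    "ThermoParams",
    "PrimerPhysical",
    "gc_content",
    "melting_temperature",
    "self_complementarity",
    "primer_physical",
    "NN_UNIFIED",
]

# Unified nearest-neighbor duplex parameters (dH kcal/mol, dS cal/mol/K),
# Allawi & SantaLucia (1997), with terminal initiation terms.
NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)   # terminal A·T pair
_INIT_GC = (0.1, -2.8)  # terminal G·C pair
_R_GAS = 1.987  # cal/(mol K)


@dataclass(frozen=True)
class ThermoParams:
    """Solution conditions for the Tm model."""

    monovalent_mM: float = 50.0
    primer_nM: float = 250.0
    nn_table_id: str = "unified-1997"

    def __post_init__(self) -> None:
        if self.monovalent_mM <= 0 or self.primer_nM <= 0:
            raise ValidationError("concentrations must be strictly positive")


DEFAULT_THERMO = ThermoParams()


@dataclass(frozen=True)
class PrimerPhysical:
    """Computed physical properties of one primer."""

    sequence: str
    length: int
    gc_percent: float
    tm_celsius: float
    self_comp: int


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValidationError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValidationError(f"sequence contains non-ACGT characters: {seq!r}")
    return seq


def gc_content(seq: str) -> float:
    """G+C percentage of a primer or spacer, in [0, 100]."""
    seq = _check_seq(seq)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


@lru_cache(maxsize=65536)
def _tm_cached(seq: str, monovalent_mM: float, primer_nM: float) -> float:
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        init = _INIT_GC if end in "GC" else _INIT_AT
        dh += init[0]
        ds += init[1]
    for i in range(len(seq) - 1):
        h, s = NN_UNIFIED[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM * 1e-3)
    k = primer_nM * 1e-9 / 4.0
    return 1000.0 * dh / (ds + _R_GAS * math.log(k)) - 273.15


def melting_temperature(seq: str, params: ThermoParams = DEFAULT_THERMO) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius."""
    seq = _check_seq(seq)
    if len(seq) < 8:
        raise ValidationError(f"sequence too short for a meaningful Tm ({len(seq)} < 8 nt)")
    return _tm_cached(seq, params.monovalent_mM, params.primer_nM)


def self_complementarity(seq: str, min_stem: int = 4) -> int:
    """Count ungapped reverse-complement stem matches within ``seq``.

    Counts unordered position pairs (i <= j) whose ``min_stem``-length
    windows are exact reverse complements of each other.  0 means the
    sequence contains no self-pairing stem of ``min_stem`` nt or longer.
    """
    seq = _check_seq(seq)
    if min_stem < 2:
        raise ValidationError("min_stem must be >= 2")
    n = len(seq)
    count = 0
    for i in range(n - min_stem + 1):
        win = seq[i : i + min_stem]
        rc = reverse_complement(win)
        for j in range(i, n - min_stem + 1):
            if seq[j : j + min_stem] == rc:
                count += 1
    return count


def primer_physical(seq: str, params: ThermoParams = DEFAULT_THERMO, min_stem: int = 4) -> PrimerPhysical:
    """Bundle GC%, Tm and self-complementarity for one primer."""
    seq = _check_seq(seq)
    return PrimerPhysical(
        sequence=seq,
        length=len(seq),
        gc_percent=gc_content(seq),
        tm_celsius=melting_temperature(seq, params),
        self_comp=self_complementarity(seq),
    )
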