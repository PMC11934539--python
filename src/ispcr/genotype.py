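"""Zygosity calling from two-tube gel observations.

Each sample/locus is scored in two PCRs — a wild-type-selective tube and a
mutant-selective tube.  Band presence in each maps to a genotype by a fixed
truth table: a band in only the wild-type tube is homozygous reference, only
the mutant tube homozygous edited, both tubes heterozygous.  No band in
either tube is reported as ``no_amplification`` rather than a genotype,
because a failed DNA prep and a novel third allele are indistinguishable on
the gel; any uninterpretable lane makes the call ``indeterminate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .seqio import ValidationError

__all__ = [
    "BandObservation",
    "GenotypeCall",
    "BAND_STATES",
    "CALLS",
    "call_genotype",
    "batch_genotype",
]

BAND_STATES = ("present", "absent", "failed")
CALLS = ("hom_ref", "hom_alt", "het", "no_amplification", "indeterminate")


@dataclass(frozen=True)
class BandObservation:
    """One sample x locus lane pair from the two sub-assays."""

    sample_id: str
    locus_id: str
    wt_band: str
    mut_band: str

    def __post_init__(self) -> None:
        for v in (self.wt_band, self.mut_band):
            if v not in BAND_STATES:
                raise ValidationError(f"band state must be one of {BAND_STATES}, got {v!r}")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    locus_id: str
    call: str


_TRUTH = {
    ("present", "present"): "het",
    ("present", "absent"): "hom_ref",
    ("absent", "present"): "hom_alt",
    ("absent", "absent"): "no_amplification",
}


def call_genotype(obs: BandObservation) -> GenotypeCall:
    """Map one band-observation pair to a zygosity call (pure function)."""
    if "failed" in (obs.wt_band, obs.mut_band):
        call = "indeterminate"
    else:
        call = _TRUTH[(obs.wt_band, obs.mut_band)]
    return GenotypeCall(obs.sample_id, obs.locus_id, call)


def batch_genotype(
    observations: pd.DataFrame,
    expected_segregation: Optional[Sequence[float]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Call genotypes for a whole screening campaign.

    ``observations`` needs columns sample_id, locus_id, wt_band, mut_band.
    Returns the per-sample calls plus a summary with per-locus counts of
    each call class.  When ``expected_segregation`` is given as the
    (hom_ref, het, hom_alt) ratio — e.g. (1, 2, 1) for a selfed
    heterozygote — a chi-square goodness-of-fit statistic over the called
    genotype classes is reported per locus (statistic and degrees of
    freedom only; interpretation is left to the user).
    """
    required = {"sample_id", "locus_id", "wt_band", "mut_band"}
    missing = required - set(observations.columns)
    if missing:
        raise ValidationError(f"observation table missing columns: {sorted(missing)}")
    dup = observations.duplicated(subset=["sample_id", "locus_id"])
    if dup.any():
        rows = observations.loc[dup, ["sample_id", "locus_id"]].iloc[0]
        raise ValidationError(
            f"duplicate (sample, locus) rows, first at {tuple(rows)}"
        )

    calls = [
        call_genotype(BandObservation(r.sample_id, r.locus_id, r.wt_band, r.mut_band))
        for r in observations.itertuples(index=False)
    ]
    calls_df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "locus_id": [c.locus_id for c in calls],
            "call": [c.call for c in calls],
        }
    )

    summary: dict = {"per_locus": {}}
    for locus, grp in calls_df.groupby("locus_id"):
        counts = {c: int((grp["call"] == c).sum()) for c in CALLS}
        entry: dict = {"counts": counts, "n": int(len(grp))}
        if expected_segregation is not None:
            ratio = list(expected_segregation)
            if len(ratio) != 3 or any(x < 0 for x in ratio) or sum(ratio) == 0:
                raise ValidationError("expected_segregation must be 3 non-negative numbers")
            observed = [counts["hom_ref"], counts["het"], counts["hom_alt"]]
            total = sum(observed)
            if total > 0:
                expected = [total * x / sum(ratio) for x in ratio]
                chi2 = stats.chisquare(observed, f_exp=expected)
                entry["chi_square"] = float(chi2.statistic)
                entry["df"] = 2
        summary["per_locus"][locus] = entry
    return calls_df, summary
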