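import pytest

from ispcr.design import DesignConfig, design_assay
from ispcr.fixtures import make_clean_indel_locus, make_dropout_locus
from ispcr.seqio import EditSpec, ReferenceSequence, apply_edit


# Toy locus from first principles: insertion of G after position 7 gives a
# mutant where both allele-specific 10-mers carry the indel at -3.
TOY_WT = "AAACGTCATGGC"
TOY_MUT = "AAACGTCGATGGC"


@pytest.fixture
def toy_wt():
    return ReferenceSequence("toy", TOY_WT)


@pytest.fixture
def toy_edit():
    return EditSpec("toy", 7, "C", "CG", "toy +1G")


@pytest.fixture
def toy_mut(toy_wt, toy_edit):
    return apply_edit(toy_wt, toy_edit)


@pytest.fixture
def toy_cfg():
    # short primers, thermodynamic constraints relaxed so geometry dominates
    return DesignConfig(
        min_len=10, max_len=10, tm_min=0.0, tm_max=100.0, tm_target=30.0,
        amplicon_min=5, amplicon_max=50, tm_pair_tolerance=100.0,
    )


@pytest.fixture(scope="session")
def dropout_locus():
    return make_dropout_locus(seed=1)


def _design_batch(n_target: int, max_attempts: int):
    designed, failures = [], 0
    seed = 0
    while len(designed) < n_target and seed < max_attempts:
        wt, edit = make_clean_indel_locus(seed)
        try:
            assay = design_assay(wt, edit)
            designed.append((wt, edit, assay))
        except Exception:
            failures += 1
        seed += 1
    return designed, failures


@pytest.fixture(scope="session")
def designed_batch():
    """>= 1000 assays designed on seeded clean-context indel loci."""
    designed, failures = _design_batch(n_target=1000, max_attempts=1200)
    assert len(designed) >= 1000, f"only {len(designed)} designable loci of 1200 seeds"
    return designed
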