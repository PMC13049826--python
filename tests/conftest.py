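import pytest

from haplotile.cohort import make_table2_cohort
from haplotile.simulate import build_reference_locus


@pytest.fixture(scope="session")
def locus():
    return build_reference_locus(seed=1)


@pytest.fixture(scope="session")
def cohort(locus):
    return make_table2_cohort(locus)


@pytest.fixture(scope="session")
def marked_cohort(locus):
    """Cohort with the benign heterozygous marker panel on haplotype 2."""
    return make_table2_cohort(locus, phasing_snvs=True)


@pytest.fixture(scope="session")
def by_id(cohort):
    return {s.sample_id: s for s in cohort}


@pytest.fixture(scope="session")
def marked_by_id(marked_cohort):
    return {s.sample_id: s for s in marked_cohort}
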