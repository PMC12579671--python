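import pytest

from rdnascan.simulate import (
    default_plan,
    demo_plan,
    make_array,
    make_canonical_unit,
    make_reference_orf,
)
from rdnascan.units import RepeatUnit

REF_SEED = 1


@pytest.fixture(scope="session")
def reference():
    """(nt, protein) of the designed 190-aa reference ORF."""
    return make_reference_orf(seed=REF_SEED)


@pytest.fixture(scope="session")
def ref_nt(reference):
    return reference[0]


@pytest.fixture(scope="session")
def ref_prot(reference):
    return reference[1]


@pytest.fixture(scope="session")
def demo_array(ref_nt):
    """Small 12-unit array with every allele kind (unit length 3 kb)."""
    plan = demo_plan(seed=REF_SEED)
    units, truth = make_array(plan, ref_nt, unit_len_bp=3_000, seed=REF_SEED)
    return plan, units, truth


@pytest.fixture(scope="session")
def demo_repeat_units(demo_array):
    _, units, _ = demo_array
    return [RepeatUnit.from_record(u) for u in units]


@pytest.fixture(scope="session")
def canonical_3kb(ref_nt):
    return make_canonical_unit(ref_nt, unit_len_bp=3_000, seed=REF_SEED)


@pytest.fixture(scope="session")
def survey_array(ref_nt):
    """The 219-unit five-chromosome plan at survey unit length."""
    plan = default_plan(seed=REF_SEED)
    units, truth = make_array(plan, ref_nt, unit_len_bp=20_000, seed=REF_SEED)
    return plan, units, truth
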