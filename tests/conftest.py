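import pytest

from dendromorph import SimulationConfig, SpecimenRecord, Taxon, synthesize_cohort

# Published sibiricus structure means (mm); the single-cornutus list makes
# the mean cornuti length equal the printed 0.188.
SIBIRICUS_MEANS = dict(
    valva_length=2.002,
    harpe_length=1.312,
    aedeagus_length_straight=3.712,
    aedeagus_length_arc=4.844,
    aedeagus_width=0.798,
    cornuti=(0.188,),
)

PINI_MEANS = dict(
    valva_length=1.356,
    harpe_length=0.339,
    aedeagus_length_straight=2.663,
    aedeagus_length_arc=3.295,
    aedeagus_width=0.576,
    cornuti=(0.243,),
)

HYBRID_MEANS = dict(
    valva_length=1.609,
    harpe_length=0.608,
    aedeagus_length_straight=3.315,
    aedeagus_length_arc=4.194,
    aedeagus_width=0.619,
    cornuti=(0.259,),
)


@pytest.fixture
def sibiricus_mean_record() -> SpecimenRecord:
    return SpecimenRecord(specimen_id="sib-mean", taxon=Taxon.SIBIRICUS, **SIBIRICUS_MEANS)


@pytest.fixture
def pini_mean_record() -> SpecimenRecord:
    return SpecimenRecord(specimen_id="pini-mean", taxon=Taxon.PINI, **PINI_MEANS)


@pytest.fixture
def hybrid_mean_record() -> SpecimenRecord:
    return SpecimenRecord(specimen_id="hyb-mean", taxon=Taxon.HYBRID, **HYBRID_MEANS)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort (33 sibiricus, 33 pini, 4 hybrids)."""
    return synthesize_cohort(SimulationConfig(seed=1))
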