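import numpy as np
import pytest

from stratpop import (
    GeneratorConfig,
    ResidenceRecord,
    SectionRecord,
    SurveyFrame,
    generate_residences,
    load_section_table,
)


@pytest.fixture(scope="session")
def bo_sections():
    """The packaged 20-section Bo City survey table."""
    return load_section_table()


@pytest.fixture(scope="session")
def bo_frame(bo_sections):
    """Synthetic residence-level frame calibrated to the Bo section margins."""
    return generate_residences(bo_sections, GeneratorConfig(seed=1))


@pytest.fixture
def toy_section():
    """A 3-residence section with occupancies (2, 2, 10)."""
    section = SectionRecord(
        name="Toy", area_km2=0.1, n_residential=3, n_structures_total=3,
        n_households=3, n_persons=14, mean_occupancy=4.67,
    )
    residences = [
        ResidenceRecord(section="Toy", persons=2),
        ResidenceRecord(section="Toy", persons=2),
        ResidenceRecord(section="Toy", persons=10),
    ]
    return SurveyFrame(sections=[section], residences=residences,
                       provenance="synthetic")


@pytest.fixture(scope="session")
def structure_counts(bo_sections):
    return np.array([s.n_residential for s in bo_sections], float)


@pytest.fixture(scope="session")
def person_totals(bo_sections):
    return np.array([s.n_persons for s in bo_sections], float)
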