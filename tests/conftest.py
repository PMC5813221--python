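import warnings

import pytest
from hypothesis import HealthCheck, settings

from allerscreen import AllergenEntry, ProteinRecord, ScoringScheme
from allerscreen.synthetic import SyntheticSpec, gen_decoy_db, legh_fixture

warnings.filterwarnings("ignore", category=DeprecationWarning)

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()  # BLOSUM50, -10/-2


@pytest.fixture(scope="session")
def leghb() -> ProteinRecord:
    return legh_fixture()


@pytest.fixture(scope="session")
def decoy_db(leghb):
    """Ten clean decoys sharing no 8-mer with leghemoglobin."""
    spec = SyntheticSpec(n_decoys=10, length_range=(90, 180), seed=42)
    entries, _ = gen_decoy_db(spec, queries=[leghb])
    return entries


def as_entry(record: ProteinRecord, name: str = "",
             status: str = "putative") -> AllergenEntry:
    """Wrap a record as a screenable allergen-tagged database entry."""
    return AllergenEntry(record=record, allergen_name=name, status=status,
                         tags=frozenset({"allergen"}))
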