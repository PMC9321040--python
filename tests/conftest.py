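import pytest
from hypothesis import HealthCheck, settings

from mitochar.codes import GeneticCode
from mitochar.reference import reference_annotation, reference_codon_counts

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return GeneticCode.invertebrate_mito()


@pytest.fixture(scope="session")
def ref_ann():
    """The published weevil mitogenome annotation (15,497 bp, circular)."""
    return reference_annotation()


@pytest.fixture(scope="session")
def ref_counts():
    """Published pooled sense-codon counts of the 13 protein-coding genes."""
    return reference_codon_counts()
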