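import pytest
from hypothesis import HealthCheck, settings

from thioburden.star import load_allele_table
from thioburden.variants import AnnotatedVariant, Zygosity

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def defs():
    """The shipped NUDT15/TPMT allele-definition table."""
    return load_allele_table()


def snv(sift=None, zyg=Zygosity.HET, gene="NUDT15", pos=48619855, ref="C", alt="T", phase=None):
    return AnnotatedVariant.make(gene, "13", pos, ref, alt, zyg, sift=sift, phase=phase)


def indel(zyg=Zygosity.HET, gene="NUDT15", pos=48611918, ref="G", alt="GGAGTC", phase=None):
    return AnnotatedVariant.make(gene, "13", pos, ref, alt, zyg, phase=phase)


@pytest.fixture
def make_snv():
    return snv


@pytest.fixture
def make_indel():
    return indel
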