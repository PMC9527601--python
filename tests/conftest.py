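import pytest

from gsicross.si_core import Haplotype, PlantGenotype, SAllele, TraitAllele

KSN_FUNCTIONAL = TraitAllele("KSN", "KSN_W", functional=True)
KSN_COPIA = TraitAllele("KSN", "ksn_copia", functional=False)
KSN_NULL = TraitAllele("KSN", "ksn_null", functional=False)


def hap(s: str, *traits: TraitAllele, anonymous: bool = False) -> Haplotype:
    return Haplotype(SAllele(s, anonymous=anonymous), tuple(traits))


def diploid(pid: str, h1: Haplotype, h2: Haplotype) -> PlantGenotype:
    return PlantGenotype.diploid(pid, h1, h2)


@pytest.fixture
def cf_seed_parent() -> PlantGenotype:
    """A continuous-flowering diploid: ksn on both haplotypes."""
    return diploid("cf_mother", hap("S1", KSN_COPIA), hap("S2", KSN_COPIA))


@pytest.fixture
def ksn_carrier_pollen_parent() -> PlantGenotype:
    """Once-flowering carrier: ksn linked to S1, wild KSN linked to S3."""
    return diploid("of_father", hap("S1", KSN_COPIA), hap("S3", KSN_FUNCTIONAL))
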