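import pytest
from hypothesis import HealthCheck, settings

from silencereplace import synth
from silencereplace.alleles import AlleleSet, PointMutation

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# Worked toy from the guide-walk scheme: SNP c.10 T>A, 21 nt context.
TOY_WT = "AAACCCGGGTTTAAACCCGGG"
TOY_MUT = "AAACCCGGGATTAAACCCGGG"


@pytest.fixture
def toy_alleles():
    """21 nt hand-checkable allele pair (c.10T>A); not a valid ORF, which
    AlleleSet permits — only build_allele_set translates."""
    from silencereplace.seqcore import NamedSequence

    return AlleleSet(
        wt_cds=NamedSequence("toyWT", TOY_WT),
        mut_cds=NamedSequence("toyMUT", TOY_MUT),
        mutation=PointMutation(10, "T", "A"),
    )


@pytest.fixture
def orf_alleles():
    """Seeded 300 nt random-ORF allele set (missense SNP at codon 34)."""
    return synth.make_toy_allele_set(synth.SimulationConfig(seed=1))
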