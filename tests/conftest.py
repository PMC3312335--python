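import pytest
from hypothesis import settings

from alevar.synth import ContigSpec, GenomeSpec, build_genome

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_spec() -> GenomeSpec:
    """A 6 kb chromosome + 2 kb plasmid with four short genes."""
    return GenomeSpec(
        contigs=(
            ContigSpec("chr", 6000, "chromosome"),
            ContigSpec("pSMALL", 2000, "plasmid"),
        ),
        gc=0.72,
        n_cds=4,
        cds_length=300,
        cds_margin=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return build_genome(small_spec)
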