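import pytest
from hypothesis import settings

from cpgpipe.simulate import build_synthetic_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from cpgpipe.variants import AnnotatedVariant


@pytest.fixture(scope="session")
def panel():
    return build_synthetic_panel()


def make_variant(**kwargs) -> AnnotatedVariant:
    """A qualifying heterozygous stop-gain in BRCA1 unless overridden."""
    defaults = dict(
        contig="chr1",
        position=10_050,
        ref="C",
        alt="T",
        gene_symbol="BRCA1",
        so_consequence="stop_gained",
        individual_id="P0001",
        zygosity="het",
        gq=60.0,
        dp=40,
        alt_depth=20,
        filter_status="PASS",
        truncation_fraction=0.5,
    )
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)
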