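import pytest

from ctdna_concord.data_model import SomaticVariant, infer_variant_type


def make_variant(**overrides) -> SomaticVariant:
    """A filter-passing missense SNP; override any field."""
    base = dict(
        chrom="chr1", pos=1000, ref="C", alt="T", gene="TP53",
        consequence_class="missense", variant_type="SNP",
        population_af=0.001, impact="HIGH", cadd_phred=35.0,
        fwd_support=5, rev_support=5, vaf=0.25,
        sample_id="S1", compartment="tissue",
    )
    base.update(overrides)
    if "variant_type" not in overrides:
        base["variant_type"] = infer_variant_type(base["ref"], base["alt"])
    return SomaticVariant(**base)


@pytest.fixture
def variant_factory():
    return make_variant
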