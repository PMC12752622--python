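import numpy as np
import pytest

from ctdnatrack.types import Compartment, PlasmaCall, TissueProfile, Variant  # noqa: F401


@pytest.fixture
def tp53_variant() -> Variant:
    return Variant(chrom="chr17", pos=7578406, ref="C", alt="T", gene="TP53")


def make_call(
    variant=None,
    alt_reads=12,
    depth=9800,
    sample_id="S1",
    compartment=Compartment.PLASMA,
    **variant_kwargs,
):
    if variant is None:
        defaults = dict(chrom="chr17", pos=7578406, ref="C", alt="T", gene="TP53")
        defaults.update(variant_kwargs)
        variant = Variant(**defaults)
    return PlasmaCall(
        variant=variant,
        alt_reads=alt_reads,
        depth=depth,
        sample_id=sample_id,
        compartment=compartment,
    )


@pytest.fixture
def small_tissue_profile(tp53_variant) -> TissueProfile:
    egfr = Variant(chrom="chr7", pos=55259515, ref="T", alt="G", gene="EGFR")
    kras = Variant(chrom="chr12", pos=25398284, ref="C", alt="A", gene="KRAS")
    return TissueProfile(
        patient_id="P1", variants=frozenset({tp53_variant, egfr, kras})
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
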