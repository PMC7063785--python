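import pytest

from varchain import AnnotatedVariant, Call, Consequence, Label
from varchain.simulate import DAMAGE_PREDICTORS


def make_variant(
    sift="D",
    polyphen="D",
    provean="D",
    exac_af=1e-6,
    common_af=1e-6,
    n_damage_pathogenic=7,
    n_damage_total=9,
    label=Label.PATHOGENIC,
    **kwargs,
) -> AnnotatedVariant:
    """Build a variant from compact discretization-relevant knobs."""
    call = {"D": Call.PATHOGENIC, "T": Call.NEUTRAL, ".": Call.MISSING}
    damage = {
        DAMAGE_PREDICTORS[i]: (
            Call.PATHOGENIC if i < n_damage_pathogenic else Call.NEUTRAL
        )
        for i in range(n_damage_total)
    }
    defaults = dict(
        chrom="1",
        pos=100,
        ref="A",
        alt="C",
        consequence=Consequence.NON_SYNONYMOUS,
        sift_call=call[sift],
        polyphen_call=call[polyphen],
        provean_call=call[provean],
        damage_calls=damage,
        exac_af=exac_af,
        common_af=common_af,
        clnsig_raw="5" if label is Label.PATHOGENIC else "2",
        label=label,
    )
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


@pytest.fixture
def variant_factory():
    return make_variant
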