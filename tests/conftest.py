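import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dietrisk.core import FoodServing, Measurement, SampleRecord, ToxicityThreshold


@pytest.fixture
def thresholds():
    return {
        "methyl-parathion": ToxicityThreshold(
            "methyl-parathion", crfd=0.0002, ptype="insecticide"
        ),
        "iprodione": ToxicityThreshold("iprodione", crfd=0.05, ptype="fungicide"),
        "captan": ToxicityThreshold("captan", crfd=0.13, ptype="fungicide"),
    }


@pytest.fixture
def servings():
    return {
        ("peaches", "fresh"): FoodServing("peaches", "fresh", serv_g=100.0),
        ("apples", "fresh"): FoodServing("apples", "fresh", serv_g=99.0),
    }


def make_sample(
    sample_id="S1",
    food="peaches",
    form="fresh",
    year=1996,
    concs=(),
    loq=0.01,
    claim="none",
    origin="US",
    **kw,
):
    """Small helper: concs is a mapping analyte -> concentration."""
    return SampleRecord(
        sample_id=sample_id,
        food_id=food,
        food_form=form,
        year=year,
        origin_country=origin,
        claim=claim,
        measurements=[
            Measurement(a, c, loq_ppm=loq) for a, c in dict(concs).items()
        ],
        **kw,
    )
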