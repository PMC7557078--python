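"""Core DRI arithmetic: reference concentrations, the three DRI kinds,
sample aggregation and exact summarisation."""

import math

import pytest
from hypothesis import given, strategies as st

from dietrisk.core import (
    DataIntegrityError,
    Diagnostics,
    FoodServing,
    InvalidInputError,
    Measurement,
    MissingServingError,
    NoPositivesError,
    ResidueSummary,
    SampleRecord,
    ToxicityThreshold,
    crfc,
    dri_m,
    fs_dri,
    sample_aggregate_dri,
    sample_dri,
    summarize_samples,
)

from conftest import make_sample


def _summary(n, npos, mean, **kw):
    return ResidueSummary(
        food_id=kw.pop("food", "peaches"),
        food_form="fresh",
        analyte_id=kw.pop("analyte", "x"),
        year=1996,
        n_tested=n,
        n_positive=npos,
        mean_positives_ppm=mean,
        **kw,
    )


class TestCrfc:
    @pytest.mark.parametrize(
        "crfd,fqpa,bw,serv,expected",
        [
            (0.0002, 1.0, 16.0, 100.0, 0.032),  # an extremely toxic OP, child serving
            (1.0, 1.0, 1.0, 1000.0, 1.0),  # 1 mg limit into 1 kg of food
            (0.0002, 10.0, 16.0, 100.0, 0.0032),  # FQPA factor divides the limit
        ],
    )
    def test_reference_concentration(self, crfd, fqpa, bw, serv, expected):
        thr = ToxicityThreshold("a", crfd=crfd, fqpa_factor=fqpa)
        serving = FoodServing("f", serv_g=serv, bw_kg=bw)
        assert crfc(thr, serving) == pytest.approx(expected, rel=1e-12)

    def test_default_child_serving_is_two_thirds_racc(self):
        serving = FoodServing("f", racc_g=150.0)
        assert serving.serv_g == pytest.approx(100.0)
        assert serving.bw_kg == 16.0

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(crfd=-1.0), "crfd"),
            (dict(crfd=0.1, fqpa_factor=0.5), "fqpa_factor"),
        ],
    )
    def test_invalid_threshold_names_field(self, kwargs, msg):
        with pytest.raises(InvalidInputError, match=msg):
            ToxicityThreshold("a", **kwargs)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(serv_g=-5.0), "serv_g"),
            (dict(serv_g=100.0, bw_kg=0.0), "bw_kg"),
        ],
    )
    def test_invalid_serving_names_field(self, kwargs, msg):
        with pytest.raises(InvalidInputError, match=msg):
            FoodServing("f", **kwargs)


class TestDriValues:
    def test_dri_m_published_rows(self):
        # 1996 peaches: parathion-methyl and iprodione
        assert dri_m(_summary(198, 82, 0.0562), 0.0320).value == pytest.approx(
            1.756, abs=5e-4
        )
        assert dri_m(_summary(198, 155, 0.923), 8.00).value == pytest.approx(
            0.115, abs=5e-4
        )

    def test_dri_m_unity_when_mean_equals_crfc(self):
        assert dri_m(_summary(10, 5, 0.25), 0.25).value == 1.0

    def test_dri_m_requires_positives(self):
        with pytest.raises(NoPositivesError):
            dri_m(_summary(10, 0, None), 0.25)

    def test_fs_dri_published_rows(self):
        v = fs_dri(_summary(198, 82, 0.0562), 0.0320)
        assert v.value == pytest.approx(0.727, abs=5e-4)
        # 1999 chlorpyrifos in single-serving apples
        v = fs_dri(_summary(1354, 416, 0.0374), 0.0483)
        assert v.value == pytest.approx(0.2378, abs=2e-4)

    def test_fs_dri_collapses_onto_dri_m_at_full_detection(self):
        s = _summary(50, 50, 0.4)
        assert fs_dri(s, 0.1).value == dri_m(s, 0.1).value

    def test_sample_dri_examples(self):
        # the highest 1996 peach sample: 0.50 ppm vs cRfC 0.032
        assert sample_dri(0.50, 0.032).value == pytest.approx(15.6, abs=0.05)
        assert sample_dri(0.0, 0.25).value == 0.0
        assert sample_dri(0.25, 0.25).value == 1.0
        with pytest.raises(InvalidInputError):
            sample_dri(-0.1, 0.25)


class TestSampleAggregate:
    def test_no_positives_is_zero(self, thresholds, servings):
        s = make_sample(concs={"methyl-parathion": 0.0})
        assert sample_aggregate_dri(s, thresholds, servings).value == 0.0

    def test_additivity_of_ratios(self, thresholds, servings):
        serving = servings[("peaches", "fresh")]
        c_mp = crfc(thresholds["methyl-parathion"], serving)
        c_ip = crfc(thresholds["iprodione"], serving)
        s = make_sample(concs={"methyl-parathion": c_mp, "iprodione": 2 * c_ip})
        assert sample_aggregate_dri(s, thresholds, servings).value == pytest.approx(
            3.0, rel=1e-12
        )

    def test_missing_serving_raises(self, thresholds):
        s = make_sample(food="durian")
        with pytest.raises(MissingServingError):
            sample_aggregate_dri(s, thresholds, {})

    def test_missing_threshold_counted_in_diagnostics(self, thresholds, servings):
        diag = Diagnostics()
        s = make_sample(concs={"methyl-parathion": 0.05, "mystery-99": 0.2})
        v = sample_aggregate_dri(s, thresholds, servings, diag)
        assert v.value == pytest.approx(0.05 / 0.032)
        assert diag.missing_threshold["mystery-99"] == 1


class TestSummarize:
    def test_counts_and_mean_of_positives(self):
        samples = [
            make_sample(sample_id=f"S{i}", concs={"captan": c})
            for i, c in enumerate([0.0, 0.0, 0.1, 0.3])
        ]
        (s,) = summarize_samples(samples)
        assert (s.n_tested, s.n_positive) == (4, 2)
        assert s.pct_positive == 0.5
        assert s.mean_positives_ppm == pytest.approx(0.2)

    def test_all_zero_group_has_no_mean(self):
        samples = [
            make_sample(sample_id=f"S{i}", concs={"captan": 0.0}) for i in range(3)
        ]
        (s,) = summarize_samples(samples)
        assert s.n_positive == 0 and s.mean_positives_ppm is None

    def test_trace_below_loq_is_a_non_detect(self):
        samples = [make_sample(concs={"captan": 0.005}, loq=0.01)]
        (s,) = summarize_samples(samples)
        assert s.n_positive == 0

    def test_duplicate_sample_analyte_rejected(self):
        with pytest.raises(DataIntegrityError):
            SampleRecord(
                "S1",
                "peaches",
                "fresh",
                1996,
                measurements=[Measurement("captan", 0.1), Measurement("captan", 0.2)],
            )
        dup = [make_sample(sample_id="S1"), make_sample(sample_id="S1")]
        for r in dup:
            r.measurements = [Measurement("captan", 0.1, 0.01)]
        with pytest.raises(DataIntegrityError):
            summarize_samples(dup)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

conc_lists = st.lists(
    st.floats(min_value=0.0, max_value=10.0, allow_nan=False), min_size=1, max_size=40
)


def _samples_from(concs, loq=0.01, analyte="captan"):
    return [
        make_sample(sample_id=f"S{i}", concs={analyte: c}, loq=loq)
        for i, c in enumerate(concs)
    ]


@given(concs=conc_lists, crfc_ppm=st.floats(min_value=1e-3, max_value=100.0))
def test_identity_fs_equals_dri_m_times_pct_positive(concs, crfc_ppm):
    """FS-DRI = DRI-M x NP/N holds to machine precision on every row."""
    (s,) = summarize_samples(_samples_from(concs))
    if s.n_positive == 0:
        return
    d = dri_m(s, crfc_ppm).value
    f = fs_dri(s, crfc_ppm).value
    assert f == d * (s.n_positive / s.n_tested)  # bit-exact by construction
    assert 0.0 <= f <= d
    assert (f == d) == (s.n_positive == s.n_tested)


@given(concs=conc_lists, k=st.floats(min_value=0.01, max_value=100.0))
def test_scale_equivariance(concs, k):
    """Scaling all concentrations by k scales DRI values by k; scaling the
    dose limit by k divides them by k."""
    base = summarize_samples(_samples_from(concs, loq=1e-9))
    scaled = summarize_samples(
        _samples_from([c * k for c in concs], loq=1e-9)
    )
    if not base or base[0].n_positive == 0:
        return
    f0 = fs_dri(base[0], 1.0).value
    assert fs_dri(scaled[0], 1.0).value == pytest.approx(k * f0, rel=1e-9)
    assert fs_dri(base[0], k).value == pytest.approx(f0 / k, rel=1e-9)


@given(
    concs=st.lists(
        st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
        min_size=2,
        max_size=60,
    ),
    split=st.integers(min_value=1, max_value=59),
    crfc_ppm=st.floats(min_value=1e-2, max_value=10.0),
)
def test_partition_weighted_union_consistency(concs, split, crfc_ppm):
    """For any disjoint split into strata, the union's FS-DRI is the
    N-weighted mean of stratum FS-DRIs, and DRI-M the NP-weighted mean."""
    split = min(split, len(concs) - 1)
    parts = [concs[:split], concs[split:]]
    (union,) = summarize_samples(_samples_from(concs))
    if union.n_positive == 0:
        return
    subs = []
    for i, p in enumerate(parts):
        got = summarize_samples(_samples_from(p))
        subs.append(got[0])
    fs_union = fs_dri(union, crfc_ppm).value
    fs_weighted = sum(
        s.n_tested * (fs_dri(s, crfc_ppm).value if s.n_positive else 0.0)
        for s in subs
    ) / sum(s.n_tested for s in subs)
    assert fs_weighted == pytest.approx(fs_union, rel=1e-9, abs=1e-12)
    dm_union = dri_m(union, crfc_ppm).value
    dm_weighted = sum(
        s.n_positive * dri_m(s, crfc_ppm).value for s in subs if s.n_positive
    ) / sum(s.n_positive for s in subs)
    assert dm_weighted == pytest.approx(dm_union, rel=1e-9, abs=1e-12)


@given(concs=conc_lists, crfc_ppm=st.floats(min_value=1e-2, max_value=10.0))
def test_summary_path_equals_raw_sample_path(concs, crfc_ppm):
    """FS-DRI via the summary equals the direct all-samples average,
    sum(positive concentrations) / (N x cRfC), from raw samples."""
    samples = _samples_from(concs)
    (s,) = summarize_samples(samples)
    if s.n_positive == 0:
        return
    direct = sum(
        m.conc_ppm for r in samples for m in r.positives
    ) / (len(samples) * crfc_ppm)
    assert fs_dri(s, crfc_ppm).value == pytest.approx(direct, rel=1e-9)
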