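"""Common-peak assignment, RRT/RPA statistics and similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gardenia_qc import (
    AnchorNotFoundError,
    ChromPeak,
    Chromatogram,
    ScenarioConfig,
    assign_common_peaks,
    build_reference,
    generate_batch_set,
    generate_validation_sets,
    relative_stats,
    similarity,
    similarity_report,
    validation_suite,
)


def _from_template(template, sample_id="s", rt_scale=1.0, area=100.0):
    peaks = [ChromPeak(rt=rt * rt_scale, area=area) for rt in template.rts]
    return Chromatogram(sample_id=sample_id, peaks=peaks)


def test_identity_sample_fully_matched(template):
    m = assign_common_peaks([_from_template(template)], template)
    assert not m.invalid_samples
    assert m.areas.notna().all().all()
    assert np.allclose(m.rrt.loc["s"], list(template.rrt.values()))


def test_common_rt_scaling_cancels_in_rrt(template):
    """A uniform +0.1% RT shift leaves every RRT deviation at zero."""
    m = assign_common_peaks([_from_template(template, rt_scale=1.001)], template)
    assert m.areas.notna().all().all()
    assert np.allclose(m.rrt.loc["s"], list(template.rrt.values()))


def test_peak_order_shuffle_is_irrelevant(template):
    a = _from_template(template, "a")
    rng = np.random.default_rng(0)
    shuffled = list(a.peaks)
    rng.shuffle(shuffled)
    b = Chromatogram(sample_id="a", peaks=shuffled)
    ma = assign_common_peaks([a], template)
    mb = assign_common_peaks([b], template)
    assert ma.areas.equals(mb.areas) and ma.rts.equals(mb.rts)


def test_missing_anchor_flags_sample_invalid(template):
    chrom = _from_template(template)
    peaks = [p for p in chrom.peaks if abs(p.rt - template.anchor_rt) > 1e-9]
    broken = Chromatogram(sample_id="s", peaks=peaks)
    # removing the anchor leaves peak 10/12 too far away to stand in
    m = assign_common_peaks([broken], template)
    assert m.invalid_samples == ["s"]


def test_synthetic_batches_fully_matched(template):
    chroms, _ = generate_batch_set(ScenarioConfig(seed=42))
    m = assign_common_peaks(chroms, template)
    assert not m.invalid_samples
    assert (m.areas.notna().sum(axis=1) == 28).all()


def test_relative_stats_reference_column(template):
    chroms, _ = generate_batch_set(ScenarioConfig(seed=9, n_samples=5))
    m = assign_common_peaks(chroms, template)
    stats = relative_stats(m)
    ref = template.reference_peak_id
    assert stats.loc[ref, "rrt_mean"] == pytest.approx(1.0)
    assert stats.loc[ref, "rpa_mean"] == pytest.approx(1.0)
    assert stats.loc[ref, "rrt_rsd_pct"] == pytest.approx(0.0)
    assert stats.loc[ref, "rpa_rsd_pct"] == pytest.approx(0.0)


def test_rpa_scale_invariance(template):
    a = _from_template(template, "a", area=100.0)
    b = Chromatogram("b", [ChromPeak(rt=p.rt, area=2 * p.area) for p in a.peaks])
    m = assign_common_peaks([a, b], template)
    stats = relative_stats(m)
    assert np.allclose(stats["rpa_rsd_pct"], 0.0)


def test_rpa_rsd_of_multiplicative_noise_matches_ratio_theory(template):
    """iid 2% lognormal area noise puts RPA RSDs near 2*sqrt(2)%.

    The anchor's noise enters every ratio, so the RSD of RPA concentrates
    around sqrt(2) times the per-peak CV; checked against a wide band that a
    direct ratio-of-lognormals simulation comfortably brackets.
    """
    cfg = ScenarioConfig(
        seed=314, n_samples=200, area_noise_cv=0.02, rt_jitter_sd=0.0,
        n_spurious_peaks=(0, 0),
        fixed_contents=None,
    )
    # re-measure one fixed sample many times: freeze contents across samples
    from gardenia_qc import table_contents, QUANTIFIED_ANALYTES

    base = table_contents().iloc[[0]][QUANTIFIED_ANALYTES]
    cfg.fixed_contents = base.loc[base.index.repeat(200)].reset_index(drop=True)
    chroms, _ = generate_batch_set(cfg)
    stats = relative_stats(assign_common_peaks(chroms, template))
    others = stats.drop(index=template.reference_peak_id)
    assert others["rpa_rsd_pct"].mean() == pytest.approx(2.0 * np.sqrt(2.0), rel=0.2)


def test_build_reference_modes(template):
    chroms, _ = generate_batch_set(ScenarioConfig(seed=3, n_samples=3))
    ref = build_reference(chroms, "designated", designated_id=chroms[0].sample_id)
    assert [p.rt for p in ref.peaks] == [p.rt for p in chroms[0].peaks]
    with pytest.raises(ValueError):
        build_reference(chroms, "designated", designated_id="nope")
    med = build_reference(chroms, "median", template=template)
    assert len(med.peaks) == 28
    # median of identical samples is that sample
    same = [
        Chromatogram(f"r{i}", [ChromPeak(rt=rt, area=7.0) for rt in template.rts])
        for i in range(3)
    ]
    med2 = build_reference(same, "median", template=template)
    assert [p.rt for p in med2.peaks] == list(template.rts)
    assert all(p.area == 7.0 for p in med2.peaks)


def test_median_reference_suppresses_outlier(template):
    areas = [100.0, 110.0, 1e6]
    samples = [
        Chromatogram(f"r{i}", [ChromPeak(rt=rt, area=a) for rt in template.rts])
        for i, a in enumerate(areas)
    ]
    med = build_reference(samples, "median", template=template)
    assert all(p.area == 110.0 for p in med.peaks)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 0, 0], [0, 1, 0], 0.0),
    ],
)
def test_cosine_similarity_basics(x, y, expected):
    assert similarity(x, y) == pytest.approx(expected, abs=1e-12)


def test_similarity_errors():
    with pytest.raises(ValueError):
        similarity([1.0], [1.0])
    with pytest.raises(ValueError):
        similarity([1, 2], [0, 0])
    with pytest.raises(ValueError):
        similarity([0, 0], [1, 2])


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.floats(0.0, 1e6, allow_subnormal=False), min_size=2, max_size=30).filter(
        lambda v: sum(v) > 1e-6
    ),
    st.floats(1e-3, 1e3),
)
def test_cosine_scale_invariance(v, c):
    assert similarity([c * x for x in v], v) == pytest.approx(1.0, abs=1e-9)


def test_similarity_report_designated_reference_scores_one(template):
    chroms, _ = generate_batch_set(ScenarioConfig(seed=6, n_samples=5))
    ref = build_reference(chroms, "designated")
    rep = similarity_report(chroms, ref, template).set_index("sample_id")
    assert rep.loc[chroms[0].sample_id, "similarity"] == pytest.approx(1.0)
    # between-batch content variation bounds how dissimilar batches can look
    assert (rep["similarity"] > 0.8).all()
    assert (rep["n_matched"] == 28).all()


def test_validation_suite_default_noise_passes(template):
    sets = generate_validation_sets(ScenarioConfig(seed=8))
    suite = validation_suite(sets, template)
    assert set(suite.index) == {"precision", "stability", "repeatability"}
    assert (suite["max_rpa_rsd_pct"] < 5.0).all()
    assert (suite["max_rrt_rsd_pct"] < 1.0).all()
    assert suite["passed"].all()


def test_validation_suite_zero_noise_all_zero(template):
    sets = generate_validation_sets(
        ScenarioConfig(seed=8, rt_jitter_sd=0.0, area_noise_cv=0.0),
        injection_cv=0.0, rt_sd=0.0, drift_cv=0.0, prep_cv=0.0,
    )
    suite = validation_suite(sets, template)
    assert np.allclose(suite["max_rpa_rsd_pct"], 0.0)
    assert np.allclose(suite["max_rrt_rsd_pct"], 0.0)


def test_high_drift_inflates_stability_rsd(template):
    sets = generate_validation_sets(ScenarioConfig(seed=8), drift_cv=0.3)
    suite = validation_suite(sets, template)
    assert (
        suite.loc["stability", "max_rpa_rsd_pct"]
        > suite.loc["precision", "max_rpa_rsd_pct"]
    )


def test_validation_suite_errors_on_missing_anchor(template):
    sets = generate_validation_sets(ScenarioConfig(seed=8))
    reps = sets["precision"]
    broken = Chromatogram(
        reps[0].sample_id,
        [p for p in reps[0].peaks if abs(p.rt / template.anchor_rt - 1) > 0.01],
    )
    sets["precision"] = [broken] + list(reps[1:])
    with pytest.raises(AnchorNotFoundError):
        validation_suite(sets, template)
    with pytest.raises(ValueError):
        validation_suite({"tiny": reps[:2]}, template)
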