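"""Calibration, content computation and validation statistics."""

import numpy as np
import pytest

from gardenia_qc import (
    IRIDOID_GROUP,
    QUANTIFIED_ANALYTES,
    CalibrationCurve,
    SamplePrep,
    aggregate_contents,
    calibration_curves,
    fit_calibration,
    lod_loq,
    precision_rsd,
    quantify,
    recovery,
    table_calibration,
    table_contents,
)


def _exact_points(slope, intercept, xs):
    return [(x, slope * x + intercept) for x in xs]


def test_fit_recovers_published_line_exactly():
    # geniposide: Y = 746351 X - 82879 over 380.6-15224 ng
    pts = _exact_points(746351.0, -82879.0, [380.6, 1000.0, 5000.0, 15224.0])
    c = fit_calibration(pts, "Geniposide")
    assert c.slope == pytest.approx(746351.0, rel=1e-12)
    assert c.intercept == pytest.approx(-82879.0, rel=1e-9)
    assert c.r_squared == pytest.approx(1.0, abs=1e-12)
    assert c.linear_range == (380.6, 15224.0)


def test_fit_recovers_every_published_line():
    for _, row in table_calibration().iterrows():
        xs = np.linspace(row.range_min_ng, row.range_max_ng, 6)
        c = fit_calibration(_exact_points(row.slope, row.intercept, xs), row.analyte)
        assert c.slope == pytest.approx(row.slope, rel=1e-10)
        assert c.intercept == pytest.approx(row.intercept, rel=1e-6)
        assert c.r_squared == pytest.approx(1.0, abs=1e-10)


def test_fit_simple_line_and_errors():
    c = fit_calibration([(1, 1), (2, 2), (3, 3)])
    assert (c.slope, c.intercept) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-12))
    with pytest.raises(ValueError):
        fit_calibration([(1, 1), (2, 2)])
    with pytest.raises(ValueError):
        fit_calibration([(1, 1), (1, 2), (1, 3)])


def test_fit_weighted_option():
    pts = _exact_points(500.0, 30.0, [1.0, 10.0, 100.0, 1000.0])
    c = fit_calibration(pts, weighting="1/x")
    assert c.slope == pytest.approx(500.0, rel=1e-9)
    assert c.intercept == pytest.approx(30.0, rel=1e-6)
    with pytest.raises(ValueError):
        fit_calibration(pts, weighting="1/x^2")
    with pytest.raises(ValueError):
        fit_calibration(_exact_points(1.0, 0.0, [0.0, 1.0, 2.0]), weighting="1/x")


def test_fit_noisy_line_r2():
    rng = np.random.default_rng(17)
    xs = np.linspace(10, 1000, 8)
    ys = 500.0 * xs + 30.0
    ys *= np.exp(rng.normal(0, 0.01, size=xs.size))
    c = fit_calibration(list(zip(xs, ys)))
    assert c.r_squared > 0.999


def test_lod_loq_formula():
    curve = calibration_curves()["Geniposide"]
    lod, loq = lod_loq(0.0, curve)
    assert (lod, loq) == (0.0, 0.0)
    lod, loq = lod_loq(1234.5, curve)
    assert loq / lod == pytest.approx(10.0 / 3.0)
    # noise implying the published LOD gives LOQ in the fixed 10:3 ratio
    noise = 2.44 * curve.slope / 3.0
    lod, loq = lod_loq(noise, curve)
    assert lod == pytest.approx(2.44)
    assert loq == pytest.approx(8.13, abs=0.01)


def test_quantify_dilution_chain():
    curve = calibration_curves()["Geniposide"]
    prep = SamplePrep()
    area = curve.slope * 3369.4 + curve.intercept
    content, in_range = quantify(area, curve, prep)
    assert content == pytest.approx(56.157, abs=1e-3)
    assert in_range
    # area at the intercept back-calculates to zero (below the linear range)
    assert quantify(curve.intercept, curve, prep) == (0.0, False)
    # negative back-calculated amount: clipped and flagged
    c, flag = quantify(curve.intercept - 1e6, curve, prep)
    assert c == 0.0 and not flag
    # doubling the weighed mass halves the content
    half = quantify(area, curve, SamplePrep(sample_mass_g=0.2))[0]
    assert half == pytest.approx(content / 2.0)


def test_quantify_channel_gate():
    curve = calibration_curves()["Chlorogenic acid"]  # 324 nm
    with pytest.raises(ValueError):
        quantify(1e6, curve, channel=254)


def test_curve_invariants():
    with pytest.raises(ValueError):
        CalibrationCurve("x", -1.0, 0.0, 0.99, (1, 10))
    with pytest.raises(ValueError):
        CalibrationCurve("x", 1.0, 0.0, 1.5, (1, 10))


def test_aggregate_published_contents():
    table = table_contents()[QUANTIFIED_ANALYTES]
    totals, summary = aggregate_contents(table, IRIDOID_GROUP)
    published_totals = table_contents()["Total of iridoids"]
    assert (totals - published_totals).abs().max() < 0.002
    assert summary.loc["Geniposide", "min"] == pytest.approx(37.917)
    assert summary.loc["Geniposide", "max"] == pytest.approx(72.216)
    assert summary.loc["Geniposide", "mean"] == pytest.approx(52.470, abs=0.01)
    assert totals.min() == pytest.approx(59.931, abs=0.002)
    assert totals.max() == pytest.approx(94.314, abs=0.002)


def test_aggregate_group_additivity_and_errors():
    table = table_contents()[QUANTIFIED_ANALYTES]
    g1, g2 = IRIDOID_GROUP[:3], IRIDOID_GROUP[3:]
    t1, _ = aggregate_contents(table, g1)
    t2, _ = aggregate_contents(table, g2)
    tot, _ = aggregate_contents(table, IRIDOID_GROUP)
    assert np.allclose(t1 + t2, tot)
    # permutation invariance
    t_perm, _ = aggregate_contents(table, list(reversed(IRIDOID_GROUP)))
    assert np.allclose(t_perm, tot)
    with pytest.raises(ValueError):
        aggregate_contents(table, [])
    with pytest.raises(ValueError):
        aggregate_contents(table, ["Unobtainium"])


def test_single_sample_aggregates():
    table = table_contents()[QUANTIFIED_ANALYTES].iloc[[0]]
    _, summary = aggregate_contents(table, IRIDOID_GROUP)
    assert (summary["min"] == summary["max"]).all()
    assert (summary["min"] == summary["mean"]).all()


def test_recovery_exact_and_noisy():
    exact = [(1.5, 1.0, 0.5)] * 3
    r = recovery(exact)
    assert r.mean_recovery_pct == pytest.approx(100.0)
    assert r.rsd_pct == pytest.approx(0.0)
    assert recovery([(1.0, 1.0, 0.5)] * 3).mean_recovery_pct == pytest.approx(0.0)
    rng = np.random.default_rng(99)
    spiked = [(1.0 + 0.5 * float(rng.normal(1.0, 0.02)), 1.0, 0.5) for _ in range(6)]
    r = recovery(spiked)
    assert 96.0 < r.mean_recovery_pct < 104.0
    assert r.rsd_pct < 5.0
    with pytest.raises(ValueError):
        recovery(exact[:2])
    with pytest.raises(ValueError):
        recovery([(1.0, 1.0, 0.0)] * 3)


def test_precision_rsd():
    assert precision_rsd([5.0, 5.0, 5.0]) == 0.0
    assert precision_rsd([90.0, 100.0, 110.0]) == pytest.approx(10.0)
    rng = np.random.default_rng(7)
    reps = np.exp(rng.normal(0.0, 0.01, size=6)) * 1e6
    assert precision_rsd(reps) == pytest.approx(1.0, abs=0.8)
    with pytest.raises(ValueError):
        precision_rsd([1.0])
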