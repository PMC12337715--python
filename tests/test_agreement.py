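"""Agreement metrics: MAD, MAPE, Pearson r, ICC, and the report builder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eptools import reference
from eptools.agreement import (
    MeasurementVector,
    build_phase1_report,
    icc,
    mad,
    mape,
    pearson_r,
)
from eptools.errors import AlignmentError, DegenerateInputError, ParameterError


def _vec(values, name="v", labels=None):
    labels = labels or tuple(f"m{i}" for i in range(len(values)))
    return MeasurementVector(tuple(labels), tuple(float(v) for v in values), name)


# ---------------------------------------------------------------------------
# published summary numbers (the validation campaign's recorded results)
# ---------------------------------------------------------------------------


def _published(group_labels, rater):
    exp = reference.time_domain_expected().subset(group_labels)
    obs = reference.time_domain_raters()[rater].subset(group_labels)
    return obs, exp


@pytest.mark.parametrize(
    "rater, group, exp_mad, exp_mape",
    [
        ("examiner 1", reference.CALCULATION_LABELS, 0.1111, 0.0094),
        ("examiner 2", reference.CALCULATION_LABELS, 0.1111, 0.0094),
        ("automatic", reference.CALCULATION_LABELS, 0.0100, 0.0037),
        ("examiner 1", reference.MARKING_LABELS, 0.0009, 0.0012),
        ("automatic", reference.MARKING_LABELS, 0.0000, 0.0000),
    ],
)
def test_recorded_summary_statistics_reproduced(rater, group, exp_mad, exp_mape):
    """MAD/MAPE over the recorded rater columns reproduce the campaign's
    summary values at 4 decimals (row-per-value convention)."""
    obs, exp = _published(list(group), rater)
    assert round(mad(obs, exp), 4) == exp_mad
    assert round(mape(obs, exp), 4) == exp_mape


def test_automatic_column_correlates_perfectly():
    obs, exp = _published(
        list(reference.MARKING_LABELS + reference.CALCULATION_LABELS), "automatic"
    )
    assert round(pearson_r(obs, exp), 3) == 1.0


def test_examiner_columns_correlate_near_perfectly():
    obs, exp = _published(
        list(reference.MARKING_LABELS + reference.CALCULATION_LABELS), "examiner 1"
    )
    assert pearson_r(obs, exp) > 0.999


# ---------------------------------------------------------------------------
# metric semantics
# ---------------------------------------------------------------------------


def test_identical_vectors_are_perfect():
    v = _vec([1.0, 2.0, 3.0])
    assert mad(v, v) == 0.0
    assert mape(v, v) == 0.0
    assert pearson_r(v, v) == pytest.approx(1.0)


def test_antipodal_zero_mean_correlation():
    exp = _vec([-2.0, -1.0, 1.0, 2.0])
    obs = _vec([2.0, 1.0, -1.0, -2.0])
    assert pearson_r(obs, exp) == pytest.approx(-1.0)


def test_alignment_errors():
    a = _vec([1.0, 2.0], labels=("x", "y"))
    b = _vec([1.0, 2.0], labels=("x", "z"))
    for fn in (mad, mape, pearson_r):
        with pytest.raises(AlignmentError):
            fn(a, b)


def test_mape_zero_policy():
    exp = _vec([1.0, 0.0, 2.0])
    obs = _vec([1.1, 0.5, 2.2])
    with pytest.raises(DegenerateInputError):
        mape(obs, exp, zero_policy="error")
    skipped = mape(obs, exp, zero_policy="skip")
    assert skipped == pytest.approx((0.1 / 1.0 + 0.2 / 2.0) / 2.0)


def test_pearson_needs_variance():
    flat = _vec([2.0, 2.0, 2.0])
    varying = _vec([1.0, 2.0, 3.0])
    with pytest.raises(DegenerateInputError):
        pearson_r(flat, varying)


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=-100, max_value=100),
            st.floats(min_value=0.5, max_value=100),
        ),
        min_size=2,
        max_size=12,
    ),
    st.floats(min_value=-50, max_value=50),
)
@settings(max_examples=60, deadline=None)
def test_mad_mape_invariances(pairs, shift):
    """MAD is translation-invariant and permutation-invariant; for positive
    expectations MAPE(obs, exp) equals MAD(obs/exp, 1)."""
    obs = _vec([p[0] for p in pairs])
    exp = _vec([p[1] for p in pairs])
    base = mad(obs, exp)
    shifted = mad(
        _vec([v + shift for v in obs.values]), _vec([v + shift for v in exp.values])
    )
    assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
    perm = np.random.default_rng(0).permutation(len(pairs))
    labels = tuple(f"m{i}" for i in perm)
    assert mad(
        _vec([obs.values[i] for i in perm], labels=labels),
        _vec([exp.values[i] for i in perm], labels=labels),
    ) == pytest.approx(base, rel=1e-12)
    ratio = _vec([o / e for o, e in zip(obs.values, exp.values)])
    ones = _vec([1.0] * len(pairs))
    assert mape(obs, exp) == pytest.approx(mad(ratio, ones), rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def _icc_a1_oracle(data):
    """Direct two-way ANOVA-table computation of ICC(A,1) (independent of
    the implementation's algebra)."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    msr = np.sum((data.mean(axis=1) - grand) ** 2) * k / (n - 1)
    msc = np.sum((data.mean(axis=0) - grand) ** 2) * n / (k - 1)
    sse = (
        np.sum((data - grand) ** 2)
        - (n - 1) * msr
        - (k - 1) * msc
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_identical_raters_is_one():
    v = _vec([1.0, 2.0, 3.0, 4.0])
    assert icc([v, v, v]) == pytest.approx(1.0)


def test_icc_penalizes_constant_offset():
    a = _vec([1.0, 2.0, 3.0, 4.0])
    b = _vec([101.0, 102.0, 103.0, 104.0])
    value = icc([a, b])
    oracle = _icc_a1_oracle(np.column_stack([a.array(), b.array()]))
    assert value == pytest.approx(oracle, rel=1e-12)
    assert value < 0.01  # absolute agreement punishes the 100-unit shift


def test_icc_matches_anova_oracle_on_noise(rng):
    data = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2.0
    raters = [_vec(data[:, j]) for j in range(3)]
    assert icc(raters) == pytest.approx(_icc_a1_oracle(data), rel=1e-9)


def test_icc_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    data = rng.normal(loc=5.0, scale=2.0, size=(10, 3))
    raters = [_vec(data[:, j]) for j in range(3)]
    frame = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(10), 3),
            "rater": np.tile(np.arange(3), 10),
            "score": data.ravel(),
        }
    )
    table = pingouin.intraclass_corr(
        frame, targets="subject", raters="rater", ratings="score"
    )
    mask = table["Type"].isin(["ICC2", "ICC(A,1)"])  # label varies by version
    icc2 = float(table.loc[mask, "ICC"].iloc[0])
    assert icc(raters) == pytest.approx(icc2, rel=1e-9)


@given(
    st.lists(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=3, max_size=3),
        min_size=3,
        max_size=10,
    )
)
@settings(max_examples=60, deadline=None)
def test_icc_bounded(rows):
    data = np.asarray(rows)
    if np.ptp(data) < 1e-6:
        return  # degenerate: no variance anywhere
    raters = [_vec(data[:, j]) for j in range(3)]
    try:
        value = icc(raters)
    except DegenerateInputError:
        return
    assert value <= 1.0 + 1e-12
    assert value >= -1.0 - 1e-12


def test_icc_alignment_and_arity():
    a = _vec([1.0, 2.0, 3.0], labels=("x", "y", "z"))
    b = _vec([1.0, 2.0, 3.0], labels=("x", "y", "w"))
    with pytest.raises(AlignmentError):
        icc([a, b])
    with pytest.raises(ParameterError):
        icc([a])


# ---------------------------------------------------------------------------
# report builder
# ---------------------------------------------------------------------------


def test_build_report_single_perfect_rater():
    exp = _vec([1.0, 2.0, 3.0, 4.0], name="expected")
    reports = build_phase1_report(
        exp, {"rater": exp}, {"all": list(exp.labels)}
    )
    report = reports[("all", "rater")]
    assert report.mad == 0.0
    assert report.mape == 0.0
    assert report.pearson_r == pytest.approx(1.0)


def test_build_report_rejects_overlapping_groups():
    exp = _vec([1.0, 2.0, 3.0])
    with pytest.raises(ParameterError):
        build_phase1_report(
            exp, {"r": exp}, {"g1": ["m0", "m1"], "g2": ["m1", "m2"]}
        )


def test_build_report_skips_empty_group(caplog):
    exp = _vec([1.0, 2.0, 3.0])
    with caplog.at_level("WARNING", logger="eptools.agreement"):
        reports = build_phase1_report(
            exp, {"r": exp}, {"full": list(exp.labels), "empty": []}
        )
    assert ("empty", "r") not in reports
    assert ("full", "r") in reports
    assert any("empty" in rec.message for rec in caplog.records)
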