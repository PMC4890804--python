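import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zratio import diffexp
from zratio.io import ExpressionMatrix, SampleDesign

from .oracles import comparison_oracle, oneway_anova


def as_matrix(array, scale="raw", samples=None):
    array = np.asarray(array, dtype=float)
    frame = pd.DataFrame(
        array,
        index=[f"P{i}" for i in range(array.shape[0])],
        columns=samples or [f"s{j}" for j in range(array.shape[1])],
    )
    return ExpressionMatrix(frame, scale=scale,
                            log_base=None if scale == "raw" else 10.0)


# ---------------------------------------------------------------- log_transform

def test_log_transform_values_and_floor():
    m = as_matrix([[100.0], [0.0]])
    out = diffexp.log_transform(m, base=10, floor=1.0)
    assert out.scale == "log"
    assert out.data.iloc[0, 0] == pytest.approx(2.0)
    assert out.data.iloc[1, 0] == pytest.approx(0.0)  # floor engages


def test_log_transform_inverts_to_floored_input(rng):
    vals = rng.lognormal(0, 2, size=(40, 3))
    m = as_matrix(vals)
    out = diffexp.log_transform(m, base=10, floor=1.0)
    np.testing.assert_allclose(
        10.0 ** out.data.to_numpy(), np.maximum(vals, 1.0), rtol=1e-12
    )


def test_log_transform_rejects_bad_base():
    with pytest.raises(ValueError, match="base"):
        diffexp.log_transform(as_matrix([[1.0], [2.0]]), base=1.0)


# ------------------------------------------------------------- zscore_normalize

def test_zscore_simple_column():
    m = as_matrix([[1.0], [2.0], [3.0]], scale="log")
    z = diffexp.zscore_normalize(m)
    np.testing.assert_allclose(z.data.iloc[:, 0], [-1.0, 0.0, 1.0])


def test_zscore_location_invariance(rng):
    vals = rng.normal(0, 1, size=(50, 4))
    z1 = diffexp.zscore_normalize(as_matrix(vals, scale="log"))
    shifted = vals.copy()
    shifted[:, 2] += 7.5
    z2 = diffexp.zscore_normalize(as_matrix(shifted, scale="log"))
    np.testing.assert_allclose(z1.data.to_numpy(), z2.data.to_numpy(), atol=1e-12)


def test_zscore_columns_standardized_and_idempotent(rng):
    vals = rng.normal(2.5, 0.7, size=(100, 4))
    z = diffexp.zscore_normalize(as_matrix(vals, scale="log"))
    assert np.allclose(z.data.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(z.data.std(axis=0, ddof=1), 1.0, atol=1e-9)
    again = diffexp.zscore_normalize(
        ExpressionMatrix(z.data, scale="log", log_base=10)
    )
    np.testing.assert_allclose(again.data.to_numpy(), z.data.to_numpy(), atol=1e-9)


def test_zscore_zero_variance_sample_names_sample():
    vals = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
    with pytest.raises(ValueError, match="s1"):
        diffexp.zscore_normalize(as_matrix(vals, scale="log"))


# ------------------------------------------------------------------- zratio

def test_zratio_zero_when_group_means_identical(rng, two_group_design):
    vals = rng.normal(0, 1, size=(10, 4))
    paired = np.hstack([vals, vals])  # group B mirrors group A sample-for-sample
    z = diffexp.zscore_normalize(
        as_matrix(paired, scale="log", samples=two_group_design.sample_ids)
    )
    res = diffexp.zratio(z, two_group_design, "A", "B")
    np.testing.assert_array_equal(res["z_ratio"].to_numpy(), 0.0)


def test_zratio_vector_has_unit_sd_and_antisymmetry(rng, two_group_design):
    vals = rng.normal(0, 1, size=(30, 8))
    z = diffexp.zscore_normalize(
        as_matrix(vals, scale="log", samples=two_group_design.sample_ids)
    )
    ab = diffexp.zratio(z, two_group_design, "A", "B")
    ba = diffexp.zratio(z, two_group_design, "B", "A")
    assert ab["z_ratio"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_array_equal(
        ab["z_ratio"].to_numpy(), -ba["z_ratio"].to_numpy()
    )


def test_zratio_unknown_group_rejected(rng, two_group_design):
    z = diffexp.zscore_normalize(
        as_matrix(rng.normal(0, 1, (10, 8)), scale="log",
                  samples=two_group_design.sample_ids)
    )
    with pytest.raises(KeyError):
        diffexp.zratio(z, two_group_design, "A", "C")


def test_missing_values_exclude_probe_from_comparison(rng, two_group_design):
    vals = rng.normal(0, 1, size=(10, 8))
    frame = pd.DataFrame(vals, index=[f"P{i}" for i in range(10)],
                         columns=two_group_design.sample_ids)
    frame.iloc[4, 1] = np.nan
    z = diffexp.zscore_normalize(ExpressionMatrix(frame, scale="log"))
    res = diffexp.zratio(z, two_group_design, "A", "B")
    assert "P4" not in res.index
    assert res.attrs["excluded_probes"] == ["P4"]


# --------------------------------------------------------------- fold_change

@pytest.mark.parametrize(
    "mean_a, mean_b, expected",
    [(200.0, 100.0, 2.0), (100.0, 200.0, -2.0), (100.0, 100.0, 1.0)],
)
def test_fold_change_signed_convention(mean_a, mean_b, expected, two_group_design):
    vals = np.column_stack([np.full(2, mean_a)] * 4 + [np.full(2, mean_b)] * 4)
    m = as_matrix(vals, samples=two_group_design.sample_ids)
    fc = diffexp.fold_change(m, two_group_design, "A", "B")
    assert fc.iloc[0] == pytest.approx(expected)


def test_fold_change_zero_denominator_is_missing(two_group_design):
    vals = np.column_stack([np.full(1, 5.0)] * 4 + [np.zeros(1)] * 4)
    m = as_matrix(vals, samples=two_group_design.sample_ids)
    assert np.isnan(diffexp.fold_change(m, two_group_design, "A", "B").iloc[0])


# -------------------------------------------------------------- ztest_pvalues

def test_ztest_pvalue_reference_points():
    p = diffexp.ztest_pvalues(np.array([0.0, 1.959964]))
    assert p[0] == pytest.approx(1.0)
    assert p[1] == pytest.approx(0.05, abs=1e-6)


@given(st.floats(0.0, 10.0), st.floats(0.0, 10.0))
def test_ztest_pvalue_monotone_in_magnitude(a, b):
    pa, pb = diffexp.ztest_pvalues(np.array([a, b]))
    if a < b:
        assert pa >= pb


# ------------------------------------------------------------------- bh_fdr

def test_bh_single_p_is_itself():
    assert diffexp.bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)


def test_bh_hand_stepup_example():
    q = diffexp.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


@given(
    st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=30)
)
def test_bh_dominates_p_and_ties_share_q(pvals):
    p = np.array(pvals)
    q = diffexp.bh_fdr(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()
    for v in np.unique(p):
        assert len(np.unique(np.round(q[p == v], 12))) == 1


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        diffexp.bh_fdr(np.array([0.5, 1.5]))


# ------------------------------------------------------------- anova_pvalues

def test_anova_matches_hand_computation(design_4x5):
    rng = np.random.default_rng(5)
    vals = rng.normal(0, 1, size=(6, 20))
    frame = pd.DataFrame(vals, index=[f"P{i}" for i in range(6)],
                         columns=design_4x5.sample_ids)
    z = diffexp.ZScoreMatrix(frame)
    res = diffexp.anova_pvalues(z, design_4x5)
    for i, probe in enumerate(frame.index):
        groups = [
            [frame.loc[probe, s] for s in design_4x5.samples_in(g)]
            for g in design_4x5.groups
        ]
        f, p = oneway_anova(groups)
        assert res.loc[probe, "F"] == pytest.approx(f, rel=1e-9)
        assert res.loc[probe, "p_anova"] == pytest.approx(p, rel=1e-9)


def test_anova_detects_extreme_separation(design_4x5):
    rng = np.random.default_rng(6)
    vals = rng.normal(0, 1, size=(1, 20))
    frame = pd.DataFrame(vals, index=["P0"], columns=design_4x5.sample_ids)
    frame[design_4x5.samples_in("mTBI")] += 10.0
    res = diffexp.anova_pvalues(diffexp.ZScoreMatrix(frame), design_4x5)
    assert res.loc["P0", "p_anova"] < 1e-6


def test_anova_null_pvalues_roughly_uniform(design_4x5):
    from scipy import stats

    rng = np.random.default_rng(7)
    vals = rng.normal(0, 1, size=(2000, 20))
    frame = pd.DataFrame(vals, index=[f"P{i}" for i in range(2000)],
                         columns=design_4x5.sample_ids)
    res = diffexp.anova_pvalues(diffexp.ZScoreMatrix(frame), design_4x5)
    ks = stats.kstest(res["p_anova"], "uniform")
    assert ks.pvalue > 0.01


def test_anova_requires_two_samples_per_group():
    d = SampleDesign({"s1": "A", "s2": "A", "s3": "B"})
    frame = pd.DataFrame(np.ones((3, 3)), columns=["s1", "s2", "s3"])
    with pytest.raises(ValueError):
        diffexp.anova_pvalues(diffexp.ZScoreMatrix(frame), d)


# -------------------------------------------------------- select_significant

def make_result(**overrides):
    base = {
        "z_ratio": [2.0],
        "p_z": [0.01],
        "q": [0.1],
        "p_anova": [0.01],
        "avg_z": [0.5],
    }
    base.update(overrides)
    return pd.DataFrame(base, index=["P0"])


@pytest.mark.parametrize(
    "field, bad_value",
    [
        ("p_z", 0.2),
        ("z_ratio", 1.0),
        ("q", 0.5),
        ("avg_z", -0.1),
        ("p_anova", 0.2),
    ],
)
def test_failing_any_single_criterion_blocks_significance(field, bad_value):
    res = diffexp.select_significant(make_result(**{field: [bad_value]}))
    assert not res["significant"].iloc[0]
    assert res["direction"].iloc[0] == "none"


def test_all_criteria_met_gives_signed_direction():
    up = diffexp.select_significant(make_result())
    assert up["significant"].iloc[0] and up["direction"].iloc[0] == "up"
    down = diffexp.select_significant(make_result(z_ratio=[-2.0]))
    assert down["significant"].iloc[0] and down["direction"].iloc[0] == "down"


def test_avgz_filter_can_be_disabled():
    thr = diffexp.SelectionThresholds(require_nonneg_avg_z=False)
    res = diffexp.select_significant(make_result(avg_z=[-1.0]), thr)
    assert res["significant"].iloc[0]


def test_missing_criterion_field_is_reported():
    res = make_result().drop(columns=["q"])
    with pytest.raises(ValueError, match="q"):
        diffexp.select_significant(res)


# ------------------------------------------------- brute-force oracle (full)

def test_comparison_table_matches_bruteforce_oracle(design_4x5, small_raw_matrix):
    anova = None
    z = diffexp.zscore_normalize(diffexp.log_transform(small_raw_matrix))
    table = diffexp.compare(
        z, design_4x5, "mTBI", "sham", raw=small_raw_matrix, anova=anova
    )
    raw_dict = {
        s: small_raw_matrix.data[s].to_dict() for s in small_raw_matrix.sample_ids
    }
    oracle = comparison_oracle(
        raw_dict, design_4x5.assignment, "mTBI", "sham", design_4x5.groups
    )
    for probe, expected in oracle.items():
        for fieldname, value in expected.items():
            assert table.loc[probe, fieldname] == pytest.approx(
                value, abs=1e-9
            ), f"{probe}/{fieldname}"
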