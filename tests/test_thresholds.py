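"""Threshold rules and cross-validation bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isletcal.thresholds import (
    candidate_thresholds,
    chisq_statistic,
    cross_validate_thresholds,
    evaluate_threshold,
    optimal_threshold_chisq,
    stratified_folds,
    summarize_cv,
    threshold_spec98,
)


@pytest.mark.parametrize(
    "table, expected",
    [((10, 0, 0, 10), 20.0), ((5, 5, 5, 5), 0.0), ((30, 10, 10, 30), 20.0)],
)
def test_chisq_statistic_closed_form(table, expected):
    assert chisq_statistic(*table) == pytest.approx(expected)


def test_chisq_zero_margin_and_negative_counts():
    assert chisq_statistic(5, 5, 0, 0) == 0.0
    with pytest.raises(ValueError, match="non-negative"):
        chisq_statistic(-1, 2, 3, 4)


def test_candidate_grid_combinatorics():
    cands = candidate_thresholds([1, 2], [3])
    assert len(cands) == 4
    assert cands[0] < 1 and cands[-1] > 3
    assert list(cands[1:3]) == [1.5, 2.5]
    degenerate = candidate_thresholds([2.0, 2.0], [2.0])
    assert len(degenerate) == 2


def test_candidate_grid_enumerates_every_confusion_table():
    rng = np.random.default_rng(2)
    cases = rng.integers(0, 20, size=25).astype(float)
    controls = rng.integers(0, 20, size=25).astype(float)
    cands = candidate_thresholds(cases, controls)
    tables = {
        (int((cases >= t).sum()), int((controls >= t).sum())) for t in cands
    }
    # oracle: scan at every observed value and far outside the range
    scan = np.concatenate([cases, controls, [-1e9, 1e9]])
    oracle = set()
    for t in scan:
        oracle.add((int((cases >= t).sum()), int((controls >= t).sum())))
        oracle.add((int((cases > t).sum()), int((controls > t).sum())))
    assert tables == oracle
    assert len(tables) == len(cands)  # each achievable table exactly once


def test_optimal_chisq_separable_and_tiebreak():
    assert optimal_threshold_chisq([5, 6, 7], [1, 2, 3]) == 4.0
    # chi-square ties at 2.667 for cuts >=1.5 and >=3.5; largest wins
    assert optimal_threshold_chisq([2, 3, 4, 5], [0, 1, 2, 3]) == 3.5
    assert optimal_threshold_chisq([2, 3, 4, 5], [0, 1, 2, 3], tie_break="smallest") == 1.5


def test_optimal_chisq_equals_bruteforce_scan():
    rng = np.random.default_rng(3)
    for _ in range(20):
        cases = rng.normal(1, 1, size=rng.integers(5, 40))
        controls = rng.normal(0, 1, size=rng.integers(5, 40))
        t_star = optimal_threshold_chisq(cases, controls)
        best = max(
            chisq_statistic(
                int((cases >= t).sum()),
                int((cases < t).sum()),
                int((controls >= t).sum()),
                int((controls < t).sum()),
            )
            for t in candidate_thresholds(cases, controls)
        )
        achieved = chisq_statistic(
            int((cases >= t_star).sum()),
            int((cases < t_star).sum()),
            int((controls >= t_star).sum()),
            int((controls < t_star).sum()),
        )
        assert achieved == pytest.approx(best, rel=1e-12)


def test_spec98_order_statistic_examples():
    t = threshold_spec98(np.arange(1, 101, dtype=float))
    assert int((np.arange(1, 101) >= t).sum()) == 2
    assert np.mean(np.arange(1, 101) < t) == 0.98

    t_tied = threshold_spec98(np.full(50, 3.0))
    assert t_tied > 3.0
    assert np.mean(np.full(50, 3.0) < t_tied) == 1.0


def test_spec98_matches_normal_quantile():
    rng = np.random.default_rng(4)
    controls = rng.standard_normal(100_000)
    assert threshold_spec98(controls) == pytest.approx(stats.norm.ppf(0.98), abs=0.05)


def test_spec98_training_specificity_never_below_level():
    rng = np.random.default_rng(5)
    for _ in range(50):
        controls = rng.choice([0.0, 1.0, 2.5, 2.5, 3.0], size=rng.integers(5, 60))
        for level in (0.8, 0.9, 0.98):
            t = threshold_spec98(controls, level=level)
            assert np.mean(controls < t) >= level


def test_spec98_rejects_bad_level():
    with pytest.raises(ValueError, match="level"):
        threshold_spec98([1.0, 2.0], level=1.5)


def test_evaluate_threshold_examples_and_oracle():
    assert evaluate_threshold(4.0, [5, 6, 7], [1, 2, 3]) == (1.0, 1.0)
    assert evaluate_threshold(-10.0, [5, 6, 7], [1, 2, 3]) == (1.0, 0.0)
    rng = np.random.default_rng(6)
    cases, controls = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
    t = 0.3
    sens, spec = evaluate_threshold(t, cases, controls)
    assert sens == sum(1 for v in cases if v >= t) / 30
    assert spec == sum(1 for v in controls if v < t) / 40


def test_stratified_folds_partition_and_balance():
    rng = np.random.default_rng(7)
    status = rng.random(137) < 0.4
    for repeat in (1, 2):
        seen = []
        for train, test in stratified_folds(status, 10, seed=0, repeat=repeat):
            seen.extend(test)
            assert set(train) | set(test) == set(range(137))
            fold_cases = status[test].sum()
            expected = status.mean() * len(test)
            assert abs(fold_cases - expected) <= 1
        assert sorted(seen) == list(range(137))


def test_cross_validation_is_deterministic_and_counts_rows(small_cohort):
    _, table = small_cohort
    sub = table[(table["analyte"] == "GADA") & (table["assay"] == "ADAP_CRC")]
    r1 = cross_validate_thresholds(sub, "chisq", n_repeats=3, k=5, seed=11)
    r2 = cross_validate_thresholds(sub, "chisq", n_repeats=3, k=5, seed=11)
    pd.testing.assert_frame_equal(r1, r2)
    assert len(r1) == 15
    assert ((r1["sensitivity"] >= 0) & (r1["sensitivity"] <= 1)).all()


def test_cross_validation_rejects_thin_strata(small_cohort):
    _, table = small_cohort
    sub = table[(table["analyte"] == "GADA") & (table["assay"] == "ADAP_CRC")]
    tiny = pd.concat(
        [
            sub[sub["status"] == "case"],
            sub[sub["status"] == "control"].head(3),
        ]
    )
    with pytest.raises(ValueError, match="controls"):
        cross_validate_thresholds(tiny, "spec98", n_repeats=1, k=10, seed=0)


def test_summary_collapses_for_identical_folds():
    df = pd.DataFrame(
        {
            "analyte": "GADA",
            "assay": "RBA",
            "method": "chisq",
            "repeat": np.repeat(np.arange(1, 101), 10),
            "fold": np.tile(np.arange(1, 11), 100),
            "threshold": 2.5,
            "sensitivity": 0.9,
            "specificity": 0.95,
        }
    )
    out = summarize_cv(df).iloc[0]
    assert out["threshold_ci_low"] == out["threshold_mean"] == out["threshold_ci_high"] == 2.5


def test_summary_percentiles_match_order_statistic_oracle():
    sens = np.arange(1, 1001) / 1000
    df = pd.DataFrame(
        {
            "analyte": "GADA",
            "assay": "RBA",
            "method": "spec98",
            "repeat": 1,
            "fold": 1,
            "threshold": 0.0,
            "sensitivity": sens,
            "specificity": 0.98,
        }
    )
    out = summarize_cv(df).iloc[0]
    assert out["sensitivity_mean"] == pytest.approx(0.5005)
    # linear-interpolation order statistics at positions 2.5% and 97.5% of n-1
    assert out["sensitivity_ci_low"] == pytest.approx(0.025975)
    assert out["sensitivity_ci_high"] == pytest.approx(0.975025)
    assert out["sensitivity_median"] == pytest.approx(0.5005)

    with pytest.raises(ValueError, match="empty"):
        summarize_cv(df.iloc[0:0])


def test_summary_normal_ci_option():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(
        {
            "analyte": "A",
            "assay": "B",
            "method": "chisq",
            "repeat": 1,
            "fold": np.arange(1000),
            "threshold": rng.normal(2, 0.1, 1000),
            "sensitivity": 0.9,
            "specificity": 0.95,
        }
    )
    out = summarize_cv(df, ci="normal").iloc[0]
    x = df["threshold"].to_numpy()
    half = 1.96 * x.std(ddof=1) / np.sqrt(1000)
    assert out["threshold_ci_low"] == pytest.approx(x.mean() - half)
    assert out["threshold_ci_high"] == pytest.approx(x.mean() + half)
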