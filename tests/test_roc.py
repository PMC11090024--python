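"""AUC, DeLong variance/CI and the paired DeLong test, checked against
enumeration, resampling oracles and the R pROC implementation."""

import json
import subprocess

import numpy as np
import pytest

from isletcal.roc import (
    auc_mann_whitney,
    delong_ci,
    delong_paired_test,
    delong_variance,
    placements,
    roc_curve,
    welch_t_test,
)


@pytest.mark.parametrize(
    "cases, controls, expected",
    [([2, 3], [0, 1], 1.0), ([1], [1], 0.5), ([0, 2], [1, 3], 0.25)],
)
def test_auc_small_instances(cases, controls, expected):
    assert auc_mann_whitney(cases, controls) == pytest.approx(expected)


def test_auc_label_swap_and_monotone_invariance():
    rng = np.random.default_rng(0)
    cases = np.round(rng.normal(1, 1, 35), 1)  # rounding forces ties
    controls = np.round(rng.normal(0, 1, 45), 1)
    a = auc_mann_whitney(cases, controls)
    assert a + auc_mann_whitney(controls, cases) == pytest.approx(1.0, abs=1e-12)
    assert auc_mann_whitney(np.exp(cases), np.exp(controls)) == pytest.approx(a, abs=1e-12)


def test_roc_curve_is_monotone_and_trapezoid_equals_auc():
    rng = np.random.default_rng(1)
    cases = np.round(rng.normal(1, 1, 60), 1)
    controls = np.round(rng.normal(0, 1, 80), 1)
    curve = roc_curve(cases, controls)
    assert (np.diff(curve.sensitivity) >= 0).all()
    assert (np.diff(curve.one_minus_specificity) >= 0).all()
    area = np.trapezoid(curve.sensitivity, curve.one_minus_specificity)
    assert area == pytest.approx(curve.auc, abs=1e-12)
    assert curve.auc == pytest.approx(auc_mann_whitney(cases, controls), abs=1e-12)


def test_delong_perfect_separation():
    assert delong_variance([2, 3], [0, 1]) == 0.0
    auc, ci = delong_ci([2, 3], [0, 1])
    assert auc == 1.0 and ci == (1.0, 1.0)


def test_delong_variance_symmetric_under_label_swap():
    rng = np.random.default_rng(2)
    cases, controls = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
    assert delong_variance(cases, controls) == pytest.approx(
        delong_variance(controls, cases), abs=1e-15
    )


def test_delong_se_matches_stratified_bootstrap():
    rng = np.random.default_rng(3)
    cases, controls = rng.normal(0.8, 1, 25), rng.normal(0, 1, 30)
    se = delong_variance(cases, controls) ** 0.5
    B = 100_000
    aucs = np.empty(B)
    for b in range(B):
        aucs[b] = auc_mann_whitney(
            rng.choice(cases, 25, replace=True), rng.choice(controls, 30, replace=True)
        )
    assert se == pytest.approx(aucs.std(ddof=1), rel=0.15)


def test_paired_test_identical_and_transformed_markers():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 60)
    labels = np.arange(60) < 25
    x[labels] += 1
    same = delong_paired_test(x, x.copy(), labels)
    assert same.auc_diff == 0.0 and same.p_value == 1.0
    trans = delong_paired_test(x, np.exp(x), labels)
    assert trans.auc_diff == pytest.approx(0.0, abs=1e-12)
    assert trans.p_value == 1.0


def test_paired_test_rejects_length_mismatch():
    with pytest.raises(ValueError, match="equal length"):
        delong_paired_test([1, 2, 3], [1, 2], [True, False, True])


def test_paired_z_matches_sign_flip_permutation_variance():
    """The paired DeLong z^2 agrees with a z^2 built from a sign-flip
    resampling estimate of the variance of the placement differences."""
    rng = np.random.default_rng(5)
    latent = np.r_[rng.normal(1.2, 1, 40), rng.normal(0, 1, 50)]
    labels = np.arange(90) < 40
    x = latent + rng.normal(0, 0.6, 90)
    y = latent + rng.normal(0, 0.6, 90)
    cmp = delong_paired_test(x, y, labels)

    v10x, v01x = placements(x[labels], x[~labels])
    v10y, v01y = placements(y[labels], y[~labels])
    d10, d01 = v10x - v10y, v01x - v01y
    m, n = d10.size, d01.size
    flips = 100_000
    s10 = rng.choice([-1.0, 1.0], size=(flips, m))
    s01 = rng.choice([-1.0, 1.0], size=(flips, n))
    perm = (s10 @ (d10 - d10.mean())) / m + (s01 @ (d01 - d01.mean())) / n
    var_perm = perm.var(ddof=0)
    z2_perm = cmp.auc_diff**2 / var_perm
    se_delong = (cmp.diff_ci[1] - cmp.auc_diff) / 1.96
    z2_delong = (cmp.auc_diff / se_delong) ** 2
    assert z2_delong == pytest.approx(z2_perm, rel=0.10)


def test_welch_t_test():
    t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
    assert t == 0.0 and p == 1.0

    rng = np.random.default_rng(6)
    g1 = rng.normal(0, 1, 15)
    g2 = g1 + 5  # identical sample variance -> pooled-limit df
    _, df, _ = welch_t_test(g1, g2)
    assert df == pytest.approx(28.0)

    a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 17)
    t, df, p = welch_t_test(a, b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t_direct = (a.mean() - b.mean()) / np.sqrt(va / 12 + vb / 17)
    df_direct = (va / 12 + vb / 17) ** 2 / (
        (va / 12) ** 2 / 11 + (vb / 17) ** 2 / 16
    )
    assert t == pytest.approx(t_direct)
    assert df == pytest.approx(df_direct)


def test_delong_matches_r_proc(tmp_path):
    """Cross-check AUC, DeLong variance and paired test against R's pROC."""
    rng = np.random.default_rng(7)
    labels = np.arange(80) < 35
    latent = np.where(labels, rng.normal(1, 1, 80), rng.normal(0, 1, 80))
    x = latent + rng.normal(0, 0.5, 80)
    y = latent + rng.normal(0, 0.7, 80)
    csv = tmp_path / "data.csv"
    with open(csv, "w") as fh:
        fh.write("label,x,y\n")
        for row in zip(labels.astype(int), x, y):
            fh.write(",".join(map(str, row)) + "\n")
    out = tmp_path / "proc.json"
    script = tmp_path / "check.R"
    script.write_text(
        f"""
suppressMessages({{library(pROC); library(jsonlite)}})
d <- read.csv("{csv}")
r1 <- roc(d$label, d$x, direction="<", quiet=TRUE)
r2 <- roc(d$label, d$y, direction="<", quiet=TRUE)
res <- list(
  auc1 = as.numeric(auc(r1)),
  var1 = as.numeric(var(r1, method="delong")),
  ci1 = as.numeric(ci.auc(r1, method="delong")),
  p_paired = roc.test(r1, r2, method="delong", paired=TRUE)$p.value
)
write_json(res, "{out}", digits=NA, auto_unbox=TRUE)
"""
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = json.loads(out.read_text())

    auc, ci = delong_ci(x[labels], x[~labels])
    assert auc == pytest.approx(ref["auc1"], abs=1e-12)
    assert delong_variance(x[labels], x[~labels]) == pytest.approx(ref["var1"], rel=1e-9)
    # pROC uses qnorm(0.975) = 1.959964 where we use 1.96
    assert ci[0] == pytest.approx(ref["ci1"][0], abs=1e-4)
    assert ci[1] == pytest.approx(ref["ci1"][2], abs=1e-4)
    cmp = delong_paired_test(x, y, labels)
    assert cmp.p_value == pytest.approx(ref["p_paired"], rel=1e-6)
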