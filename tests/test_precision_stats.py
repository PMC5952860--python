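"""Agreement statistics: ICC(2,1), Glüer precision, LSC, Bland-Altman, QC gate."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cortigap import (
    PairedMeasurements,
    StackGrades,
    apply_exclusions,
    bland_altman,
    icc_rating,
    icc_two_way_random_absolute,
    lsc,
    paired_t,
    precision_report,
    rms_precision,
)
from cortigap.precision_stats import LSC_FACTOR


def pm(m1, m2):
    return PairedMeasurements(list(range(len(m1))), np.asarray(m1, float), m2)


def icc21_oracle(x):
    """Independent ICC(2,1) via explicit variance-component sums (loop form)."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    msr = sum((row.mean() - grand) ** 2 for row in x) * k / (n - 1)
    msc = sum((x[:, j].mean() - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_perfect_agreement_is_icc_one():
    icc, (lo, hi) = icc_two_way_random_absolute(pm([1, 2, 3, 4], [1, 2, 3, 4]))
    assert icc == pytest.approx(1.0)


def test_affine_transform_of_all_values_leaves_icc_unchanged():
    rng = np.random.default_rng(1)
    a = rng.normal(10, 3, 8)
    b = a + rng.normal(0, 0.5, 8)
    icc1, _ = icc_two_way_random_absolute(pm(a, b))
    icc2, _ = icc_two_way_random_absolute(pm(3.5 * a - 7, 3.5 * b - 7))
    assert icc1 == pytest.approx(icc2)


def test_systematic_offset_penalizes_absolute_agreement():
    """A large constant rater offset must depress ICC(2,1) far below the
    consistency-type correlation of the same data (hand ANOVA oracle)."""
    rng = np.random.default_rng(2)
    a = rng.normal(20, 5, 4)
    b = a + 50 + rng.normal(0, 0.1, 4)
    x = np.column_stack([a, b])
    icc, _ = icc_two_way_random_absolute(pm(a, b))
    assert icc == pytest.approx(icc21_oracle(x), abs=1e-12)
    assert icc < 0.2  # offset dominates
    assert np.corrcoef(a, b)[0, 1] > 0.99  # yet the pairs correlate perfectly


@pytest.mark.parametrize("seed", range(50))
def test_icc_matches_brute_force_anova_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (5, 2)) + rng.normal(0, 1, (5, 1))
    icc, _ = icc_two_way_random_absolute(pm(x[:, 0], x[:, 1]))
    assert icc == pytest.approx(icc21_oracle(x), abs=1e-10)


def test_icc_ci_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(3)
    for _ in range(5):
        base = rng.normal(10, 4, 8)
        a = base + rng.normal(0, 1, 8)
        b = base + rng.normal(0, 1, 8)
        icc, (lo, hi) = icc_two_way_random_absolute(pm(a, b))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(8), 2),
                "raters": np.tile([0, 1], 8),
                "scores": np.column_stack([a, b]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        ref_row = ref.loc["ICC(A,1)"]  # single-measure absolute agreement
        ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
        assert icc == pytest.approx(ref_row["ICC"], abs=1e-8)
        # pingouin prints its CI rounded to two decimals
        assert lo == pytest.approx(ref_row[ci_col][0], abs=0.006)
        assert hi == pytest.approx(ref_row[ci_col][1], abs=0.006)


def test_degenerate_zero_variance_is_an_error():
    with pytest.raises(ValueError, match="degenerate"):
        icc_two_way_random_absolute(pm([5, 5, 5, 5], [5, 5, 5, 5]))


@pytest.mark.parametrize(
    "value,band",
    [
        (0.70, "good"),
        (0.82, "excellent"),
        (0.39, "poor"),
        (0.40, "fair"),
        (0.60, "good"),
        (0.75, "excellent"),
        (1.0, "excellent"),
        (-0.2, "poor"),
    ],
)
def test_icc_rating_bands(value, band):
    assert icc_rating(value) == band


def test_rms_precision_hand_computed():
    sd, cv = rms_precision(pm([10, 20], [12, 18]))
    assert sd == pytest.approx(math.sqrt(2), abs=1e-12)
    cv1 = 100 * math.sqrt(2) / 11
    cv2 = 100 * math.sqrt(2) / 19
    assert cv == pytest.approx(math.sqrt((cv1**2 + cv2**2) / 2), abs=1e-12)
    assert cv == pytest.approx(10.50, abs=0.01)


def test_rms_precision_identities():
    sd, cv = rms_precision(pm([3, 4, 5], [3, 4, 5]))
    assert (sd, cv) == (0.0, 0.0)
    sd1, _ = rms_precision(pm([1], [3]))
    assert sd1 == pytest.approx(math.sqrt(2))
    # zero subject mean -> CV undefined (n.a.)
    sd2, cv2 = rms_precision(pm([0, 2], [0, 3]))
    assert cv2 is None and sd2 > 0


def test_sd_rms_squared_equals_half_mean_square_difference():
    rng = np.random.default_rng(4)
    a, b = rng.normal(5, 2, 30), rng.normal(5, 2, 30)
    sd, _ = rms_precision(pm(a, b))
    assert sd**2 == pytest.approx(((a - b) ** 2).sum() / (2 * len(a)), abs=1e-12)


def test_lsc_constant_and_values():
    assert LSC_FACTOR == pytest.approx(2.77186, abs=1e-5)
    assert lsc(1.5) == pytest.approx(4.2, abs=0.05)
    assert lsc(0.0) == 0.0
    assert lsc(1.0) == pytest.approx(2.7719, abs=1e-4)
    with pytest.raises(ValueError):
        lsc(-0.1)


def test_bland_altman_degenerate_cases():
    ba = bland_altman(pm([1, 2, 3], [1, 2, 3]))
    assert ba == {"mean_diff": 0.0, "loa_lo": 0.0, "loa_hi": 0.0}
    ba2 = bland_altman(pm([5, 6, 7], [2, 3, 4]))
    assert ba2["mean_diff"] == pytest.approx(3.0)
    assert ba2["loa_lo"] == pytest.approx(ba2["loa_hi"])


def test_bland_altman_limits_recover_gaussian_width():
    rng = np.random.default_rng(5)
    d = rng.normal(0, 1, 10_000)
    ba = bland_altman(pm(d, np.zeros_like(d)))
    assert ba["loa_hi"] == pytest.approx(1.96, rel=0.03)
    assert ba["loa_lo"] == pytest.approx(-1.96, rel=0.03)


def test_paired_t_matches_closed_form():
    res = paired_t(pm([1, 2, 3], [2, 4, 6]))
    d = np.array([-1.0, -2.0, -3.0])
    t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(3))
    assert res["t"] == pytest.approx(t_hand, abs=1e-12)
    assert res["p"] == pytest.approx(2 * sps.t.sf(abs(t_hand), 2), abs=1e-12)


def test_paired_t_degenerate_differences_error():
    with pytest.raises(ValueError):
        paired_t(pm([2, 3, 4, 5], [1, 2, 3, 4]))


def test_paired_t_p_uniform_under_null():
    rng = np.random.default_rng(6)
    ps = []
    for _ in range(500):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        ps.append(paired_t(pm(a, b))["p"])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def study_grade_tables():
    """42 joints x 3 stacks reproducing the clinical tally: 20 poor on scan 1,
    13 on scan 2, 2 poor on both, 2 joints poor on all stacks."""
    grades = []
    for j in range(42):
        g1, g2 = [1, 1, 1], [1, 1, 1]
        if j == 0:
            g1 = [4, 4, 4]  # all-poor joint (scan 1)
        elif j == 1:
            g1, g2 = [4, 4, 1], [1, 1, 5]  # all-poor joint (union)
        elif 2 <= j <= 16:
            g1[0] = 4  # 15 more scan-1 poor stacks
            if j in (2, 3):
                g2[0] = 4  # 2 of them poor on both scans
        elif 19 <= j <= 28:
            g2[2] = 4  # 10 more scan-2 poor stacks
        grades.append(StackGrades(f"J{j:02d}", g1, g2))
    return grades


def test_exclusion_rule_reproduces_study_counts():
    res = apply_exclusions(study_grade_tables())
    assert res.n_excluded_stacks == 31
    assert res.n_excluded_stacks / 126 == pytest.approx(0.246, abs=0.0005)
    assert len(res.excluded_joints) == 2
    assert len(res.included_joints) == 40


def test_all_good_grades_exclude_nothing():
    grades = [StackGrades(f"J{i}", [1, 2, 3], [3, 2, 1]) for i in range(5)]
    res = apply_exclusions(grades)
    assert res.n_excluded_stacks == 0
    assert len(res.included_joints) == 5


def test_malformed_grades_rejected():
    with pytest.raises(ValueError):
        StackGrades("J0", [1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        StackGrades("J0", [1, 2, 6], [1, 2, 3])


def test_sd_rms_recovers_injected_noise_at_cohort_size():
    """Duplicate measurements with noise sigma: SD_RMS estimates sigma within
    chi-square sampling bounds at n = 40."""
    rng = np.random.default_rng(7)
    sigma = 1.3
    base = rng.normal(10, 4, 40)
    a = base + rng.normal(0, sigma, 40)
    b = base + rng.normal(0, sigma, 40)
    sd, _ = rms_precision(pm(a, b))
    lo = sigma * math.sqrt(sps.chi2.ppf(0.005, 40) / 40)
    hi = sigma * math.sqrt(sps.chi2.ppf(0.995, 40) / 40)
    assert lo <= sd <= hi


def test_precision_report_is_consistent():
    rng = np.random.default_rng(8)
    base = rng.normal(10, 4, 12)
    p = pm(base + rng.normal(0, 0.5, 12), base + rng.normal(0, 0.5, 12))
    rep = precision_report(p)
    assert rep.lsc_sd == pytest.approx(LSC_FACTOR * rep.sd_rms)
    assert rep.lsc_cv_pct == pytest.approx(LSC_FACTOR * rep.cv_rms_pct)
    assert rep.icc_rating == icc_rating(rep.icc)
    rep_count = precision_report(p, count_outcome=True)
    assert rep_count.cv_rms_pct is None and rep_count.lsc_cv_pct is None


def test_missing_values_dropped_with_warning():
    with pytest.warns(UserWarning, match="missing"):
        p = PairedMeasurements([1, 2, 3], [1.0, np.nan, 3.0], [1.0, 2.0, 3.0])
    assert len(p) == 2
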