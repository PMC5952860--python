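"""Agreement and reproducibility statistics for paired joint measurements.

Implements the precision machinery of densitometry/HR-pQCT reproducibility
studies: the single-measure two-way random absolute-agreement intraclass
correlation ICC(2,1) with its F-based 95% confidence interval, the Glüer
short-term precision errors (SD_RMS and CV_RMS from duplicate measurements),
the least significant change LSC = 1.96 * sqrt(2) * precision error,
Bland–Altman limits of agreement, a paired t-test, and the per-stack motion
grade exclusion rule (grade > 3 on either scan excludes the stack; a joint is
excluded only when all of its stacks are).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "PrecisionReport",
    "StackGrades",
    "ExclusionResult",
    "icc_two_way_random_absolute",
    "icc_rating",
    "rms_precision",
    "lsc",
    "bland_altman",
    "paired_t",
    "apply_exclusions",
    "precision_report",
    "LSC_FACTOR",
]

#: LSC multiplier 1.96 * sqrt(2) = 2.7719...
LSC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class PairedMeasurements:
    """Duplicate measurements (scan1/scan2 or operator1/operator2) per subject."""

    subject_ids: list
    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if not (len(self.subject_ids) == len(self.m1) == len(self.m2)):
            raise ValueError("subject_ids, m1 and m2 must have equal length")
        missing = ~(np.isfinite(self.m1) & np.isfinite(self.m2))
        if missing.any():
            warnings.warn(
                f"dropping {int(missing.sum())} subject(s) with missing values",
                stacklevel=2,
            )
            keep = ~missing
            self.subject_ids = [s for s, k in zip(self.subject_ids, keep) if k]
            self.m1 = self.m1[keep]
            self.m2 = self.m2[keep]

    def __len__(self) -> int:
        return len(self.m1)

    @classmethod
    def from_csv(cls, path) -> "PairedMeasurements":
        """Load from a CSV with columns subject_id, m1, m2."""
        df = pd.read_csv(path)
        for col in ("subject_id", "m1", "m2"):
            if col not in df.columns:
                raise ValueError(f"CSV is missing required column {col!r}")
        return cls(df["subject_id"].tolist(), df["m1"].to_numpy(), df["m2"].to_numpy())


@dataclass
class PrecisionReport:
    """All agreement statistics for one outcome."""

    icc: float
    icc_ci95: tuple[float, float]
    icc_rating: str
    sd_rms: float
    cv_rms_pct: float | None
    lsc_sd: float
    lsc_cv_pct: float | None
    bland_altman: dict
    paired_t: dict

    def as_dict(self) -> dict:
        return {
            "icc": self.icc,
            "icc_ci95": list(self.icc_ci95),
            "icc_rating": self.icc_rating,
            "sd_rms": self.sd_rms,
            "cv_rms_pct": self.cv_rms_pct,
            "lsc_sd": self.lsc_sd,
            "lsc_cv_pct": self.lsc_cv_pct,
            "bland_altman": self.bland_altman,
            "paired_t": self.paired_t,
        }


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, columns=raters).

    Returns (MSR, MSC, MSE): mean squares for rows, columns and residual.
    """
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way_random_absolute(
    pm: PairedMeasurements, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Single-measure ICC(2,1): two-way random effects, absolute agreement.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the 95% confidence interval from the F-based method of McGraw & Wong
    (Satterthwaite degrees of freedom for the denominator).
    """
    n = len(pm)
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    x = np.column_stack([pm.m1, pm.m2])
    k = 2
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate data: zero total variance")
    icc = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or mse == 0:
        return float(icc), (float(icc), float(icc))
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v
    f_lower = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_upper = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = (n * (msr - f_lower * mse)) / (
        f_lower * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = (n * (f_upper * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_upper * msr
    )
    return float(icc), (float(lo), float(hi))


def icc_rating(icc: float) -> str:
    """Qualitative rating bands: < 0.40 poor, 0.40–0.60 fair, 0.60–0.75 good,
    0.75–1.00 excellent. Boundary values go to the higher band."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.60:
        return "good"
    if icc >= 0.40:
        return "fair"
    return "poor"


def rms_precision(pm: PairedMeasurements) -> tuple[float, float | None]:
    """Glüer short-term precision from duplicate measurements.

    Per subject j with pair (x1, x2): SD_j = |x1 - x2| / sqrt(2) and
    CV_j = 100 * SD_j / mean_j; then SD_RMS = sqrt(mean SD_j^2) and
    CV_RMS = sqrt(mean CV_j^2). CV_RMS is None (n.a.) when any subject mean is
    zero — as happens for count outcomes — since the CV is then undefined.
    """
    if len(pm) < 1:
        raise ValueError("need at least one pair")
    d = pm.m1 - pm.m2
    sd_j = np.abs(d) / math.sqrt(2.0)
    sd_rms = float(np.sqrt((sd_j**2).mean()))
    means = (pm.m1 + pm.m2) / 2.0
    if np.any(means == 0):
        return sd_rms, None
    cv_j = 100.0 * sd_j / np.abs(means)
    return sd_rms, float(np.sqrt((cv_j**2).mean()))


def lsc(precision_error: float) -> float:
    """Least significant change: 1.96 * sqrt(2) * precision error.

    Works on SD_RMS (absolute LSC) or CV_RMS (percent LSC) alike.
    """
    if precision_error < 0:
        raise ValueError("precision error must be >= 0")
    return LSC_FACTOR * precision_error


def bland_altman(pm: PairedMeasurements, plot_path=None) -> dict:
    """Bland–Altman mean difference and 95% limits of agreement.

    With ``plot_path`` a means-vs-differences plot is written (matplotlib
    required only in that case).
    """
    if len(pm) < 2:
        raise ValueError("need at least two pairs")
    d = pm.m1 - pm.m2
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        means = (pm.m1 + pm.m2) / 2.0
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(means, d, s=14, alpha=0.8)
        for y, style in ((mean_diff, "-"), (loa_lo, "--"), (loa_hi, "--")):
            ax.axhline(y, color="k", linestyle=style, linewidth=1)
        ax.set_xlabel("mean of pair")
        ax.set_ylabel("difference (m1 - m2)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return {"mean_diff": mean_diff, "loa_lo": float(loa_lo), "loa_hi": float(loa_hi)}


def paired_t(pm: PairedMeasurements) -> dict:
    """Two-sided paired t-test on the duplicate measurements."""
    if len(pm) < 2:
        raise ValueError("need at least two pairs")
    d = pm.m1 - pm.m2
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance of differences: t undefined")
    t, p = stats.ttest_rel(pm.m1, pm.m2)
    return {"t": float(t), "p": float(p)}


def precision_report(
    pm: PairedMeasurements, count_outcome: bool = False, plot_path=None
) -> PrecisionReport:
    """All statistics for one outcome in a single report.

    ``count_outcome`` suppresses CV-based quantities (reported n.a.), as is
    conventional for discrete counts.
    """
    icc, ci = icc_two_way_random_absolute(pm)
    sd_rms, cv_rms = rms_precision(pm)
    if count_outcome:
        cv_rms = None
    try:
        t_res = paired_t(pm)
    except ValueError:
        t_res = {"t": float("nan"), "p": float("nan")}
    return PrecisionReport(
        icc=icc,
        icc_ci95=ci,
        icc_rating=icc_rating(icc),
        sd_rms=sd_rms,
        cv_rms_pct=cv_rms,
        lsc_sd=lsc(sd_rms),
        lsc_cv_pct=lsc(cv_rms) if cv_rms is not None else None,
        bland_altman=bland_altman(pm, plot_path),
        paired_t=t_res,
    )


@dataclass
class StackGrades:
    """Per-stack motion grades (1–5, Pialat scheme) of one joint's scan pair."""

    joint_id: str
    grades_scan1: list[int]
    grades_scan2: list[int]

    def __post_init__(self) -> None:
        if len(self.grades_scan1) != len(self.grades_scan2):
            raise ValueError("scan1/scan2 must grade the same number of stacks")
        for g in (*self.grades_scan1, *self.grades_scan2):
            if not (1 <= int(g) <= 5):
                raise ValueError(f"motion grade {g} outside 1..5")


@dataclass
class ExclusionResult:
    """Outcome of the motion-grade quality gate."""

    excluded_stacks: list[tuple[str, int]] = field(default_factory=list)
    excluded_joints: list[str] = field(default_factory=list)
    included_joints: list[str] = field(default_factory=list)

    @property
    def n_excluded_stacks(self) -> int:
        return len(self.excluded_stacks)


def apply_exclusions(
    grades: list[StackGrades], grade_max: int = 3
) -> ExclusionResult:
    """Exclude stacks with grade > ``grade_max`` on either scan.

    A stack poor on both scans counts once. A joint is excluded only when all
    of its stacks are excluded.
    """
    res = ExclusionResult()
    for sg in grades:
        bad = [
            i
            for i, (g1, g2) in enumerate(zip(sg.grades_scan1, sg.grades_scan2))
            if g1 > grade_max or g2 > grade_max
        ]
        res.excluded_stacks.extend((sg.joint_id, i) for i in bad)
        if len(bad) == len(sg.grades_scan1):
            res.excluded_joints.append(sg.joint_id)
        else:
            res.included_joints.append(sg.joint_id)
    return res
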