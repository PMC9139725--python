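"""Agreement and diagnostic-accuracy statistics for segmentations and volumes.

Covers the battery used to compare predicted against reference
segmentations and one reader against another: Dice overlap, Bland–Altman
limits of agreement, two-way random-effects ICC (absolute agreement, single
measure), Pearson r², confusion-matrix accuracy with exact binomial CIs,
and subgroup comparisons by Welch's t-test or the Mann–Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .calibrate import BinomialCI, clopper_pearson
from .imaging_io import SegMask, check_same_grid


@dataclass
class AgreementStats:
    dice: float | None
    pearson_r2: float
    bland_altman_mean_diff: float
    bland_altman_loa: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    n: int


@dataclass
class AccuracyStats:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: BinomialCI | None
    specificity: BinomialCI | None


@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]
    degenerate: bool = False


def dice(a: SegMask, b: SegMask) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|).

    Two empty masks agree perfectly: the result is 1.0 (with a warning,
    since overlap is then vacuous).
    """
    check_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def bland_altman(x, y) -> tuple[float, tuple[float, float]]:
    """Bland–Altman mean difference and 95% limits of agreement for paired
    measurements: differences x - y, limits mean ± 1.96·SD (n-1 denominator)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd)


def icc_agreement(x, y) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC (ICC(2,1))
    with its F-based 95% CI, for two raters measuring the same cases."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 pairs")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return ICCResult(icc=np.nan, ci=(np.nan, np.nan), degenerate=True)
    n = x.size
    long = pd.DataFrame(
        {
            "case": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "value": np.concatenate([x, y]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=long, targets="case", raters="rater", ratings="value"
        )
    table = table.set_index("Type")
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"  # naming varies by version
    row = table.loc[key]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(icc=float(row["ICC"]), ci=(float(lo), float(hi)))


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation of two paired series."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def accuracy(pred_flags, truth_flags) -> AccuracyStats:
    """Confusion counts and sensitivity/specificity with exact binomial CIs.

    A side with an empty denominator (no true positives+false negatives, or
    no true negatives+false positives) is reported as None.
    """
    pred = np.asarray(pred_flags, dtype=bool)
    truth = np.asarray(truth_flags, dtype=bool)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("flag sequences must be equal-length and 1-D")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    sens = clopper_pearson(tp, tp + fn) if tp + fn > 0 else None
    spec = clopper_pearson(tn, tn + fp) if tn + fp > 0 else None
    return AccuracyStats(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec)


def compare_subgroups(values_a, values_b, kind: str = "rank"):
    """Two-sample comparison of a statistic between subgroups.

    ``kind='mean'`` uses Welch's unequal-variance t-test; ``kind='rank'``
    uses the Mann–Whitney U test (exact when both groups have at most 8
    observations, otherwise the tie-corrected normal approximation with
    continuity correction).  Returns ``(statistic, p_value)``.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two observations")
    if kind == "mean":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError("degenerate groups: no variance")
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if kind == "rank":
        method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"kind must be 'mean' or 'rank', got {kind!r}")


def volume_agreement(x, y, dice_value: float | None = None) -> AgreementStats:
    """Bundle the continuous-agreement battery for paired volume series."""
    mean_diff, loa = bland_altman(x, y)
    icc = icc_agreement(x, y)
    return AgreementStats(
        dice=dice_value,
        pearson_r2=pearson_r2(x, y),
        bland_altman_mean_diff=mean_diff,
        bland_altman_loa=loa,
        icc=icc.icc,
        icc_ci=icc.ci,
        n=int(np.asarray(x).size),
    )
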