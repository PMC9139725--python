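import itertools

import numpy as np
import pytest

from pefquant.errors import GridMismatchError
from pefquant.evaluate import (
    accuracy,
    bland_altman,
    compare_subgroups,
    dice,
    icc_agreement,
    pearson_r2,
)
from tests.conftest import make_mask


def icc2_1_anova(x, y):
    """Brute-force ICC(2,1) from the two-way ANOVA mean squares."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )


class TestDice:
    def test_identical_masks(self):
        m = make_mask((8, 8, 8), (1, 1, 1), where=np.s_[:4])
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = make_mask((8, 8, 8), (1, 1, 1), where=np.s_[:2])
        b = make_mask((8, 8, 8), (1, 1, 1), where=np.s_[6:])
        assert dice(a, b) == 0.0

    def test_partial_overlap_arithmetic(self):
        # |a| = |b| = 100, overlap 75 -> 2*75/200
        a = make_mask((10, 10, 10), (1, 1, 1), where=np.s_[0, :, :])
        b = np.zeros((10, 10, 10), np.uint8)
        b[0, :, :] = 1
        b[0, 0, :] = 0  # drop 10
        b[0, 1, :] = 0  # drop 10
        b[0, 2, 5:] = 0  # drop 5
        b[1, 0, :] = 1
        b[1, 1, :] = 1
        b[1, 2, :5] = 1
        from pefquant.imaging_io import SegMask

        bm = SegMask(b, (1, 1, 1))
        assert bm.n_voxels == 100
        assert dice(a, bm) == pytest.approx(0.75)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = make_mask((8, 8, 8), (1, 1, 1), where=rng.random((8, 8, 8)) > 0.5)
        b = make_mask((8, 8, 8), (1, 1, 1), where=rng.random((8, 8, 8)) > 0.5)
        assert dice(a, b) == dice(b, a)

    def test_both_empty_is_one_with_warning(self):
        a = make_mask((4, 4, 4), (1, 1, 1))
        with pytest.warns(UserWarning):
            assert dice(a, a) == 1.0

    def test_grid_mismatch(self):
        with pytest.raises(GridMismatchError):
            dice(make_mask((4, 4, 4), (1, 1, 1)), make_mask((4, 4, 5), (1, 1, 1)))


class TestBlandAltman:
    def test_identical_series(self):
        md, loa = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert md == 0 and loa == (0, 0)

    def test_constant_offset(self):
        x = np.array([10.0, 20.0, 30.0])
        md, loa = bland_altman(x, x + 5)
        assert md == pytest.approx(-5)
        assert loa == (pytest.approx(-5), pytest.approx(-5))

    def test_against_direct_recomputation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(200, 50, 40), rng.normal(200, 50, 40)
        md, (lo, hi) = bland_altman(x, y)
        d = x - y
        assert md == pytest.approx(d.mean(), abs=1e-10)
        assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-10)
        assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-10)
        assert md == pytest.approx(x.mean() - y.mean(), abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        res = icc_agreement(x, x)
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(2)
        case = rng.normal(0, 3, 60)
        x = case + rng.normal(0, 1, 60)
        y = case + rng.normal(0, 1, 60)
        res = icc_agreement(x, y)
        assert res.icc == pytest.approx(icc2_1_anova(x, y), abs=1e-10)

    def test_shuffled_pairing_destroys_agreement(self):
        rng = np.random.default_rng(3)
        x = rng.normal(100, 20, 200)
        y = rng.permutation(x)
        assert abs(icc_agreement(x, y).icc) < 0.2

    def test_known_variance_components(self):
        # case variance 9, error variance 1 -> ICC ~ 0.9
        rng = np.random.default_rng(4)
        case = rng.normal(0, 3, 500)
        x = case + rng.normal(0, 1, 500)
        y = case + rng.normal(0, 1, 500)
        res = icc_agreement(x, y)
        assert res.icc == pytest.approx(0.9, abs=0.05)
        assert res.ci[0] < res.icc < res.ci[1]

    def test_degenerate_flagged(self):
        res = icc_agreement([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.degenerate


class TestPearson:
    def test_linear_is_one(self):
        x = np.arange(10.0)
        assert pearson_r2(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson_r2(x, -x) == pytest.approx(1.0)  # sign-blind

    def test_independent_near_zero(self):
        rng = np.random.default_rng(5)
        assert pearson_r2(rng.normal(size=10_000), rng.normal(size=10_000)) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAccuracy:
    def test_all_correct(self):
        res = accuracy([True] * 10 + [False] * 10, [True] * 10 + [False] * 10)
        assert res.sensitivity.estimate == 100.0
        assert res.specificity.estimate == 100.0

    def test_printed_confusion_interval(self):
        pred = [True] * 97 + [False] * 3 + [False] * 100
        truth = [True] * 100 + [False] * 100
        res = accuracy(pred, truth)
        assert (res.tp, res.fn, res.tn, res.fp) == (97, 3, 100, 0)
        assert res.sensitivity.estimate == pytest.approx(97.00)
        assert res.sensitivity.lower == pytest.approx(91.48, abs=0.005)
        assert res.sensitivity.upper == pytest.approx(99.38, abs=0.005)
        assert res.specificity.lower == pytest.approx(96.38, abs=0.005)
        assert res.specificity.upper == 100.0

    def test_against_brute_force_counts(self):
        rng = np.random.default_rng(6)
        pred = rng.random(200) > 0.5
        truth = rng.random(200) > 0.5
        res = accuracy(pred, truth)
        brute = {
            "tp": sum(p and t for p, t in zip(pred, truth)),
            "fp": sum(p and not t for p, t in zip(pred, truth)),
            "tn": sum(not p and not t for p, t in zip(pred, truth)),
            "fn": sum(not p and t for p, t in zip(pred, truth)),
        }
        assert (res.tp, res.fp, res.tn, res.fn) == tuple(brute.values())

    def test_one_class_flags_undefined_side(self):
        res = accuracy([True, False], [True, True])
        assert res.specificity is None
        assert res.sensitivity is not None


class TestSubgroupComparisons:
    def test_identical_groups_rank_p_one(self):
        stat, p = compare_subgroups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], kind="rank")
        assert p == pytest.approx(1.0, abs=0.05)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 50)
        b = rng.normal(3, 1, 50)
        for kind in ("mean", "rank"):
            _, p = compare_subgroups(a, b, kind=kind)
            assert p < 1e-3

    def test_u_statistic_matches_exhaustive_enumeration(self):
        """Exact U and its permutation p-value on a tiny fixed example."""
        a = np.array([3.1, 1.2, 5.0, 2.2])
        b = np.array([0.5, 2.8, 1.9])
        u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        stat, p = compare_subgroups(a, b, kind="rank")
        assert stat == u_brute
        # exhaustive permutation distribution of U
        pooled = np.concatenate([a, b])
        us = []
        for idx in itertools.combinations(range(7), 4):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(7) if i not in idx]]
            us.append(sum((x > y) + 0.5 * (x == y) for x in ga for y in gb))
        us = np.array(us)
        n1n2 = a.size * b.size
        p_brute = np.mean(np.minimum(us, n1n2 - us) <= min(u_brute, n1n2 - u_brute))
        assert p == pytest.approx(p_brute, abs=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_subgroups([1.0], [2.0, 3.0], kind="mean")
        with pytest.raises(ValueError):
            compare_subgroups([1.0, 1.0], [1.0, 1.0], kind="mean")
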