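"""Weighted kappa, ICC(2,1), bootstrap CIs and the interpretation bands.

The kappa and ICC implementations are checked against independent
brute-force formula evaluations and against sklearn / pingouin as
external oracles.
"""

import numpy as np
import pingouin as pg
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from frailgait.agreement import (
    DegenerateAgreementError,
    RatingSet,
    bootstrap_ci,
    evaluate_agreement,
    icc,
    interpret_band,
    weighted_kappa,
)


def _brute_force_kappa(actual, predicted, categories, power):
    """Direct double-loop evaluation of the weighted-kappa formula."""
    k = len(categories)
    n = len(actual)
    idx = {c: i for i, c in enumerate(categories)}
    p = np.zeros((k, k))
    for a, b in zip(actual, predicted):
        p[idx[a], idx[b]] += 1.0 / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (abs(i - j) / (k - 1)) ** power
            num += w * p[i, j]
            den += w * row[i] * col[j]
    return 1.0 - num / den


def _brute_force_icc21(actual, predicted):
    """ICC(2,1) from an explicit two-way ANOVA decomposition."""
    data = np.stack([np.asarray(actual, float), np.asarray(predicted, float)], 1)
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
    resid = data - data.mean(1)[:, None] - data.mean(0)[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def _random_ratings(rng, n=60):
    return (rng.integers(3, 7, size=n), rng.integers(3, 7, size=n))


class TestWeightedKappa:
    def test_identical_ratings_give_kappa_one(self, rng):
        a = rng.integers(3, 7, size=50)
        r = RatingSet(a, a.copy())
        assert weighted_kappa(r) == pytest.approx(1.0)
        assert weighted_kappa(r, "linear") == pytest.approx(1.0)

    def test_independent_raters_give_kappa_near_zero(self):
        rng = np.random.default_rng(123)
        a, b = rng.integers(3, 7, 10_000), rng.integers(3, 7, 10_000)
        assert abs(weighted_kappa(RatingSet(a, b))) < 0.05

    @pytest.mark.parametrize("power,weights", [(1, "linear"), (2, "quadratic")])
    def test_matches_brute_force_formula_to_1e12(self, power, weights, rng):
        for _ in range(20):
            a, b = _random_ratings(rng)
            got = weighted_kappa(RatingSet(a, b), weights)
            want = _brute_force_kappa(a, b, (3, 4, 5, 6), power)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_matches_sklearn_oracle(self, weights, rng):
        for _ in range(10):
            a, b = _random_ratings(rng)
            got = weighted_kappa(RatingSet(a, b), weights)
            want = cohen_kappa_score(a, b, weights=weights,
                                     labels=[3, 4, 5, 6])
            assert got == pytest.approx(want, abs=1e-10)

    def test_single_shared_category_is_degenerate(self):
        r = RatingSet([4] * 10, [4] * 10)
        with pytest.raises(DegenerateAgreementError):
            weighted_kappa(r)

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.lists(st.integers(3, 6), min_size=4, max_size=40),
        b=st.lists(st.integers(3, 6), min_size=4, max_size=40),
        seed=st.integers(0, 10_000),
    )
    def test_symmetry_and_subject_permutation_invariance(self, a, b, seed):
        n = min(len(a), len(b))
        a, b = np.asarray(a[:n]), np.asarray(b[:n])
        try:
            forward = weighted_kappa(RatingSet(a, b))
        except DegenerateAgreementError:
            return
        assert weighted_kappa(RatingSet(b, a)) == pytest.approx(forward, abs=1e-12)
        perm = np.random.default_rng(seed).permutation(n)
        assert weighted_kappa(RatingSet(a[perm], b[perm])) == pytest.approx(
            forward, abs=1e-12
        )
        assert forward <= 1.0 + 1e-12


class TestICC:
    def test_identical_ratings_with_variance_give_one(self):
        a = np.array([3, 4, 5, 6, 4, 5])
        assert icc(RatingSet(a, a.copy())) == pytest.approx(1.0)

    def test_matches_brute_force_anova_to_1e10(self, rng):
        for _ in range(20):
            a, b = _random_ratings(rng)
            got = icc(RatingSet(a, b))
            assert got == pytest.approx(_brute_force_icc21(a, b), abs=1e-10)

    def test_matches_pingouin_icc2_oracle(self, rng):
        a, b = _random_ratings(rng, n=80)
        df = pd.DataFrame({
            "subject": np.tile(np.arange(80), 2),
            "rater": np.repeat(["act", "pred"], 80),
            "score": np.concatenate([a, b]).astype(float),
        })
        table = pg.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score")
        # absolute-agreement single-rater row: labelled ICC2 or ICC(A,1)
        table = table.set_index("Type")
        key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
        want = float(table.loc[key, "ICC"])
        assert icc(RatingSet(a, b)) == pytest.approx(want, abs=1e-10)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateAgreementError):
            icc(RatingSet([4, 4, 4], [4, 4, 4]))

    def test_quadratic_kappa_and_icc_agree_asymptotically(self):
        # the near-identity that makes kappa and ICC coincide to ~3 decimals
        rng = np.random.default_rng(7)
        fl = np.clip(rng.normal(4.2, 0.9, 20_000), 3.0, 6.99)
        actual = np.floor(fl).astype(int)
        predicted = np.clip(
            np.floor(fl + rng.normal(0, 0.35, fl.size)).astype(int), 3, 6
        )
        r = RatingSet(actual, predicted)
        assert abs(weighted_kappa(r) - icc(r)) < 0.02


class TestBootstrap:
    def test_perfect_agreement_gives_unit_interval(self):
        a = np.array([3, 4, 5, 6] * 10)
        r = RatingSet(a, a.copy())
        lo, hi = bootstrap_ci(r, weighted_kappa, n_boot=200, seed=0)
        assert (lo, hi) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(5):
            a = rng.integers(3, 7, 100)
            b = np.clip(a + rng.integers(-1, 2, 100), 3, 6)
            r = RatingSet(a, b)
            point = weighted_kappa(r)
            lo, hi = bootstrap_ci(r, weighted_kappa, n_boot=300, seed=1)
            assert lo <= point <= hi

    def test_deterministic_given_seed(self, rng):
        a = rng.integers(3, 7, 80)
        b = np.clip(a + rng.integers(-1, 2, 80), 3, 6)
        r = RatingSet(a, b)
        assert bootstrap_ci(r, weighted_kappa, 200, seed=5) == bootstrap_ci(
            r, weighted_kappa, 200, seed=5
        )


class TestBands:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.866, "strong"),
            (0.20, "none"),
            (0.95, "almost perfect"),
            (0.90, "strong"),
            (0.905, "almost perfect"),
            (0.30, "minimal"),
            (0.50, "weak"),
            (0.70, "moderate"),
            (-0.2, "none"),
        ],
    )
    def test_band_assignment_as_printed(self, value, label):
        assert interpret_band(value) == label

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            interpret_band(1.5)


def test_full_evaluation_report_is_internally_consistent(rng):
    a = rng.integers(3, 7, 150)
    b = np.clip(a + (rng.random(150) < 0.2) * rng.integers(-1, 2, 150), 3, 6)
    res = evaluate_agreement(a, b, n_boot=300, seed=3)
    assert res.kappa_ci[0] <= res.kappa_w <= res.kappa_ci[1]
    assert res.icc_ci[0] <= res.icc <= res.icc_ci[1]
    assert res.kappa_band == interpret_band(res.kappa_w)
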