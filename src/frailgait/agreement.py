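"""Agreement between actual and predicted ordinal frailty ratings.

Cohen's weighted kappa with linear or quadratic disagreement weights,
the intraclass correlation ICC(2,1) (two-way random effects, absolute
agreement, single measurement), percentile-bootstrap confidence
intervals, and the conventional interpretation bands.

Quadratic weighting is the default: it is asymptotically equivalent to
ICC(2,1), which is why the two statistics typically agree to two or
three decimals on the same rating pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RatingSet",
    "AgreementResult",
    "DegenerateAgreementError",
    "weighted_kappa",
    "icc",
    "bootstrap_ci",
    "interpret_band",
    "evaluate_agreement",
]

DEFAULT_CATEGORIES = (3, 4, 5, 6)


class DegenerateAgreementError(ValueError):
    """The statistic is undefined on this rating set (no variance)."""


@dataclass(frozen=True)
class RatingSet:
    """Paired ordinal ratings (actual, predicted) on a shared category list."""

    actual: np.ndarray
    predicted: np.ndarray
    categories: tuple[int, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        a = np.asarray(self.actual, dtype=int)
        p = np.asarray(self.predicted, dtype=int)
        object.__setattr__(self, "actual", a)
        object.__setattr__(self, "predicted", p)
        if a.shape != p.shape or a.ndim != 1:
            raise ValueError("actual and predicted must be equal-length 1-D")
        if len(a) < 2:
            raise ValueError("at least 2 rating pairs are required")
        cats = set(self.categories)
        if not (set(a.tolist()) <= cats and set(p.tolist()) <= cats):
            raise ValueError("ratings outside the declared categories")

    def __len__(self) -> int:
        return len(self.actual)

    def take(self, idx: np.ndarray) -> "RatingSet":
        return RatingSet(self.actual[idx], self.predicted[idx], self.categories)


@dataclass(frozen=True)
class AgreementResult:
    kappa_w: float
    kappa_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    n_boot: int
    kappa_band: str
    icc_band: str


def _contingency(r: RatingSet) -> np.ndarray:
    cat = np.asarray(r.categories)
    k = len(cat)
    ia = np.searchsorted(cat, r.actual)
    ip = np.searchsorted(cat, r.predicted)
    table = np.bincount(ia * k + ip, minlength=k * k).reshape(k, k).astype(float)
    return table / len(r)


def _weights(k: int, kind: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if kind == "quadratic":
        return ((i - j) / (k - 1)) ** 2
    if kind == "linear":
        return np.abs(i - j) / (k - 1)
    raise ValueError(f"unknown weight kind {kind!r}")


def weighted_kappa(r: RatingSet, weights: str = "quadratic") -> float:
    """Cohen's weighted kappa, kappa_w = 1 - sum(w p) / sum(w e).

    ``p`` is the observed joint proportion table, ``e`` the product of
    its marginals, and ``w`` the disagreement weight matrix.
    """
    p = _contingency(r)
    w = _weights(p.shape[0], weights)
    e = np.outer(p.sum(axis=1), p.sum(axis=0))
    denom = float((w * e).sum())
    if denom == 0.0:
        raise DegenerateAgreementError(
            "all mass in a single category for both raters"
        )
    return 1.0 - float((w * p).sum()) / denom


def icc(r: RatingSet) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    With n subjects and k = 2 raters, from the two-way ANOVA mean squares
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    """
    if len(r) < 3:
        raise ValueError("ICC requires at least 3 subjects")
    data = np.stack([r.actual, r.predicted], axis=1).astype(float)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise DegenerateAgreementError("zero total variance in ratings")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(
        (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    )


def bootstrap_ci(
    r: RatingSet,
    statistic: Callable[[RatingSet], float],
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling subjects with pairs kept intact.

    Degenerate resamples (on which the statistic is undefined) are
    skipped; more than 50% degenerate resamples is an error.
    """
    rng = np.random.default_rng(seed)
    n = len(r)
    values = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(statistic(r.take(idx)))
        except DegenerateAgreementError:
            continue
    if len(values) < n_boot / 2:
        raise DegenerateAgreementError(
            f"{n_boot - len(values)}/{n_boot} bootstrap resamples degenerate"
        )
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


_BANDS = (
    (Decimal("0.20"), "none"),
    (Decimal("0.39"), "minimal"),
    (Decimal("0.59"), "weak"),
    (Decimal("0.79"), "moderate"),
    (Decimal("0.90"), "strong"),
)


def interpret_band(value: float) -> str:
    """Conventional agreement band of a kappa/ICC value.

    Values are rounded half-up to two decimals first, so a value in a
    printed gap (e.g. 0.905) lands in the nearer band (almost perfect),
    while the printed edge 0.90 itself stays "strong".
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError("agreement values lie in [-1, 1]")
    r = Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    for edge, label in _BANDS:
        if r <= edge:
            return label
    return "almost perfect"


def evaluate_agreement(
    actual: Sequence[int],
    predicted: Sequence[int],
    n_boot: int = 1000,
    seed: int | None = None,
    weights: str = "quadratic",
    categories: tuple[int, ...] = DEFAULT_CATEGORIES,
) -> AgreementResult:
    """Kappa + ICC with bootstrap CIs and interpretation bands."""
    r = RatingSet(np.asarray(actual), np.asarray(predicted), categories)
    kw = weighted_kappa(r, weights)
    ic = icc(r)
    k_ci = bootstrap_ci(r, lambda s: weighted_kappa(s, weights), n_boot, seed)
    i_ci = bootstrap_ci(r, icc, n_boot, None if seed is None else seed + 1)
    return AgreementResult(
        kappa_w=kw,
        kappa_ci=k_ci,
        icc=ic,
        icc_ci=i_ci,
        n_boot=n_boot,
        kappa_band=interpret_band(kw),
        icc_band=interpret_band(ic),
    )
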