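"""Statistical framework for segmentation evaluation and clinical validation.

Implements the normality-gated comparison scheme used throughout the
pipeline's reporting:

* samples are gated by the Shapiro–Wilk test (normal iff p >= 0.05),
* paired comparisons use the paired t-test on the normal branch and the
  Wilcoxon signed-rank test otherwise,
* unpaired comparisons use Welch's t-test on the normal branch and the
  Mann–Whitney U test otherwise,
* effect sizes are Cohen's d on t-branches and the rank-biserial
  correlation on rank branches,
* families of p-values are adjusted by Benjamini–Hochberg step-up FDR
  control,

plus confidence intervals from cross-validation fold means (t-interval),
Bland–Altman volumetric agreement (bias and 95% limits of agreement
bias ± 1.96·sd of the paired differences), and Fleiss' kappa for
multi-rater 3-point Likert tables with a configurable rating simulator.

Wilcoxon uses the exact null distribution for n <= 25 (after dropping
zero differences, the Wilcoxon convention) and the continuity-corrected
normal approximation above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsResult",
    "BlandAltmanResult",
    "RatingTable",
    "normality_gate",
    "compare_paired",
    "compare_unpaired",
    "bh_adjust",
    "fold_ci",
    "bland_altman",
    "fleiss_kappa",
    "rating_summary",
    "simulate_ratings",
    "LIKERT_CATEGORIES",
]

LIKERT_CATEGORIES = ("Poor", "Fair", "Excellent")

WILCOXON_EXACT_MAX_N = 25


@dataclass
class StatsResult:
    """Outcome of one statistical comparison."""

    test_name: str
    statistic: float
    p_value: float
    effect_size: float
    effect_size_type: str
    n: tuple[int, ...]
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    degenerate: bool = False
    note: str = ""
    p_adjusted: Optional[float] = None


@dataclass
class BlandAltmanResult:
    """Volumetric agreement: bias and 95% limits of agreement (cm^3)."""

    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray


@dataclass
class RatingTable:
    """Items x raters matrix of 3-point Likert categories."""

    ratings: np.ndarray  # dtype object/str, shape (n_items, n_raters)
    categories: tuple[str, ...] = LIKERT_CATEGORIES

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=object)
        if self.ratings.ndim != 2:
            raise ValueError("ratings must be an items x raters matrix")
        n_items, n_raters = self.ratings.shape
        if n_items < 2 or n_raters < 2:
            raise ValueError("need >= 2 items and >= 2 raters")
        bad = set(self.ratings.ravel()) - set(self.categories)
        if bad:
            raise ValueError(f"invalid rating categories: {sorted(bad)}")

    @property
    def n_items(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    def counts(self) -> np.ndarray:
        """(n_items, n_categories) category counts per item."""
        out = np.zeros((self.n_items, len(self.categories)), dtype=int)
        for j, cat in enumerate(self.categories):
            out[:, j] = (self.ratings == cat).sum(axis=1)
        return out


def normality_gate(sample: Sequence[float], alpha: float = 0.05) -> str:
    """Shapiro–Wilk gate: 'normal' iff p >= alpha, else 'non_normal'.

    Constant samples are non-normal by convention (flagged with a warning).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("normality test requires n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: treating as non-normal")
        return "non_normal"
    _, p = stats.shapiro(x)
    return "normal" if p >= alpha else "non_normal"


def _rank_biserial_wilcoxon(diffs: np.ndarray) -> float:
    """r = (W+ − W−)/(W+ + W−) over the ranks of |differences|."""
    ranks = stats.rankdata(np.abs(diffs))
    w_pos = ranks[diffs > 0].sum()
    w_neg = ranks[diffs < 0].sum()
    total = w_pos + w_neg
    return float((w_pos - w_neg) / total) if total > 0 else 0.0


def compare_paired(a: Sequence[float], b: Sequence[float],
                   force: Optional[str] = None) -> StatsResult:
    """Paired comparison of a vs b, gated on the differences.

    Normal differences: paired t-test with Cohen's d = mean(d)/sd(d).
    Otherwise: Wilcoxon signed-rank (zero differences dropped; exact null
    for n <= 25) with the rank-biserial correlation.  ``force`` overrides
    the gate ('parametric' or 'nonparametric').
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return StatsResult(
            test_name="degenerate",
            statistic=float("nan"),
            p_value=float("nan"),
            effect_size=0.0,
            effect_size_type="none",
            n=(len(a),),
            degenerate=True,
            note="all paired differences are zero",
        )
    if np.ptp(diffs) == 0:
        # constant nonzero shift: sd(diff) = 0, no test statistic is defined
        return StatsResult(
            test_name="degenerate",
            statistic=float("nan"),
            p_value=float("nan"),
            effect_size=float("nan"),
            effect_size_type="cohen_d",
            n=(len(a),),
            degenerate=True,
            note="zero-variance differences",
        )
    if force == "parametric":
        gate = "normal"
    elif force == "nonparametric":
        gate = "non_normal"
    else:
        gate = normality_gate(diffs) if len(diffs) >= 3 else "non_normal"
    if gate == "normal":
        sd = diffs.std(ddof=1)
        if sd == 0:
            return StatsResult(
                test_name="degenerate",
                statistic=float("nan"),
                p_value=float("nan"),
                effect_size=float("nan"),
                effect_size_type="cohen_d",
                n=(len(a),),
                degenerate=True,
                note="zero-variance differences",
            )
        t, p = stats.ttest_rel(a, b)
        d = diffs.mean() / sd
        return StatsResult("paired_t", float(t), float(p), float(d), "cohen_d", (len(a),))
    if len(nonzero) < 5:
        warnings.warn("fewer than 5 nonzero differences: Wilcoxon p is coarse")
    method = "exact" if len(nonzero) <= WILCOXON_EXACT_MAX_N else "approx"
    if method == "exact":
        stat, p = stats.wilcoxon(nonzero, alternative="two-sided", method="exact")
    else:
        stat, p = stats.wilcoxon(
            nonzero, alternative="two-sided", method="approx", correction=True
        )
    r = _rank_biserial_wilcoxon(nonzero)
    return StatsResult(
        "wilcoxon_signed_rank", float(stat), float(p), r, "rank_biserial",
        (len(a),), note=f"method={method}, zeros_dropped={len(diffs) - len(nonzero)}"
    )


def compare_unpaired(a: Sequence[float], b: Sequence[float],
                     force: Optional[str] = None) -> StatsResult:
    """Unpaired comparison, gated on each group's normality.

    Both normal: Welch's t-test with Cohen's d using the Welch-consistent
    denominator sqrt((s1^2 + s2^2)/2).  Otherwise: Mann–Whitney U with the
    rank-biserial correlation r = 2U/(n1 n2) − 1, U counting wins of ``a``.
    ``force`` overrides the gate ('parametric' or 'nonparametric').
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    constant = np.ptp(a) == 0 and np.ptp(b) == 0
    if force == "parametric":
        gate_a = gate_b = "normal"
    elif force == "nonparametric":
        gate_a = gate_b = "non_normal"
    else:
        gate_a = normality_gate(a) if np.ptp(a) > 0 else "non_normal"
        gate_b = normality_gate(b) if np.ptp(b) > 0 else "non_normal"
    if gate_a == "normal" and gate_b == "normal":
        t, p = stats.ttest_ind(a, b, equal_var=False)
        denom = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        d = (a.mean() - b.mean()) / denom if denom > 0 else float("nan")
        return StatsResult("welch_t", float(t), float(p), float(d), "cohen_d",
                           (len(a), len(b)))
    if constant and np.all(a == b[0]):
        return StatsResult(
            "degenerate", float("nan"), float("nan"), 0.0, "none",
            (len(a), len(b)), degenerate=True, note="both groups constant and equal",
        )
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    r = 2.0 * float(u) / (len(a) * len(b)) - 1.0
    return StatsResult("mann_whitney_u", float(u), float(p), r, "rank_biserial",
                       (len(a), len(b)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_ci(fold_values: Sequence[float], level: float = 0.95):
    """t-interval over cross-validation fold means.

    Returns (mean, ci_low, ci_high) with half-width
    ``t_{k−1, 1−α/2} · sd/sqrt(k)``.
    """
    x = np.asarray(fold_values, dtype=float)
    k = len(x)
    if k < 2:
        raise ValueError("need at least 2 folds for a CI")
    mean = x.mean()
    se = x.std(ddof=1) / np.sqrt(k)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=k - 1)
    return float(mean), float(mean - tcrit * se), float(mean + tcrit * se)


def bland_altman(pred: Sequence[float], ref: Sequence[float]) -> BlandAltmanResult:
    """Bland–Altman agreement of paired volume measurements.

    bias = mean(pred − ref); 95% limits of agreement = bias ± 1.96·sd of
    the differences (n−1 denominator).
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("paired measurement vectors differ in length")
    if len(pred) < 2:
        raise ValueError("need n >= 2 pairs")
    diffs = pred - ref
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(pred + ref) / 2.0,
        differences=diffs,
    )


def fleiss_kappa(table: RatingTable) -> dict:
    """Fleiss' kappa κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) plus per-category proportions.

    When every rating falls in a single category, chance agreement
    saturates (P̄ₑ = 1) and κ is undefined; this is flagged rather than
    returned as a number.
    """
    counts = table.counts()
    n_raters = counts.sum(axis=1)
    if np.ptp(n_raters) != 0:
        raise ValueError("rater count must be constant across items")
    p_cat = counts.sum(axis=0) / counts.sum()
    p_e = float((p_cat ** 2).sum())
    if p_e >= 1.0:
        warnings.warn(
            "all ratings in one category: agreement is perfect but "
            "chance-saturated; kappa undefined"
        )
        return {
            "kappa": float("nan"),
            "category_proportions": dict(zip(table.categories, p_cat)),
            "defined": False,
        }
    kappa = float(_sm_fleiss_kappa(counts, method="fleiss"))
    return {
        "kappa": kappa,
        "category_proportions": dict(zip(table.categories, p_cat)),
        "defined": True,
    }


def rating_summary(table: RatingTable) -> dict:
    """Category percentages over all item x rater cells (sum to 100)."""
    counts = table.counts().sum(axis=0)
    pct = 100.0 * counts / counts.sum()
    return dict(zip(table.categories, pct))


def simulate_ratings(
    n_items: int,
    n_raters: int,
    category_probs: Sequence[float] = (0.017, 0.091, 0.892),
    agreement: float = 0.9,
    seed: int = 0,
) -> RatingTable:
    """Simulate a Likert :class:`RatingTable` with controllable agreement.

    Each item draws a latent consensus category from ``category_probs``
    (ordered Poor, Fair, Excellent); each rater reports the consensus with
    probability ``agreement`` and otherwise redraws from the marginal.
    """
    probs = np.asarray(category_probs, dtype=float)
    if probs.shape != (len(LIKERT_CATEGORIES),) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("category_probs must be 3 probabilities summing to 1")
    if not 0 <= agreement <= 1:
        raise ValueError("agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cats = np.array(LIKERT_CATEGORIES, dtype=object)
    latent = rng.choice(3, size=n_items, p=probs)
    ratings = np.empty((n_items, n_raters), dtype=object)
    for i in range(n_items):
        for j in range(n_raters):
            if rng.random() < agreement:
                ratings[i, j] = cats[latent[i]]
            else:
                ratings[i, j] = cats[rng.choice(3, p=probs)]
    return RatingTable(ratings=ratings)


def compare_metric_table(
    metrics: pd.DataFrame,
    group_col: str = "diagnosis",
    metric_cols: Sequence[str] = ("dsc", "hd_mm", "asd_mm", "precision", "recall"),
) -> list[StatsResult]:
    """Cohort comparison (e.g. prostate vs cervical) per metric column.

    Runs the gated unpaired comparison for every metric and applies
    Benjamini–Hochberg adjustment across the family before returning.
    """
    groups = metrics[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in {group_col!r}, got {groups}")
    g1 = metrics[metrics[group_col] == groups[0]]
    g2 = metrics[metrics[group_col] == groups[1]]
    results = []
    for col in metric_cols:
        a = g1[col].dropna().to_numpy()
        b = g2[col].dropna().to_numpy()
        res = compare_unpaired(a, b)
        res.note = (res.note + f" metric={col}").strip()
        results.append(res)
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results
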