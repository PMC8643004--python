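"""Cohort-level statistics for the posture features.

The screening pipeline applied per feature across the five severity groups:

1. Kolmogorov-Smirnov normality screen per group;
2. one-way ANOVA when every group looks normal, otherwise Kruskal-Wallis;
3. pairwise post hoc tests over all C(5,2) = 10 group pairs, Bonferroni
   corrected to alpha' = 0.05 / 10 = 0.005;
4. Spearman rank correlation between each feature and the severity score.

The KS screen uses the sample's own mean and SD, which is known to be
conservative (the Lilliefors problem); ``normality_test`` exposes a
Lilliefors-corrected variant for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidInputError, UndefinedStatisticError
from .geometry import FEATURE_NAMES

__all__ = [
    "TestResult",
    "CorrelationResult",
    "ALPHA",
    "normality_test",
    "omnibus_group_test",
    "pairwise_posthoc",
    "spearman",
    "summarize_cohort",
    "group_summary_table",
]

#: uncorrected significance level used throughout
ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    corrected_alpha: float = ALPHA
    groups: tuple[int, ...] | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha


@dataclass(frozen=True)
class CorrelationResult:
    r_s: float
    p_value: float


def normality_test(sample, lilliefors: bool = False) -> TestResult:
    """Kolmogorov-Smirnov test against a normal with the sample's mean and SD.

    With ``lilliefors=True`` the p-value is corrected for the estimated
    parameters (Lilliefors); the plain KS p-value is otherwise reported.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise InvalidInputError("normality test needs a 1-D sample with n >= 4")
    sd = x.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("normality undefined for a constant sample")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return TestResult(float(stat), float(p), "lilliefors")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(float(stat), float(p), "kolmogorov-smirnov")


def omnibus_group_test(groups: Sequence, lilliefors: bool = False) -> TestResult:
    """Omnibus comparison of a feature across severity groups.

    One-way ANOVA when every group passes the normality screen at 0.05,
    Kruskal-Wallis (tie-corrected) otherwise; ``test_name`` records which
    branch ran.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise InvalidInputError("need at least 2 non-empty groups")
    all_normal = True
    for s in samples:
        try:
            if normality_test(s, lilliefors=lilliefors).p_value < ALPHA:
                all_normal = False
                break
        except (InvalidInputError, UndefinedStatisticError):
            all_normal = False
            break
    if all_normal:
        stat, p = sps.f_oneway(*samples)
        return TestResult(float(stat), float(p), "anova")
    stat, p = sps.kruskal(*samples)
    return TestResult(float(stat), float(p), "kruskal-wallis")


def pairwise_posthoc(groups: Sequence, omnibus: TestResult) -> list[TestResult]:
    """All pairwise group comparisons, Bonferroni corrected.

    The pairwise test matches the omnibus branch: two-sample t-tests after
    ANOVA, Mann-Whitney U after Kruskal-Wallis. Each result carries the
    corrected alpha 0.05 / C(k,2); its ``significant`` flag uses it.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise InvalidInputError("need at least 2 groups")
    pairs = list(combinations(range(len(samples)), 2))
    alpha_corr = ALPHA / len(pairs)
    parametric = omnibus.test_name == "anova"
    out: list[TestResult] = []
    for i, j in pairs:
        if parametric:
            stat, p = sps.ttest_ind(samples[i], samples[j])
            name = "t-test"
        else:
            stat, p = sps.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            name = "mann-whitney"
        out.append(TestResult(float(stat), float(p), name, alpha_corr, groups=(i, j)))
    return out


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p-value)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise InvalidInputError("spearman needs two equal-length samples with n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise UndefinedStatisticError("spearman undefined for a constant input")
    r, p = sps.spearmanr(xa, ya)
    return CorrelationResult(float(r), float(p))


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-severity-group n, mean and SD (ddof=1) of every feature.

    Returns a DataFrame indexed by score 0..4 with a MultiIndex column per
    (feature, statistic); SD of a single-subject group is reported as NaN.
    """
    if "score" not in cohort.columns:
        raise InvalidInputError("cohort table must have a 'score' column")
    scores = cohort["score"]
    if scores.isna().any():
        raise InvalidInputError("missing severity scores in cohort")
    if not scores.isin(range(5)).all():
        raise InvalidInputError("scores must lie in 0..4")
    features = [f for f in FEATURE_NAMES if f in cohort.columns]
    rows = {}
    for score, grp in cohort.groupby("score"):
        row: dict[tuple[str, str], float] = {("", "n"): len(grp)}
        for f in features:
            row[(f, "mean")] = grp[f].mean()
            row[(f, "sd")] = grp[f].std(ddof=1)  # NaN for n=1
        rows[score] = row
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    out.index.name = "score"
    return out


def group_summary_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Human-readable per-group summary: one 'mean ± SD' string column per
    feature plus the numeric columns, groups as rows."""
    summ = summarize_cohort(cohort)
    features = sorted({f for f, _ in summ.columns if f})
    table = pd.DataFrame(index=summ.index)
    table["n"] = summ[("", "n")].astype(int)
    for f in features:
        mean, sd = summ[(f, "mean")], summ[(f, "sd")]
        table[f] = [
            f"{m:.1f} ± {s:.1f}" if np.isfinite(s) else f"{m:.1f}"
            for m, s in zip(mean, sd)
        ]
        table[f + "_mean"] = mean
        table[f + "_sd"] = sd
    return table
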