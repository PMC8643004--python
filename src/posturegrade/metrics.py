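"""Human-machine agreement metrics.

Three ingredients of model selection and evaluation for the severity grader:

* the model-selection objective ``f`` — the mean absolute score deviation
  plus a penalty of ``lam`` per *gross* error (machine off by more than one
  severity class), so minimizing ``f`` prefers trees whose mistakes stay
  within one class of the clinician;
* macro one-vs-rest accuracy / sensitivity / specificity, turning the
  5-class grading problem into five binary problems and averaging;
* ICC(2,1) — the two-way random-effects, absolute-agreement, single-measures
  intraclass correlation between two score series, with its 95% CI from the
  F-distribution method. Absolute agreement is the clinically meaningful
  form here: a grader with a systematic offset from the clinician is *not*
  consistent, even if perfectly correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidInputError, UndefinedStatisticError

__all__ = ["ObjectiveConfig", "GradingMetrics", "ICCResult", "objective",
           "macro_ovr_metrics", "icc"]


@dataclass(frozen=True)
class ObjectiveConfig:
    """Weight of the gross-error penalty in the selection objective."""

    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise InvalidInputError("lambda must be non-negative")


def objective(doc, machine, cfg: ObjectiveConfig = ObjectiveConfig()) -> float:
    """Selection objective f = mean(|doc - machine|) + lam * #{|doc - machine| > 1}.

    Zero iff the two score series are identical; the count term uses a
    strict inequality, so an error of exactly one class is not penalized
    beyond its contribution to the mean.
    """
    d = np.asarray(doc, dtype=float)
    m = np.asarray(machine, dtype=float)
    if d.shape != m.shape or d.ndim != 1 or d.size == 0:
        raise InvalidInputError("doc and machine scores must be equal-length, non-empty 1-D")
    err = np.abs(d - m)
    return float(err.mean() + cfg.lam * int(np.sum(err > 1)))


@dataclass(frozen=True)
class GradingMetrics:
    """Macro one-vs-rest metrics over the severity classes present in truth."""

    accuracy: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def macro_ovr_metrics(y_true, y_pred) -> GradingMetrics:
    """Macro-averaged one-vs-rest accuracy, sensitivity and specificity.

    Each severity class present in ``y_true`` defines one binary
    class-vs-rest problem; binary accuracy, sensitivity TP/(TP+FN) and
    specificity TN/(TN+FP) are computed per problem and averaged without
    class-size weights. Classes absent from ``y_true`` are skipped.
    """
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise InvalidInputError("y_true and y_pred must be equal-length, non-empty 1-D")
    n = t.size
    accs, sens, specs = [], [], []
    for c in np.unique(t):
        tp = int(np.sum((t == c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        fp = int(np.sum((t != c) & (p == c)))
        tn = n - tp - fn - fp
        accs.append((tp + tn) / n)
        sens.append(tp / (tp + fn))
        if tn + fp > 0:
            specs.append(tn / (tn + fp))
    return GradingMetrics(
        accuracy=float(np.mean(accs)),
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(specs)) if specs else float("nan"),
    )


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) point estimate with its 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict[str, float]:
        return {"estimate": self.estimate, "ci_low": self.ci_low, "ci_high": self.ci_high}


def icc(a, b, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``a`` and ``b`` are the two raters' scores of the same subjects (e.g.
    clinician vs machine). Computed from the two-way ANOVA mean squares
    (rows = subjects, columns = raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the confidence interval from the F-distribution method
    (Satterthwaite degrees of freedom for the lower/upper bounds).
    """
    x = np.column_stack([np.asarray(a, dtype=float), np.asarray(b, dtype=float)])
    if x.ndim != 2 or x.shape[0] < 3:
        raise InvalidInputError("need at least 3 paired scores")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("scores must be finite")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise UndefinedStatisticError("ICC undefined: zero total variance")

    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedStatisticError("ICC undefined: degenerate mean squares")
    est = float((msr - mse) / denom)

    if mse == 0 and msc == 0:
        # perfect agreement: the interval degenerates to the estimate
        lo = hi = est
    else:
        # Satterthwaite df for the F bounds (McGraw & Wong)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_ = k * est / (n * (1 - est)) if est != 1 else np.inf
            b_ = 1 + k * est * (n - 1) / (n * (1 - est)) if est != 1 else np.inf
        if np.isinf(a_) or np.isinf(b_):
            v = (n - 1) * (k - 1)
        else:
            num = (a_ * msc + b_ * mse) ** 2
            den = (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else (n - 1) * (k - 1)
        f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
        common = k * msc + (k * n - k - n) * mse
        lo = float(n * (msr - f_lo * mse) / (f_lo * common + n * msr))
        hi = float(n * (f_hi * msr - mse) / (common + n * f_hi * msr))

    lo = max(-1.0, min(lo, est))
    hi = min(1.0, max(hi, est))
    return ICCResult(estimate=est, ci_low=lo, ci_high=hi)
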