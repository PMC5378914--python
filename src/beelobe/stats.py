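"""Normality-gated test selection, effect sizes, and Fisher's exact test.

The study's statistical workflow: test each sample for normality
(Shapiro-Wilk) and, for independent designs, for equal variances (F-test);
when both gates pass (p > 0.05) run a Student's t-test (paired or
unpaired per design), otherwise the non-parametric counterpart —
Mann-Whitney U for independent samples, Wilcoxon signed-rank for paired.
Tests are two-tailed unless a directional prior is declared.  Effect sizes
are Cohen's d against the pooled SD, binned as negligible (< 0.2), small
(0.2-0.5), medium (0.5-0.8) or large (> 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonSpec",
    "CohortResult",
    "select_and_run",
    "cohens_d",
    "effect_category",
    "variance_f_test",
    "exclusion_table",
]

#: |d| bin edges for negligible / small / medium / large.
EFFECT_BINS = (0.2, 0.5, 0.8)

#: Sample size up to which exact Mann-Whitney/Wilcoxon p-values are used
#: (above, the tie-corrected normal approximation).
EXACT_N_MAX = 25


@dataclass(frozen=True)
class ComparisonSpec:
    """What to compare and how."""

    metric: str = ""
    design: str = "independent"          # "independent" | "paired"
    tails: str = "two"                   # "two" | "one"
    direction: Optional[str] = None      # "greater"|"less" (x relative to y)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.design not in ("independent", "paired"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.tails not in ("one", "two"):
            raise ValueError(f"unknown tails {self.tails!r}")
        if self.tails == "one" and self.direction not in ("greater", "less"):
            raise ValueError("one-tailed comparisons require a direction")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def alternative(self) -> str:
        return self.direction if self.tails == "one" else "two-sided"


@dataclass
class CohortResult:
    """One executed comparison with its diagnostics."""

    test_used: str
    p_value: float
    effect_size_d: Optional[float]
    effect_category: Optional[str]
    n_x: int
    n_y: int
    shapiro_p_x: Optional[float] = None
    shapiro_p_y: Optional[float] = None
    f_test_p: Optional[float] = None
    significant: Optional[bool] = None
    notes: Tuple[str, ...] = ()


def effect_category(d: float) -> str:
    a = abs(d)
    if a < EFFECT_BINS[0]:
        return "negligible"
    if a < EFFECT_BINS[1]:
        return "small"
    if a < EFFECT_BINS[2]:
        return "medium"
    return "large"


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled standard deviation.

    ``d = (mean(x) - mean(y)) / sqrt(((n1-1) s1^2 + (n2-1) s2^2)
    / (n1 + n2 - 2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2 for Cohen's d")
    pooled = np.sqrt(
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        / (x.size + y.size - 2)
    )
    if pooled == 0:
        raise ValueError("pooled SD is zero: effect size undefined")
    return float((x.mean() - y.mean()) / pooled)


def variance_f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test for equal variances of two independent samples."""
    if x.size < 2 or y.size < 2:
        return 1.0     # variance not estimable; the normality gate decides
    s1, s2 = x.var(ddof=1), y.var(ddof=1)
    if s1 == 0 and s2 == 0:
        return 1.0
    if s2 == 0 or s1 == 0:
        return 0.0
    f = s1 / s2
    p = sps.f.cdf(f, x.size - 1, y.size - 1)
    return float(2.0 * min(p, 1.0 - p))


def _shapiro_p(x: np.ndarray) -> Optional[float]:
    if x.size < 3 or np.ptp(x) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def select_and_run(
    x: Sequence[float],
    y: Sequence[float],
    spec: ComparisonSpec,
) -> CohortResult:
    """Run the gated test-selection workflow on two samples.

    ``x`` is the first-named arm (e.g. solvent) and ``y`` the second; a
    one-tailed spec with direction "greater" tests x > y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if spec.design == "paired" and x.size != y.size:
        raise ValueError("paired design requires equal sample sizes")
    notes = []

    px, py = _shapiro_p(x), _shapiro_p(y)
    if px is None or py is None:
        notes.append(
            "normality not assessable (n < 3 or constant sample): "
            "non-parametric fallback"
        )
        normal = False
    else:
        normal = px > 0.05 and py > 0.05
    fp = None
    if spec.design == "independent":
        fp = variance_f_test(x, y)
        equal_var = fp > 0.05
    else:
        equal_var = True
    alt = spec.alternative

    if normal and equal_var:
        if spec.design == "paired":
            res = sps.ttest_rel(x, y, alternative=alt)
            test = "t"
        else:
            res = sps.ttest_ind(x, y, equal_var=True, alternative=alt)
            test = "t"
        p = float(res.pvalue)
    elif spec.design == "paired":
        test = "wilcoxon"
        diff = x - y
        if np.all(diff == 0):
            notes.append("all paired differences zero: p = 1")
            p = 1.0
        else:
            method = ("exact" if x.size <= EXACT_N_MAX
                      and np.unique(np.abs(diff[diff != 0])).size
                      == np.count_nonzero(diff) else "approx")
            res = sps.wilcoxon(x, y, alternative=alt, method=method)
            p = float(res.pvalue)
    else:
        test = "mannwhitney"
        pooled = np.concatenate([x, y])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (max(x.size, y.size) <= EXACT_N_MAX
                             and no_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative=alt, method=method)
        p = float(res.pvalue)

    d = cat = None
    if x.size >= 2 and y.size >= 2:
        try:
            d = cohens_d(x, y)
            cat = effect_category(d)
        except ValueError as err:
            notes.append(str(err))
    return CohortResult(
        test_used=test,
        p_value=p,
        effect_size_d=d,
        effect_category=cat,
        n_x=int(x.size),
        n_y=int(y.size),
        shapiro_p_x=px,
        shapiro_p_y=py,
        f_test_p=fp,
        significant=bool(p < spec.alpha),
        notes=tuple(notes),
    )


def exclusion_table(counts: Sequence[Sequence[int]]) -> CohortResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Used for comparing exclusion (or distinctness) rates between treatment
    arms.  A zero margin makes the table uninformative: p = 1 is returned
    with a warning.
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("counts must be a non-negative 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("zero margin: Fisher's exact p set to 1", stacklevel=2)
        p = 1.0
    else:
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return CohortResult(
        test_used="fisher",
        p_value=p,
        effect_size_d=None,
        effect_category=None,
        n_x=int(table[0].sum()),
        n_y=int(table[1].sum()),
        significant=bool(p < 0.05),
    )
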