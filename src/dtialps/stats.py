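"""Cohort statistics: two-sample and paired t, χ², Spearman, partial Pearson.

Two-sample t-tests accept either raw samples or printed summaries
(mean, SD, n) — group comparisons published as mean ± SD can be re-checked
without per-subject data, and the summary and sample paths share one
formula so they agree exactly when the summaries come from the samples.
Welch (unpooled variances, Welch–Satterthwaite df) is the default variant;
Student's pooled-variance t is available. All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "GroupSummary",
    "two_sample_t",
    "paired_t",
    "chi_square_2x2",
    "spearman",
    "pearson_partial",
    "adjust_pvalues",
    "welch_replicates",
]


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its degrees of freedom, p-value and provenance."""

    statistic: float
    df: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "method": self.method,
            "n": list(self.n),
        }


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary of one group: mean ± SD with sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary needs n ≥ 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


def _as_summary(x) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    if isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0]):
        return GroupSummary(float(x[0]), float(x[1]), int(x[2]))
    return GroupSummary.from_sample(x)


def two_sample_t(a, b, variant: str = "welch") -> StatResult:
    """Two-sample t-test from raw samples or (mean, sd, n) summaries.

    variant "welch": t = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂) with Welch–Satterthwaite
    df; "student": pooled variance, df = n₁+n₂−2.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    if sa.sd == 0 and sb.sd == 0:
        raise ValueError("zero variance in both groups; t undefined")
    va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
    if variant == "welch":
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (
            va**2 / (sa.n - 1) + vb**2 / (sb.n - 1)
        )
        method = "welch_t"
    elif variant == "student":
        sp2 = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / (sa.n + sb.n - 2)
        se = np.sqrt(sp2 * (1 / sa.n + 1 / sb.n))
        df = sa.n + sb.n - 2
        method = "student_t"
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'welch' or 'student'")
    t = (sa.mean - sb.mean) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(float(t), float(df), float(p), method, (sa.n, sb.n))


def paired_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Paired t-test on within-subject differences (df = n − 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and equally long")
    if x.size < 2:
        raise ValueError("paired t needs n ≥ 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("all paired differences identical; t undefined")
    t = d.mean() / (sd / np.sqrt(d.size))
    df = d.size - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(float(t), float(df), float(p), "paired_t", (d.size,))


def chi_square_2x2(counts, yates: bool = True) -> StatResult:
    """Pearson χ² on a 2×2 table, with Yates continuity correction by default."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin; χ² undefined")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=yates)
    method = "chi2_yates" if yates else "chi2_plain"
    return StatResult(float(chi2), float(df), float(p), method, (int(table.sum()),))


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation (mid-ranks for ties), p via t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs equal-length samples with n ≥ 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    df = x.size - 2
    return StatResult(float(rho), float(df), float(p), "spearman", (int(x.size),))


def pearson_partial(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Iterable[Sequence[float]] = (),
) -> StatResult:
    """Pearson correlation of x and y after regressing out the covariates.

    Both variables are residualized by least squares on the covariates plus
    an intercept; with no covariates this is the plain Pearson correlation.
    df = n − 2 − (number of covariates) for the t-approximation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = [np.asarray(c, dtype=float) for c in covariates]
    n = x.size
    if y.size != n:
        raise ValueError("x and y must be equally long")
    k = len(cov)
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} for {k} covariate(s); got n = {n}")
    design = np.column_stack([np.ones(n)] + cov) if k else np.ones((n, 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"collinear covariates: design rank {rank} < {design.shape[1]} columns"
        )
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("a residualized variable is constant")
    r = float((rx * ry).sum() / denom)
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df) if abs(r) < 1 else 0.0
    return StatResult(r, float(df), float(p), "pearson_partial", (n,))


def welch_replicates(
    a: GroupSummary,
    b: GroupSummary,
    n_replicates: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch t and p over many replicate two-group normal cohorts.

    Each replicate draws fresh samples of sizes (a.n, b.n) from
    N(a.mean, a.sd²) and N(b.mean, b.sd²) and applies the Welch test —
    used for type-I-error calibration (equal means) and for checking that
    a printed effect size is internally consistent with its printed t.
    Vectorized across replicates; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    xa = rng.normal(a.mean, a.sd, size=(n_replicates, a.n))
    xb = rng.normal(b.mean, b.sd, size=(n_replicates, b.n))
    va = xa.var(axis=1, ddof=1) / a.n
    vb = xb.var(axis=1, ddof=1) / b.n
    t = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p


def adjust_pvalues(pvals: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-comparison adjustment: Benjamini–Hochberg or Bonferroni."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}; use 'bh' or 'bonferroni'")
    return multipletests(p, method=key)[1]
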