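"""Contingency-table and duration statistics for cohort comparisons.

Implements the tests used on rearrangement cohorts: the uncorrected Pearson
r×c chi-squared test, post-hoc pairwise chi-squared with Benjamini–Hochberg
FDR adjustment, two-sample t-tests, one-way ANOVA with Wilks' Λ, and exact
integer count reconstruction from printed group sizes and percentages.

No Yates continuity correction is applied anywhere: published 2×2 values
(e.g. X² = 6.1774 on the vangl2 Roll/No-Roll table) are reproduced exactly by
the uncorrected statistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "TestResult",
    "pearson_chi2",
    "posthoc_pairwise_chi2",
    "counts_from_percentages",
    "two_sample_t",
    "oneway_anova_wilks",
    "dunnett_approx",
]


@dataclass
class ContingencyTable:
    """Labeled r×c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: Optional[List[str]] = None
    col_labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("counts must be a 2-D table with at least 2 rows and 2 columns")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.sum() == 0:
            raise ValueError("grand total must be positive")
        r, c = self.counts.shape
        if self.row_labels is None:
            self.row_labels = [f"row{i}" for i in range(r)]
        if self.col_labels is None:
            self.col_labels = [f"col{j}" for j in range(c)]
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths must match the table shape")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    df: Union[int, Tuple[int, int], None]
    p_value: float
    method: str
    adjusted_p: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        df = self.df if self.df is not None else "-"
        s = f"{self.method}: statistic={self.statistic:.4f}, df={df}, p={self.p_value:.4g}"
        if self.adjusted_p is not None:
            s += f", adj. p={self.adjusted_p:.4g}"
        return s


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Uncorrected Pearson chi-squared test of independence.

    ``X² = Σ (O − E)² / E`` with expectations from the row/column margins and
    ``df = (r − 1)(c − 1)``; the p-value is the upper chi-squared tail.
    """
    obs = table.counts.astype(float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError(
            "table has an all-zero row or column (expected count 0): collapse those categories"
        )
    expected = row @ col / n
    x2 = float(((obs - expected) ** 2 / expected).sum())
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    p = float(sps.chi2.sf(x2, df))
    return TestResult(statistic=x2, df=df, p_value=p, method="pearson-chi2",
                      extra={"expected": expected})


def posthoc_pairwise_chi2(
    table: ContingencyTable,
    axis: str = "cols",
    adjust: str = "bh_fdr",
) -> List[TestResult]:
    """Pairwise chi-squared tests between groups along one axis.

    Each pair of groups yields a sub-table (categories that are all-zero
    within the sub-table are dropped); p-values are Benjamini–Hochberg
    adjusted when ``adjust='bh_fdr'``.
    """
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    if adjust not in ("bh_fdr", "none"):
        raise ValueError("adjust must be 'bh_fdr' or 'none'")
    counts = table.counts if axis == "cols" else table.counts.T
    groups = table.col_labels if axis == "cols" else table.row_labels
    cats = table.row_labels if axis == "cols" else table.col_labels
    if counts.shape[1] < 3:
        raise ValueError("need >= 3 groups for post-hoc comparisons; use pearson_chi2")

    results = []
    for i, j in itertools.combinations(range(counts.shape[1]), 2):
        sub = counts[:, [i, j]]
        keep = sub.sum(axis=1) > 0
        sub_table = ContingencyTable(
            counts=sub[keep],
            row_labels=[c for c, k in zip(cats, keep) if k],
            col_labels=[groups[i], groups[j]],
        )
        res = pearson_chi2(sub_table)
        res.method = f"pearson-chi2[{groups[i]} vs {groups[j]}]"
        results.append(res)
    if adjust == "bh_fdr":
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    return results


def counts_from_percentages(n: int, percents: Sequence[float]) -> np.ndarray:
    """Reconstruct the integer counts behind printed percentages.

    Returns the composition of ``n`` minimizing the maximum absolute
    deviation of ``100·count/n`` from the printed percentages, requiring the
    reconstruction to round back to every printed value (half-up, to the
    printed precision).  Ties are broken by the largest-remainder rule; other
    compositions attaining the same deviation are reported in a warning.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    p = np.asarray(percents, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 100.0) > 1.0:
        raise ValueError("percentages must be non-negative and sum to 100 within 1")

    # decimals printed: match reconstruction precision to the input precision
    def _decimals(x: float) -> int:
        s = f"{x:.10f}".rstrip("0")
        return max(0, len(s.split(".")[1])) if "." in s else 0

    dec = max(_decimals(x) for x in p)
    scale = 10.0**dec

    # candidate range per category around the quota n*p/100
    quotas = n * p / 100.0
    ranges = [
        range(max(0, int(np.floor(q - 2))), min(n, int(np.ceil(q + 2))) + 1) for q in quotas
    ]

    def _consistent(vec) -> bool:
        pct = 100.0 * np.asarray(vec) / n
        rounded = np.floor(pct * scale + 0.5) / scale
        return bool(np.all(np.abs(rounded - p) < 0.5 / scale + 1e-9))

    best_dev = np.inf
    candidates: List[Tuple[int, ...]] = []
    for vec in itertools.product(*ranges[:-1]):
        last = n - sum(vec)
        if last not in ranges[-1]:
            continue
        full = vec + (last,)
        dev = float(np.max(np.abs(100.0 * np.asarray(full) / n - p)))
        if dev < best_dev - 1e-12:
            best_dev = dev
            candidates = [full]
        elif abs(dev - best_dev) <= 1e-12:
            candidates.append(full)

    candidates = [c for c in candidates if _consistent(c)]
    if not candidates:
        raise ValueError(
            f"no integer composition of {n} rounds to the printed percentages {tuple(p)}"
        )
    if len(candidates) > 1:
        # largest-remainder apportionment as the tie-break
        floor = np.floor(quotas).astype(int)
        rem = quotas - floor
        give = n - floor.sum()
        order = np.argsort(-rem)
        lr = floor.copy()
        lr[order[:give]] += 1
        lr_t = tuple(int(v) for v in lr)
        chosen = lr_t if lr_t in candidates else sorted(candidates)[0]
        others = [c for c in candidates if c != chosen]
        warnings.warn(
            f"multiple compositions match within deviation {best_dev:.3f}: "
            f"chose {chosen}, alternatives {others}",
            stacklevel=2,
        )
        return np.array(chosen, dtype=int)
    return np.array(candidates[0], dtype=int)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], variant: str = "student"
) -> TestResult:
    """Two-sample two-tailed t-test (Student pooled-variance or Welch)."""
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, int(x.size + y.size - 2), 1.0,
                              f"t-test[{variant}]", extra={"degenerate": True})
        return TestResult(float("inf"), int(x.size + y.size - 2), 0.0,
                          f"t-test[{variant}]", extra={"degenerate": True})
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    df = float(res.df)
    return TestResult(float(res.statistic), df if variant == "welch" else int(df),
                      float(res.pvalue), f"t-test[{variant}]")


def _wilks_f_approx(lam: float, k: int, n_total: int, q: int) -> TestResult:
    """Rao's F approximation for one-way Wilks' Λ with q responses, k groups."""
    vh = k - 1
    ve = n_total - k
    if q * vh == 2:
        t = 1.0
    else:
        t = np.sqrt((q**2 * vh**2 - 4.0) / (q**2 + vh**2 - 5.0))
    w = ve + vh - (q + vh + 1) / 2.0
    df1 = q * vh
    df2 = w * t - (q * vh - 2.0) / 2.0
    lam_t = lam ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else float("inf")
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return TestResult(statistic=float(lam), df=(int(df1), float(df2)), p_value=p,
                      method="wilks-lambda", extra={"F_approx": float(f)})


def oneway_anova_wilks(groups: Sequence[np.ndarray]) -> dict:
    """One-way ANOVA per response plus multivariate Wilks' Λ across groups.

    ``groups`` is a list of ``(n_i, q)`` arrays (or 1-D vectors for a single
    response) observed jointly per subject.  Returns ``{"per_response":
    [TestResult per response], "wilks": TestResult}`` where the Wilks result
    carries Λ as its statistic and Rao's F approximation in ``extra``.
    """
    mats = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    mats = [m.T if m.shape[0] == 1 else m for m in mats]
    q = mats[0].shape[1]
    if len(mats) < 2 or any(m.shape[0] < 2 for m in mats):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if any(m.shape[1] != q for m in mats):
        raise ValueError("all groups must share the same responses")

    per_response = []
    for j in range(q):
        f, p = sps.f_oneway(*[m[:, j] for m in mats])
        if not np.isfinite(f):  # identical constant groups
            f, p = 0.0, 1.0
        k = len(mats)
        n_total = sum(m.shape[0] for m in mats)
        per_response.append(
            TestResult(float(f), (k - 1, n_total - k), float(p), "oneway-anova-F")
        )

    k = len(mats)
    n_total = sum(m.shape[0] for m in mats)
    grand = np.vstack(mats).mean(axis=0)
    w = np.zeros((q, q))
    b = np.zeros((q, q))
    for m in mats:
        mu = m.mean(axis=0)
        d = m - mu
        w += d.T @ d
        dm = (mu - grand)[:, None]
        b += m.shape[0] * (dm @ dm.T)
    det_t = np.linalg.det(w + b)
    if det_t <= 0 or np.linalg.det(w) < 0:
        raise ValueError("singular within-group covariance: drop a response")
    lam = float(np.linalg.det(w) / det_t) if det_t > 0 else 1.0
    lam = min(1.0, max(0.0, lam))
    wilks = _wilks_f_approx(lam, k, n_total, q)
    return {"per_response": per_response, "wilks": wilks}


def dunnett_approx(groups: Sequence[np.ndarray], control: int = 0) -> List[TestResult]:
    """Bonferroni-style conservative approximation to Dunnett's many-to-one test.

    Each treatment group is compared to the control with a pooled-variance
    t-test; two-tailed p-values are Bonferroni-adjusted over the number of
    comparisons.  This upper-bounds the exact Dunnett p-values and is clearly
    labeled as an approximation in the result method string.
    """
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("need a control plus at least one treatment group")
    m = len(arrs) - 1
    ctrl = arrs[control]
    results = []
    for i, g in enumerate(arrs):
        if i == control:
            continue
        res = two_sample_t(ctrl, g, variant="student")
        res.method = "dunnett-bonferroni-approx"
        res.adjusted_p = float(min(1.0, res.p_value * m))
        results.append(res)
    return results
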