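"""Group-comparison statistics: ANOVA with η², pooled t with Cohen's d,
Pearson χ², Mann-Whitney U, Spearman ρ, and Bonferroni adjustment.

Two entry styles are provided for the variance-based tests:

* raw-data (`anova_oneway`, `ttest_pooled`) — classical sums-of-squares
  decompositions computed from per-group samples;
* summary-statistics (`anova_from_summary`, `ttest_from_summary`) — the same
  statistics reconstructed exactly from per-group (n, mean, SD). For k groups
  with sizes nᵢ, means mᵢ and SDs sᵢ:

      SSB = Σ nᵢ (mᵢ − m̄)²,   SSW = Σ (nᵢ − 1) sᵢ²,
      F = (SSB/(k−1)) / (SSW/(N−k)),   η² = SSB / (SSB + SSW),

  which matches `anova_oneway` on any raw data having those summaries. This
  makes published group tables sufficient inputs for re-deriving reported
  F/t/d/η² values; agreement with published statistics is limited to ~0.5%
  relative by the rounding of the printed means and SDs.

The t-test is the pooled-variance form (df = n₁+n₂−2) and Cohen's d divides
the mean difference by the pooled SD. η² is the classical SSB/SST, not the
partial form. χ² is Pearson's statistic without continuity correction. Rank
ties are handled by average ranks throughout; the Mann-Whitney p-value uses
the normal approximation with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "StatResult",
    "ContingencyTable",
    "anova_oneway",
    "anova_from_summary",
    "ttest_pooled",
    "ttest_from_summary",
    "chi_square",
    "mann_whitney",
    "spearman",
    "bonferroni_adjust",
    "summarize_groups",
]


@dataclass(frozen=True)
class StatResult:
    """A named test statistic with df, p-value and effect size."""

    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float | None = None
    effect_name: str | None = None
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.adjusted_p is not None and not (0.0 <= self.adjusted_p <= 1.0):
            raise ValueError(f"adjusted_p {self.adjusted_p} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "effect_name": self.effect_name,
            "adjusted_p": self.adjusted_p,
        }


@dataclass(frozen=True)
class GroupSummary:
    """Per-group (label, n, mean, sd) sufficient statistics."""

    labels: tuple[str, ...]
    ns: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if not (len(self.ns) == len(self.means) == len(self.sds) == k):
            raise ValueError("labels, ns, means, sds must have equal length")
        if k < 2:
            raise ValueError("need at least two groups")
        if any(n < 2 for n in self.ns):
            raise ValueError("each group needs n >= 2 for variance-based tests")
        if any(s < 0 for s in self.sds):
            raise ValueError("SDs must be non-negative")

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, int, float, float]]) -> "GroupSummary":
        labels, ns, means, sds = zip(*rows)
        return cls(tuple(labels), tuple(int(n) for n in ns),
                   tuple(float(m) for m in means), tuple(float(s) for s in sds))

    def pair(self, a: str, b: str) -> "GroupSummary":
        """Restrict to the two named groups (for pairwise post hocs)."""
        idx = [self.labels.index(a), self.labels.index(b)]
        return GroupSummary(
            tuple(self.labels[i] for i in idx),
            tuple(self.ns[i] for i in idx),
            tuple(self.means[i] for i in idx),
            tuple(self.sds[i] for i in idx),
        )


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulated non-negative integer counts."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if arr.sum() <= 0:
            raise ValueError("contingency table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def summarize_groups(samples: dict[str, Sequence[float]]) -> GroupSummary:
    """Compute (n, mean, sample SD) per group from raw data."""
    rows = []
    for label, xs in samples.items():
        arr = np.asarray(xs, dtype=np.float64)
        rows.append((label, arr.size, float(arr.mean()), float(arr.std(ddof=1))))
    return GroupSummary.from_rows(rows)


def _anova_from_ss(ssb: float, ssw: float, k: int, n_total: int,
                   scale: float = 1.0) -> StatResult:
    df1, df2 = k - 1, n_total - k
    sst = ssb + ssw
    # SST at rounding-noise level (relative to the data's magnitude) means
    # all observations are identical
    if sst <= 1e-12 * n_total * max(1.0, scale):
        # all observations identical: no variation to apportion
        return StatResult("anova_oneway", 0.0, (float(df1), float(df2)), 1.0,
                          effect_size=0.0, effect_name="eta_squared")
    if ssw <= 0.0:
        # perfect separation with zero within-group variance
        return StatResult("anova_oneway", float("inf"), (float(df1), float(df2)), 0.0,
                          effect_size=1.0, effect_name="eta_squared")
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta2 = ssb / sst
    return StatResult("anova_oneway", float(f), (float(df1), float(df2)), p,
                      effect_size=float(eta2), effect_name="eta_squared")


def anova_oneway(samples: dict[str, Sequence[float]] | Sequence[Sequence[float]]) -> StatResult:
    """One-way fixed-effects ANOVA over ≥2 groups of raw observations."""
    if isinstance(samples, dict):
        groups = [np.asarray(v, dtype=np.float64) for v in samples.values()]
    else:
        groups = [np.asarray(v, dtype=np.float64) for v in samples]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    ns = np.array([g.size for g in groups], dtype=np.float64)
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    scale = float(np.mean(np.concatenate(groups) ** 2))
    return _anova_from_ss(ssb, ssw, len(groups), int(ns.sum()), scale=scale)


def anova_from_summary(summary: GroupSummary) -> StatResult:
    """One-way ANOVA reconstructed from per-group (n, mean, SD)."""
    ns = np.asarray(summary.ns, dtype=np.float64)
    means = np.asarray(summary.means, dtype=np.float64)
    sds = np.asarray(summary.sds, dtype=np.float64)
    n_total = float(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1.0) * sds**2).sum())
    scale = float((ns * (means**2 + sds**2)).sum() / n_total)
    return _anova_from_ss(ssb, ssw, len(summary.labels), int(n_total), scale=scale)


def _ttest_from_moments(n1: int, m1: float, s1: float,
                        n2: int, m2: float, s2: float) -> StatResult:
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    diff = m1 - m2
    if sp2 <= 0.0:
        if diff == 0.0:
            return StatResult("ttest_pooled", 0.0, (float(df),), 1.0,
                              effect_size=0.0, effect_name="cohens_d")
        raise ValueError("zero pooled variance with nonzero mean difference")
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    d = diff / np.sqrt(sp2)
    return StatResult("ttest_pooled", float(t), (float(df),), p,
                      effect_size=float(d), effect_name="cohens_d")


def ttest_pooled(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Independent-samples pooled-variance t-test with Cohen's d."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    return _ttest_from_moments(x.size, float(x.mean()), float(x.std(ddof=1)),
                               y.size, float(y.mean()), float(y.std(ddof=1)))


def ttest_from_summary(summary: GroupSummary) -> StatResult:
    """Pooled t-test from two groups' (n, mean, SD)."""
    if len(summary.labels) != 2:
        raise ValueError("ttest_from_summary needs exactly two groups")
    (n1, n2), (m1, m2), (s1, s2) = summary.ns, summary.means, summary.sds
    return _ttest_from_moments(n1, m1, s1, n2, m2, s2)


def chi_square(table: ContingencyTable) -> StatResult:
    """Pearson χ² of independence, no continuity correction."""
    obs = table.as_array().astype(np.float64)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("contingency table has a zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    # Cramér's V as the conventional effect size for r×c tables
    v = float(np.sqrt(chi2 / (obs.sum() * (min(obs.shape) - 1))))
    return StatResult("chi_square", chi2, (float(df),), p,
                      effect_size=v, effect_name="cramers_v")


def _average_ranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Mann-Whitney U from rank sums, normal approximation with tie correction.

    Reports U for the first sample: the number of (x, y) pairs with x > y,
    ties counting one half.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _average_ranks(combined)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if sigma2 <= 0.0:  # all observations tied
        p = 1.0
    else:
        z = (u1 - mu) / np.sqrt(sigma2)
        p = float(2.0 * sps.norm.sf(abs(z)))
    # rank-biserial correlation as effect size
    rb = 2.0 * u1 / (n1 * n2) - 1.0
    return StatResult("mann_whitney", float(u1), (float(n1), float(n2)), min(p, 1.0),
                      effect_size=float(rb), effect_name="rank_biserial")


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation: Pearson on average ranks, t-approximate p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rx, ry = _average_ranks(x), _average_ranks(y)
    sx, sy = rx.std(ddof=1), ry.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero rank variance (a variable is constant)")
    rho = float(np.cov(rx, ry, ddof=1)[0, 1] / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    n = x.size
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return StatResult("spearman", rho, (float(n - 2),), p,
                      effect_size=rho, effect_name="rho")


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni: adjusted p = min(1, p·m); m defaults to len(p_values)."""
    ps = list(p_values)
    if any(not (0.0 <= p <= 1.0) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, p * m) for p in ps]
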