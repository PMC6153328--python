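"""Group statistics computed from raw values or from (n, mean, sd) summaries.

Every test here is expressible in terms of the groups' sufficient
statistics, so published summary tables are enough to recompute F and t
statistics, partial eta squared, Cohen's f, Cohen's d, Hedges' g,
Tukey-Kramer post-hoc p-values, Type-III factorial effects, and
noncentral-t power/sample-size results.  Raw-data overloads agree with the
summary path to numerical precision.

Conventions: t-tests are Student pooled-variance by default (Welch
optional); Cohen's d uses the pooled two-group SD; Hedges' g applies the
small-sample factor J = 1 - 3/(4N - 9); the factorial uses Type-III
(unweighted-marginal-means) sums of squares with sum-to-zero coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "OneWayAnovaResult",
    "TTestResult",
    "TukeyPair",
    "FactorialEffect",
    "one_way_anova",
    "tukey_posthoc",
    "two_sample_t",
    "factorial_2x3",
    "sample_size_ttest",
    "cohens_d_from_summaries",
    "hedges_correction",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics for one group: n, mean, sample SD (ddof=1)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")

    @classmethod
    def from_values(cls, values, label: str = "") -> "GroupSummary":
        v = np.asarray(values, float)
        return cls(label=label, n=v.size, mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass
class OneWayAnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_p_sq: float
    cohens_f: float
    ms_within: float
    bf10: float | None = None
    bf_error: float | None = None


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    hedges_g: float
    mean_diff: float
    bf10: float | None = None
    bf_error: float | None = None


@dataclass
class TukeyPair:
    label_a: str
    label_b: str
    mean_diff: float
    q: float
    p: float
    cohens_d: float
    hedges_g: float


@dataclass
class FactorialEffect:
    effect: str
    F: float
    df_effect: int
    df_error: int
    p: float
    eta_p_sq: float
    cohens_f: float


def _as_summaries(groups: Sequence) -> list[GroupSummary]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupSummary):
            out.append(g)
        else:
            out.append(GroupSummary.from_values(g, label=f"g{i + 1}"))
    return out


def _effect_sizes(ssb: float, ssw: float) -> tuple[float, float]:
    eta = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    f = np.sqrt(eta / (1.0 - eta)) if eta < 1.0 else np.inf
    return eta, f


def one_way_anova(groups: Sequence, compute_bf: bool = False,
                  bf_rscale: float = 0.5) -> OneWayAnovaResult:
    """One-way between-subjects ANOVA from summaries or raw value arrays.

    SSW = sum (n_i - 1) s_i^2; SSB = sum n_i (m_i - grand mean)^2 with the
    size-weighted grand mean; partial eta squared = SSB/(SSB+SSW) and
    Cohen's f = sqrt(eta/(1-eta)).  Optionally attaches the JZS Bayes
    factor computed from the same summaries.
    """
    gs = _as_summaries(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in gs], float)
    means = np.array([g.mean for g in gs])
    sds = np.array([g.sd for g in gs])
    grand = float(np.average(means, weights=ns))
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    df_b = len(gs) - 1
    df_w = int(ns.sum()) - len(gs)
    msb, msw = ssb / df_b, ssw / df_w
    F = msb / msw if msw > 0 else np.inf
    p = float(sps.f.sf(F, df_b, df_w))
    eta, f = _effect_sizes(ssb, ssw)
    res = OneWayAnovaResult(F=F, df_between=df_b, df_within=df_w, p=p,
                            eta_p_sq=eta, cohens_f=f, ms_within=msw)
    if compute_bf:
        from .bayes import jzs_bf_anova_summaries

        bf = jzs_bf_anova_summaries(gs, rscale=bf_rscale)
        res.bf10, res.bf_error = bf.bf10, bf.error
    return res


def hedges_correction(n_total: int) -> float:
    """Small-sample bias factor J = 1 - 3/(4N - 9)."""
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def cohens_d_from_summaries(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float]:
    """(|d|, |g|) from two group summaries using the pooled two-group SD."""
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
    sp = np.sqrt(sp2)
    d = abs(g1.mean - g2.mean) / sp if sp > 0 else np.inf
    return d, d * hedges_correction(g1.n + g2.n)


def two_sample_t(g1, g2, method: str = "student", compute_bf: bool = False,
                 bf_rscale: float = float(np.sqrt(2) / 2)) -> TTestResult:
    """Independent-samples t-test from summaries or raw arrays.

    ``student`` pools the variances (df = n1 + n2 - 2); ``welch`` uses the
    Welch-Satterthwaite df.  Effect sizes always use the pooled SD.  The
    sign of t follows mean1 - mean2; d and g are reported as magnitudes.
    """
    a = g1 if isinstance(g1, GroupSummary) else GroupSummary.from_values(g1, "g1")
    b = g2 if isinstance(g2, GroupSummary) else GroupSummary.from_values(g2, "g2")
    diff = a.mean - b.mean
    if method == "student":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    elif method == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1)) if se > 0 else a.n + b.n - 2
    else:
        raise ValueError(f"unknown t-test method {method!r}")
    t = diff / se if se > 0 else np.inf * np.sign(diff) if diff != 0 else 0.0
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    d, g = cohens_d_from_summaries(a, b)
    res = TTestResult(t=float(t), df=float(df), p=p, cohens_d=d, hedges_g=g, mean_diff=diff)
    if compute_bf and np.isfinite(t):
        from .bayes import jzs_bf_ttest

        bf = jzs_bf_ttest(float(t), a.n, b.n, rscale=bf_rscale)
        res.bf10, res.bf_error = bf.bf10, bf.error
    return res


def tukey_posthoc(groups: Sequence, ms_within: float | None = None,
                  df_within: int | None = None) -> list[TukeyPair]:
    """Tukey-Kramer pairwise comparisons from group summaries.

    The studentized-range statistic uses the Kramer harmonic term
    sqrt(MSW/2 (1/n_i + 1/n_j)) for unequal n; p-values come from the
    studentized-range distribution with k groups and the ANOVA error df.
    Pairwise d and g use the two groups' pooled SD (not MSW), matching how
    pairwise effect sizes are conventionally reported alongside the test.
    """
    gs = _as_summaries(groups)
    k = len(gs)
    if ms_within is None or df_within is None:
        aov = one_way_anova(gs)
        ms_within, df_within = aov.ms_within, aov.df_within
    if df_within < 1:
        raise ValueError("df_within must be >= 1")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[i], gs[j]
            se = np.sqrt(ms_within / 2.0 * (1.0 / a.n + 1.0 / b.n))
            q = abs(a.mean - b.mean) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, df_within)) if np.isfinite(q) else 0.0
            d, g = cohens_d_from_summaries(a, b)
            out.append(
                TukeyPair(label_a=a.label, label_b=b.label, mean_diff=a.mean - b.mean,
                          q=float(q), p=min(p, 1.0), cohens_d=d, hedges_g=g)
            )
    return out


def _factorial_design_rows() -> np.ndarray:
    # sum-to-zero coded rows for the 2x3 grid, cells ordered (row-major):
    # (context0, stim0..2), (context1, stim0..2)
    # columns: intercept, context, stim1, stim2, context*stim1, context*stim2
    rows = []
    for a in (1.0, -1.0):
        for b in ((1.0, 0.0), (0.0, 1.0), (-1.0, -1.0)):
            rows.append([1.0, a, b[0], b[1], a * b[0], a * b[1]])
    return np.asarray(rows)


def factorial_2x3(cells, compute_interaction: bool = True) -> list[FactorialEffect]:
    """Type-III effects for a 2x3 between-subjects design from cell summaries.

    ``cells`` is a 2x3 nested sequence of GroupSummary (or raw arrays):
    rows = context levels, columns = stimulation groups.  Effect sums of
    squares are Wald quadratic forms on the sum-to-zero regression
    coefficients (equivalently contrasts of unweighted marginal means),
    with MS_error pooled from the within-cell variances.  Partial eta
    squared uses SS_effect/(SS_effect + SS_error).
    """
    grid = [[c if isinstance(c, GroupSummary) else GroupSummary.from_values(c, f"c{i}{j}")
             for j, c in enumerate(row)] for i, row in enumerate(cells)]
    if len(grid) != 2 or any(len(r) != 3 for r in grid):
        raise ValueError("cells must form a 2x3 grid")
    flat = [c for row in grid for c in row]
    ns = np.array([c.n for c in flat], float)
    means = np.array([c.mean for c in flat])
    sds = np.array([c.sd for c in flat])
    X = _factorial_design_rows()
    XtX = (X.T * ns) @ X
    Xty = (X.T * ns) @ means
    beta = np.linalg.solve(XtX, Xty)
    XtX_inv = np.linalg.inv(XtX)
    sse = float(np.sum((ns - 1) * sds**2))
    df_err = int(np.sum(ns - 1))
    mse = sse / df_err
    effects = {"context": [1], "stim": [2, 3]}
    if compute_interaction:
        effects["interaction"] = [4, 5]
    out = []
    for name, idx in effects.items():
        bi = beta[idx]
        Vi = XtX_inv[np.ix_(idx, idx)]
        ss = float(bi @ np.linalg.solve(Vi, bi))
        df_e = len(idx)
        F = (ss / df_e) / mse if mse > 0 else np.inf
        p = float(sps.f.sf(F, df_e, df_err))
        eta, f = _effect_sizes(ss, sse)
        out.append(FactorialEffect(effect=name, F=F, df_effect=df_e, df_error=df_err,
                                   p=p, eta_p_sq=eta, cohens_f=f))
    return out


def sample_size_ttest(d: float, alpha: float = 0.05, power: float = 0.80,
                      n_max: int = 100_000) -> int:
    """Smallest per-group n for a two-sided two-sample t-test.

    Power is evaluated exactly under the noncentral t with noncentrality
    d*sqrt(n/2) and df = 2n - 2.  The search floor is n = 2 (minimum
    admissible group size).
    """
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        ncp = d * np.sqrt(n / 2.0)
        achieved = float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
        if achieved >= power:
            return n
    raise RuntimeError(f"power {power} not reached for any n <= {n_max}")
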