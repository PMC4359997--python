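"""Statistical procedures for cohort comparisons.

Implements the exact battery used for group-level electrophysiology
summaries: one-proportion Z, pooled-variance Student t, one-way ANOVA,
Dunnett and Fisher-LSD post hoc comparisons against a control group,
Kruskal-Wallis with tie correction, Dunn rank post hoc, and mean +/- SE
summaries.  Everything is computed from the formulas directly; ``scipy``
supplies only the reference distributions (normal, t, F, chi-square).

The Dunnett family-wise adjustment is evaluated by seeded Monte Carlo on
the exact null of the maximum-|t| statistic: each treatment-vs-control t
shares the control-group mean and the pooled variance estimate, so the
vector of contrasts follows an equicorrelated multivariate t whose joint
tail is simulated directly from group-mean normals and a common chi-square
variance draw.  This handles arbitrary unbalanced designs and is
reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    """One omnibus or two-sample test: named statistic, df, p, method tag."""

    statistic: float
    statistic_name: str
    p_value: float
    df: Optional[tuple] = None
    sidedness: str = "two"
    method: str = ""
    flags: list = field(default_factory=list)


@dataclass
class Comparison:
    """One treatment-vs-control contrast inside a post hoc procedure."""

    index: int
    estimate: float
    statistic: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class PosthocResult:
    method: str
    control_index: int
    comparisons: list[Comparison]
    df: Optional[float] = None
    seed: Optional[int] = None


@dataclass
class MeanSE:
    n: int
    mean: float
    se: float
    flags: list = field(default_factory=list)


def mean_se(sample) -> MeanSE:
    """Mean and standard error (sample SD, n-1 denominator)."""
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n == 1:
        return MeanSE(n=1, mean=float(x[0]), se=0.0, flags=["n1"])
    return MeanSE(n=n, mean=float(x.mean()), se=float(x.std(ddof=1) / np.sqrt(n)))


def one_proportion_z(x: int, n: int, p0: float = 0.5, sided: str = "one") -> TestResult:
    """Z-test of an observed proportion x/n against p0.

    Null-SE denominator, no continuity correction.  One-sided p (the
    default) is the tail in the direction of the observed deviation,
    1 - Phi(|Z|); two-sided doubles it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError("x must be in [0, n]")
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    phat = x / n
    z = (phat - p0) / np.sqrt(p0 * (1 - p0) / n)
    if sided == "one":
        p = float(sps.norm.sf(abs(z)))
    elif sided == "two":
        p = float(2 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return TestResult(
        statistic=float(z),
        statistic_name="Z",
        p_value=p,
        df=None,
        sidedness=sided,
        method="one_proportion_z",
    )


def two_sample_t(a, b, pooled: bool = True) -> TestResult:
    """Student's t-test (pooled variance), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    if not pooled:
        raise NotImplementedError("only the pooled (Student) variant is provided")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    flags = []
    if denom == 0:
        # zero variance in both samples
        if a.mean() == b.mean():
            return TestResult(0.0, "t", 1.0, df=(df,), method="student_t", flags=["degenerate"])
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TestResult(float(t), "t", 0.0, df=(df,), method="student_t", flags=["degenerate"])
    t = (a.mean() - b.mean()) / denom
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(float(t), "t", p, df=(df,), method="student_t", flags=flags)


def _as_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    return gs


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA (F = MS_between / MS_within)."""
    gs = _as_groups(groups)
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    k = len(gs)
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    grand = np.concatenate(gs).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, gs)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b, df_w = k - 1, N - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ms_b == 0 else np.inf
        p = 1.0 if ms_b == 0 else 0.0
        return TestResult(float(f), "F", p, df=(df_b, df_w), method="one_way_anova", flags=["degenerate"])
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(float(f), "F", p, df=(df_b, df_w), method="one_way_anova")


def _pooled_mse(gs) -> tuple[float, int]:
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    k = len(gs)
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    return ss_within / (N - k), N - k


def _contrast_ts(gs, control_index):
    mse, df = _pooled_mse(gs)
    ctrl = gs[control_index]
    out = []
    for i, g in enumerate(gs):
        if i == control_index:
            continue
        est = g.mean() - ctrl.mean()
        se = np.sqrt(mse * (1 / g.size + 1 / ctrl.size))
        t = est / se if se > 0 else (0.0 if est == 0 else np.inf * np.sign(est))
        out.append((i, float(est), float(t)))
    return out, df


def dunnett_max_t_samples(
    ns: Sequence[int], control_index: int, df: int, n_mc: int, seed: int
) -> np.ndarray:
    """Monte-Carlo draws of max_j |t_j| under the global null.

    Group means are drawn N(0, 1/n_i), the shared variance estimate as
    chi2(df)/df; each contrast t is formed exactly as in the data path.
    """
    rng = np.random.default_rng(seed)
    ns = np.asarray(ns, dtype=float)
    n0 = ns[control_index]
    treat = [i for i in range(len(ns)) if i != control_index]
    means = rng.standard_normal((n_mc, len(ns))) / np.sqrt(ns)
    s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    ts = np.empty((n_mc, len(treat)))
    for j, i in enumerate(treat):
        ts[:, j] = (means[:, i] - means[:, control_index]) / (
            s * np.sqrt(1 / ns[i] + 1 / n0)
        )
    return np.abs(ts).max(axis=1)


def dunnett_critical_value(
    ns: Sequence[int], control_index: int, df: int, alpha: float = 0.05,
    n_mc: int = 1_000_000, seed: int = 0,
) -> float:
    """Two-sided Dunnett critical value |t| for family-wise level alpha."""
    maxt = dunnett_max_t_samples(ns, control_index, df, n_mc, seed)
    return float(np.quantile(maxt, 1 - alpha))


def dunnett_posthoc(
    groups, control_index: int = 0, alpha: float = 0.05,
    n_mc: int = 200_000, seed: int = 0,
) -> PosthocResult:
    """Dunnett many-to-one comparisons with Monte-Carlo adjusted p-values.

    Each adjusted p is P(max_j |T_j| >= |t_i|) under the joint null, which
    is always >= the unadjusted pooled-t p of the same contrast.
    """
    gs = _as_groups(groups)
    contrasts, df = _contrast_ts(gs, control_index)
    maxt = dunnett_max_t_samples([g.size for g in gs], control_index, df, n_mc, seed)
    comps = []
    for i, est, t in contrasts:
        p_un = float(2 * sps.t.sf(abs(t), df))
        p_adj = float((maxt >= abs(t)).mean())
        comps.append(Comparison(i, est, t, p_un, max(p_adj, p_un)))
    return PosthocResult("dunnett", control_index, comps, df=df, seed=seed)


def fisher_lsd(groups, control_index: int = 0) -> PosthocResult:
    """Fisher least-significant-difference: unadjusted pooled t vs control,
    using the omnibus ANOVA's MSE and error df."""
    gs = _as_groups(groups)
    contrasts, df = _contrast_ts(gs, control_index)
    comps = []
    for i, est, t in contrasts:
        p = float(2 * sps.t.sf(abs(t), df))
        comps.append(Comparison(i, est, t, p, p))
    return PosthocResult("fisher_lsd", control_index, comps, df=df)


def _ranks_and_ties(gs):
    pooled = np.concatenate(gs)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return ranks, counts


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    gs = _as_groups(groups)
    ranks, tie_counts = _ranks_and_ties(gs)
    ns = [g.size for g in gs]
    N = int(sum(ns))
    h = 0.0
    start = 0
    for n in ns:
        rbar = ranks[start : start + n].mean()
        h += n * (rbar - (N + 1) / 2) ** 2
        start += n
    h *= 12 / (N * (N + 1))
    tie_term = 1 - (tie_counts**3 - tie_counts).sum() / (N**3 - N)
    if tie_term == 0:
        # all observations identical
        return TestResult(0.0, "H", 1.0, df=(len(gs) - 1,), method="kruskal_wallis", flags=["degenerate"])
    h /= tie_term
    p = float(sps.chi2.sf(h, len(gs) - 1))
    return TestResult(float(h), "H", p, df=(len(gs) - 1,), method="kruskal_wallis")


def dunn_posthoc(groups, control_index: int = 0, adjust: str = "none") -> PosthocResult:
    """Dunn's rank-based many-to-one comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)] with the
    tie term T = sum(t^3 - t) / (12(N-1)).  ``adjust``: "none" (default) or
    "bonferroni".
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    gs = _as_groups(groups)
    ranks, tie_counts = _ranks_and_ties(gs)
    ns = [g.size for g in gs]
    N = int(sum(ns))
    rbars = []
    start = 0
    for n in ns:
        rbars.append(ranks[start : start + n].mean())
        start += n
    tie_T = float((tie_counts**3 - tie_counts).sum() / (12 * (N - 1)))
    var_core = N * (N + 1) / 12 - tie_T
    m = len(gs) - 1
    comps = []
    for i in range(len(gs)):
        if i == control_index:
            continue
        est = rbars[i] - rbars[control_index]
        se = np.sqrt(var_core * (1 / ns[i] + 1 / ns[control_index]))
        z = est / se if se > 0 else 0.0
        p = float(2 * sps.norm.sf(abs(z)))
        p_adj = p if adjust == "none" else min(1.0, m * p)
        comps.append(Comparison(i, float(est), float(z), p, p_adj))
    return PosthocResult(f"dunn_{adjust}", control_index, comps)
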