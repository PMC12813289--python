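"""Adaptive group comparisons with compact letter displays.

Two-group comparisons are selected by a normality/variance decision tree:
Shapiro-Wilk on each group, then an F-test (normal data) or Brown-Forsythe
test (non-normal data) for variance homogeneity, all at alpha = 0.05.

    normal, equal variance      -> unpaired two-tailed t-test
    normal, unequal variance    -> Welch's t-test
    non-normal, equal variance  -> Mann-Whitney U
    non-normal, unequal         -> Kolmogorov-Smirnov

More than two groups: one-way ANOVA with the Tukey-Kramer post hoc and a
capital letter display when every group is normal with homogeneous
variance; otherwise Kruskal-Wallis with Dunn's post hoc (Bonferroni) and a
lower-case display. Post hoc matrices are produced only when the omnibus
test is significant.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ALPHA",
    "GroupData",
    "DecisionTrace",
    "TestResult",
    "PosthocMatrix",
    "CLDResult",
    "assess_distribution",
    "select_two_group_test",
    "run_two_group",
    "adaptive_two_group",
    "one_way_anova_tukey",
    "kruskal_dunn",
    "adaptive_multi_group",
    "compact_letter_display",
]

ALPHA = 0.05

TWO_GROUP_TESTS = ("t", "welch", "mannwhitney", "ks")


class TooFewObservationsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupData:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0 or not np.all(np.isfinite(v)):
            raise ValueError("values must be a non-empty finite 1-D array")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DecisionTrace:
    """Record of the normality/variance decisions behind a test choice."""

    shapiro_p: dict  # label -> p
    variance_test: str  # "f" or "brown-forsythe"
    variance_p: float
    normal: bool
    equal_variance: bool
    selected_test: str
    alpha: float = ALPHA


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class PosthocMatrix:
    """Symmetric matrix of pairwise adjusted p-values (diagonal = 1)."""

    labels: tuple[str, ...]
    p_values: np.ndarray
    method: str  # "tukey-kramer" or "dunn"

    def __post_init__(self) -> None:
        p = np.asarray(self.p_values, dtype=float)
        k = len(self.labels)
        if p.shape != (k, k):
            raise ValueError("p_values must be k x k")
        if not np.allclose(p, p.T):
            raise ValueError("p_values must be symmetric")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        object.__setattr__(self, "p_values", p)

    def p(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.p_values[i, j])


@dataclass(frozen=True)
class CLDResult:
    """Compact letter display: groups sharing a letter are not
    significantly different."""

    letters: dict  # label -> letter string
    case: str  # "upper" or "lower"


def _f_test_variances(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test for equality of two Normal variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    F = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = sps.f.cdf(F, dfa, dfb)
    return float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))


def assess_distribution(
    a: GroupData, b: GroupData, alpha: float = ALPHA
) -> DecisionTrace:
    """Shapiro-Wilk per group, then F (normal) or Brown-Forsythe test.

    The data are called normal only when *both* groups pass Shapiro-Wilk.
    """
    for g in (a, b):
        if g.n < 3:
            raise TooFewObservationsError(
                f"group {g.label!r} has n={g.n} < 3 (normality untestable)"
            )
    sp = {g.label: float(sps.shapiro(g.values).pvalue) for g in (a, b)}
    normal = all(p >= alpha for p in sp.values())
    if normal:
        var_test = "f"
        var_p = _f_test_variances(a.values, b.values)
    else:
        var_test = "brown-forsythe"
        var_p = float(sps.levene(a.values, b.values, center="median").pvalue)
    equal = var_p >= alpha
    trace = DecisionTrace(
        shapiro_p=sp,
        variance_test=var_test,
        variance_p=var_p,
        normal=normal,
        equal_variance=equal,
        selected_test="",
        alpha=alpha,
    )
    object.__setattr__(trace, "selected_test", select_two_group_test(trace))
    return trace


def select_two_group_test(trace: DecisionTrace) -> str:
    """The four-way decision table mapping (normal, equal variance) to a
    two-sample test name."""
    if trace.normal:
        return "t" if trace.equal_variance else "welch"
    return "mannwhitney" if trace.equal_variance else "ks"


def _degenerate(a: GroupData, b: GroupData) -> bool:
    pooled = np.concatenate([a.values, b.values])
    return np.ptp(pooled) == 0


def run_two_group(a: GroupData, b: GroupData, test: str) -> TestResult:
    """Run one of the four two-sample tests, two-tailed.

    Mann-Whitney uses exact enumeration for n <= 8 per group (no ties) and
    the tie-corrected normal approximation otherwise.
    """
    if test not in TWO_GROUP_TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TWO_GROUP_TESTS}")
    if _degenerate(a, b):
        return TestResult(
            test=test,
            statistic=0.0,
            p_value=1.0,
            groups=(a.label, b.label),
            degenerate=True,
        )
    x, y = a.values, b.values
    if test == "t":
        r = sps.ttest_ind(x, y, equal_var=True)
    elif test == "welch":
        r = sps.ttest_ind(x, y, equal_var=False)
    elif test == "mannwhitney":
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (max(x.size, y.size) <= 8 and not has_ties) else (
            "asymptotic"
        )
        r = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    else:
        r = sps.ks_2samp(x, y)
    return TestResult(
        test=test,
        statistic=float(r.statistic),
        p_value=float(min(1.0, r.pvalue)),
        groups=(a.label, b.label),
    )


def adaptive_two_group(
    a: GroupData, b: GroupData, alpha: float = ALPHA
) -> tuple[DecisionTrace, TestResult]:
    """Full adaptive two-group procedure: assess, select, test."""
    trace = assess_distribution(a, b, alpha=alpha)
    return trace, run_two_group(a, b, trace.selected_test)


# ---------------------------------------------------------------------------
# multi-group
# ---------------------------------------------------------------------------


def _check_groups(groups: list[GroupData], min_n: int) -> None:
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use the two-group path otherwise")
    for g in groups:
        if g.n < min_n:
            raise TooFewObservationsError(f"group {g.label!r} has n < {min_n}")


def one_way_anova_tukey(
    groups: list[GroupData], alpha: float = ALPHA
) -> tuple[TestResult, PosthocMatrix | None]:
    """One-way ANOVA; Tukey-Kramer pairwise matrix only if significant.

    Tukey-Kramer (statsmodels' pairwise_tukeyhsd) handles unequal group
    sizes. When the omnibus F is not significant the post hoc is skipped
    and None is returned.
    """
    _check_groups(groups, min_n=2)
    arrays = [g.values for g in groups]
    labels = tuple(g.label for g in groups)
    if np.ptp(np.concatenate(arrays)) == 0:
        omni = TestResult(test="anova", statistic=0.0, p_value=1.0,
                          groups=labels, degenerate=True)
        return omni, None
    F, p = sps.f_oneway(*arrays)
    if np.isnan(F):  # zero within-group variance everywhere
        F, p = 0.0, 1.0
    omni = TestResult(test="anova", statistic=float(F), p_value=float(p),
                      groups=labels)
    if omni.p_value >= alpha:
        return omni, None
    values = np.concatenate(arrays)
    tags = np.concatenate([[g.label] * g.n for g in groups])
    res = pairwise_tukeyhsd(values, tags, alpha=alpha)
    uniq = list(res.groupsunique)
    k = len(labels)
    P = np.ones((k, k))
    for (ia, ib), pv in zip(
        itertools.combinations(range(len(uniq)), 2), res.pvalues
    ):
        i, j = labels.index(uniq[ia]), labels.index(uniq[ib])
        P[i, j] = P[j, i] = float(pv)
    return omni, PosthocMatrix(labels=labels, p_values=P, method="tukey-kramer")


def _dunn_matrix(groups: list[GroupData]) -> np.ndarray:
    """Dunn's rank-based pairwise z-tests, Bonferroni-adjusted."""
    values = np.concatenate([g.values for g in groups])
    ranks = sps.rankdata(values)
    N = values.size
    # tie correction to the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.n].mean())
        start += g.n
    k = len(groups)
    m = k * (k - 1) // 2
    P = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / groups[i].n + 1.0 / groups[j].n))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(z) * m)
        P[i, j] = P[j, i] = p
    return P


def kruskal_dunn(
    groups: list[GroupData], alpha: float = ALPHA
) -> tuple[TestResult, PosthocMatrix | None]:
    """Kruskal-Wallis (tie-corrected H); Dunn post hoc when significant."""
    _check_groups(groups, min_n=1)
    arrays = [g.values for g in groups]
    labels = tuple(g.label for g in groups)
    if np.ptp(np.concatenate(arrays)) == 0:
        omni = TestResult(test="kruskal", statistic=0.0, p_value=1.0,
                          groups=labels, degenerate=True)
        return omni, None
    H, p = sps.kruskal(*arrays)
    omni = TestResult(test="kruskal", statistic=float(H), p_value=float(p),
                      groups=labels)
    if omni.p_value >= alpha:
        return omni, None
    P = _dunn_matrix(groups)
    return omni, PosthocMatrix(labels=labels, p_values=P, method="dunn")


def adaptive_multi_group(
    groups: list[GroupData], alpha: float = ALPHA
) -> tuple[TestResult, PosthocMatrix | None, CLDResult | None]:
    """Adaptive omnibus: ANOVA + Tukey + capital letters when all groups
    are normal with homogeneous variance (Brown-Forsythe across groups);
    otherwise Kruskal-Wallis + Dunn + lower-case letters."""
    _check_groups(groups, min_n=3)
    normal = all(
        float(sps.shapiro(g.values).pvalue) >= alpha for g in groups
    )
    equal = (
        float(sps.levene(*[g.values for g in groups], center="median").pvalue)
        >= alpha
        if normal
        else False
    )
    if normal and equal:
        omni, post = one_way_anova_tukey(groups, alpha=alpha)
        case = "upper"
    else:
        omni, post = kruskal_dunn(groups, alpha=alpha)
        case = "lower"
    cld = compact_letter_display(post, alpha=alpha, case=case) if post else None
    return omni, post, cld


# ---------------------------------------------------------------------------
# compact letter display
# ---------------------------------------------------------------------------


def compact_letter_display(
    matrix: PosthocMatrix, alpha: float = ALPHA, case: str = "upper"
) -> CLDResult:
    """Insert-and-absorb letter display.

    Start with one column containing all groups; for every significant
    pair, split each column containing both into two copies (one without
    each member), then absorb columns that are subsets of another. Groups
    share a letter iff their adjusted p >= alpha; letters are assigned in
    group order.
    """
    if case not in ("upper", "lower"):
        raise ValueError("case must be 'upper' or 'lower'")
    k = len(matrix.labels)
    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if matrix.p_values[i, j] >= alpha:
            continue
        new_cols: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {i})
                new_cols.append(col - {j})
            else:
                new_cols.append(col)
        # absorb: drop proper subsets of another column, and duplicates
        columns = []
        for c in new_cols:
            if any(c < d for d in new_cols) or c in columns:
                continue
            columns.append(c)
    columns = [c for c in columns if c]
    # canonical order: by smallest member index
    columns.sort(key=lambda c: min(c))
    alphabet = string.ascii_uppercase if case == "upper" else (
        string.ascii_lowercase
    )
    letters = {lab: "" for lab in matrix.labels}
    for letter, col in zip(alphabet, columns):
        for g in sorted(col):
            letters[matrix.labels[g]] += letter
    return CLDResult(letters=letters, case=case)
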