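"""Pairwise group comparison battery.

Size is compared with the two-sided Wilcoxon rank-sum test and its spread
with the Fligner–Killeen test; shape and form with one-way MANOVA (Wilks'
lambda, Rao's F approximation) on retained PC scores; allometry with a
MANCOVA test of the group x log-size interaction (homogeneity of allometric
slopes); and shape disparity with a permutation test on the absolute
difference of per-group Procrustes variances.  Raw p-values from a battery
are corrected for multiple comparisons (Benjamini–Hochberg by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    test_name: str
    statistic_label: str  # one of W, F, x2, d_var
    statistic_value: float
    p_value: float
    dfs: tuple[float, float] | None = None
    n_per_group: dict[str, int] = field(default_factory=dict)
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic_label": self.statistic_label,
            "statistic_value": self.statistic_value,
            "p_value": self.p_value,
            "dfs": list(self.dfs) if self.dfs is not None else None,
            "n_per_group": self.n_per_group,
            "p_adjusted": self.p_adjusted,
        }
        d.update({k: v for k, v in self.extra.items()})
        return d


# ---------------------------------------------------------------------------
# Size
# ---------------------------------------------------------------------------

def wilcoxon_size_test(sizes_a: Sequence[float], sizes_b: Sequence[float],
                       labels: tuple[str, str] = ("a", "b")) -> TestResult:
    """Two-sided Wilcoxon/Mann–Whitney rank-sum test on (log) centroid sizes.

    The reported statistic W is the Mann–Whitney U of the first group.  The
    p-value is exact by enumeration when n_a + n_b <= 12 and there are no
    ties, otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    a = np.asarray(sizes_a, float)
    b = np.asarray(sizes_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size <= 12) and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        test_name="wilcoxon_size",
        statistic_label="W",
        statistic_value=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group={labels[0]: a.size, labels[1]: b.size},
        extra={"method": "exact" if exact else "normal_approx",
               "statistic_definition": "Mann-Whitney U of first group"},
    )


def fligner_killeen_test(groups: dict[str, Sequence[float]]) -> TestResult:
    """Fligner–Killeen test of equal spread across groups (chi-squared p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for name, vals in groups.items():
        v = np.asarray(vals, float)
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        samples.append(v)
    stat, p = sps.fligner(*samples)
    return TestResult(
        test_name="fligner_killeen_size_variance",
        statistic_label="x2",
        statistic_value=float(stat),
        p_value=float(p),
        dfs=(float(len(groups) - 1), float("inf")),
        n_per_group={name: len(v) for name, v in zip(groups, samples)},
    )


# ---------------------------------------------------------------------------
# Wilks' lambda machinery
# ---------------------------------------------------------------------------

def _rao_f(lam: float, p: int, vh: int, ve: int) -> tuple[float, float, float]:
    """Rao's F approximation to the Wilks' lambda null distribution.

    Returns (F, df1, df2) for lambda with p response variables, hypothesis
    degrees of freedom vh and error degrees of freedom ve.
    """
    if p * p + vh * vh - 5 > 0:
        t = np.sqrt((p * p * vh * vh - 4.0) / (p * p + vh * vh - 5.0))
    else:
        t = 1.0
    df1 = p * vh
    w = ve + vh - (p + vh + 1) / 2.0
    df2 = w * t - (p * vh - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    if lam_t <= 0:
        return np.inf, df1, df2
    f = (1.0 - lam_t) / lam_t * df2 / df1
    return float(f), float(df1), float(df2)


def _sscp_residual(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual SSCP of the multivariate least-squares fit of y on x."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return resid.T @ resid


def _group_dummies(groups: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    labels = sorted(set(groups))
    g = np.zeros((len(groups), len(labels)))
    for i, lab in enumerate(groups):
        g[i, labels.index(lab)] = 1.0
    return g, labels


def manova_test(scores: np.ndarray, groups: Sequence[str]) -> TestResult:
    """One-way MANOVA on retained PC scores: Wilks' lambda with Rao's F."""
    y = np.atleast_2d(np.asarray(scores, float))
    if y.ndim != 2:
        raise ValueError("scores must be 2-D (specimens x components)")
    n, p = y.shape
    dummies, labels = _group_dummies(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if n <= p + g:
        raise ValueError(f"too few specimens (n={n}) for p={p} variables and {g} groups")
    grand = y.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    counts = {}
    for j, lab in enumerate(labels):
        sub = y[dummies[:, j] == 1.0]
        counts[lab] = len(sub)
        mu = sub.mean(axis=0)
        centered = sub - mu
        w += centered.T @ centered
        b += len(sub) * np.outer(mu - grand, mu - grand)
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError(
            "singular pooled within-group covariance; reduce the number of "
            "retained components"
        )
    lam = float(np.exp(logdet_w - logdet_t))
    lam = min(lam, 1.0)
    f, df1, df2 = _rao_f(lam, p, g - 1, n - g)
    p_val = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    if lam >= 1.0:
        f, p_val = 0.0, 1.0
    return TestResult(
        test_name="manova",
        statistic_label="F",
        statistic_value=f,
        p_value=p_val,
        dfs=(df1, df2),
        n_per_group=counts,
        extra={"wilks_lambda": lam},
    )


def mancova_allometry_test(
    scores: np.ndarray, log_sizes: Sequence[float], groups: Sequence[str]
) -> TestResult:
    """Homogeneity of allometric slopes.

    Fits the multivariate linear model scores ~ group + log_size +
    group:log_size and tests the interaction block with Wilks' lambda: equal
    slopes across groups means shape change with size is shared, and group
    differences are not allometric repatterning.
    """
    y = np.atleast_2d(np.asarray(scores, float))
    n, p = y.shape
    ls = np.asarray(log_sizes, float)
    if not np.all(np.isfinite(ls)):
        raise ValueError("non-finite log sizes")
    if np.ptp(ls) <= 0:
        raise ValueError("log size is constant; allometry is not testable")
    dummies, labels = _group_dummies(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    ve = n - 2 * g
    if ve <= p:
        raise ValueError(
            f"too few error dfs (n - 2g = {ve}) for p={p} response variables"
        )
    x_full = np.hstack([dummies, dummies * ls[:, None]])
    x_reduced = np.hstack([dummies, ls[:, None]])
    e_full = _sscp_residual(x_full, y)
    e_reduced = _sscp_residual(x_reduced, y)
    h = e_reduced - e_full
    sign_e, logdet_e = np.linalg.slogdet(e_full)
    sign_t, logdet_t = np.linalg.slogdet(e_full + h)
    if sign_e <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular residual SSCP in allometry model")
    lam = float(np.exp(logdet_e - logdet_t))
    lam = min(lam, 1.0)
    vh = g - 1
    f, df1, df2 = _rao_f(lam, p, vh, ve)
    p_val = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    if lam >= 1.0:
        f, p_val = 0.0, 1.0
    counts: dict[str, int] = {}
    for j, lab in enumerate(labels):
        counts[lab] = int(dummies[:, j].sum())
    return TestResult(
        test_name="mancova_allometry",
        statistic_label="F",
        statistic_value=f,
        p_value=p_val,
        dfs=(df1, df2),
        n_per_group=counts,
        extra={"wilks_lambda": lam, "hypothesis": "group x log-size interaction"},
    )


# ---------------------------------------------------------------------------
# Procrustes variance
# ---------------------------------------------------------------------------

def procrustes_variances(flat: np.ndarray, groups: Sequence[str]) -> dict[str, float]:
    """Per-group Procrustes variance: sum of squared distances of each shape
    from its group mean shape, divided by (n_g - 1), in the common aligned
    frame."""
    x = np.asarray(flat, float)
    out = {}
    arr = np.asarray(groups)
    for lab in sorted(set(groups)):
        sub = x[arr == lab]
        if len(sub) < 2:
            raise ValueError(f"group {lab!r} needs at least 2 specimens")
        mu = sub.mean(axis=0)
        out[lab] = float(np.sum((sub - mu) ** 2) / (len(sub) - 1))
    return out


def procrustes_variance_test(
    flat: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> TestResult:
    """Permutation test of equal shape disparity between two groups.

    The statistic is d_var = |var_a - var_b|; group labels are permuted and
    the p-value is the proportion of permutations (the observed labelling
    included) with d_var at least as large as observed.
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse")
    x = np.asarray(flat, float)
    arr = np.asarray(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("procrustes_variance_test compares exactly 2 groups")
    obs = procrustes_variances(x, groups)
    d_obs = abs(obs[labels[0]] - obs[labels[1]])

    n = len(x)
    n_a = int(np.sum(arr == labels[0]))
    sq = np.sum(x**2, axis=1)
    rng = np.random.default_rng(seed)
    # vectorized label permutations: each row of `order` is a permutation,
    # the first n_a entries forming group a
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    idx_a = order[:, :n_a]
    idx_b = order[:, n_a:]

    def group_var(idx: np.ndarray) -> np.ndarray:
        n_g = idx.shape[1]
        sums = x[idx].sum(axis=1)  # (n_perm, d)
        ss = sq[idx].sum(axis=1) - np.sum(sums**2, axis=1) / n_g
        return ss / (n_g - 1)

    d_perm = np.abs(group_var(idx_a) - group_var(idx_b))
    count = int(np.sum(d_perm >= d_obs - 1e-12))
    p = (count + 1) / (n_perm + 1)
    direction = (
        f"{labels[0]} > {labels[1]}" if obs[labels[0]] > obs[labels[1]]
        else f"{labels[1]} > {labels[0]}"
    )
    return TestResult(
        test_name="procrustes_variance",
        statistic_label="d_var",
        statistic_value=float(d_obs),
        p_value=float(p),
        n_per_group={labels[0]: n_a, labels[1]: n - n_a},
        extra={"variances": obs, "direction": direction,
               "n_perm": n_perm, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

_METHOD_MAP = {
    "benjamini-hochberg": "fdr_bh",
    "holm": "holm",
    "bonferroni": "bonferroni",
}


def adjust_pvalues(
    p_values: Sequence[float], method: str = "benjamini-hochberg"
) -> np.ndarray:
    """Multiple-comparison adjustment (step-up BH by default; monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _METHOD_MAP:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHOD_MAP)}")
    if p.size == 0:
        return p
    _, adjusted, *_ = multipletests(p, method=_METHOD_MAP[method])
    return np.minimum(np.maximum(adjusted, p), 1.0)
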