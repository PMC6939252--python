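"""Haplotype-frequency differentiation between dog populations.

Mitochondrial subclade assignments (A1a, A1b, A2a, A2b, X, ...) per specimen
are tallied into group x haplotype count tables; differentiation between
groups or periods is quantified with F_ST in its G_ST form,
(H_T - H_S) / H_T, where H_S is the sample-size-weighted mean within-group
gene diversity and H_T the gene diversity of the pooled frequencies.
Significance comes from permuting specimen group labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HaplotypeCounts:
    """Group x haplotype contingency table of nonnegative integer counts."""

    groups: list[str]
    haplotypes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.groups), len(self.haplotypes)):
            raise ValueError("counts shape does not match labels")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        self.counts = c.astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.groups, columns=self.haplotypes)

    def subset(self, groups: list[str]) -> "HaplotypeCounts":
        idx = [self.groups.index(g) for g in groups]
        return HaplotypeCounts(groups, list(self.haplotypes), self.counts[idx])


@dataclass
class FstResult:
    estimate: float
    p_value: float
    n_perm: int
    seed: int
    estimator: str = "G_ST (haplotype frequencies)"

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "estimator": self.estimator,
        }


def build_counts(assignments: pd.DataFrame,
                 haplotypes: list[str] | None = None) -> HaplotypeCounts:
    """Tally a per-specimen (group, haplotype) table into counts.

    ``haplotypes`` may list extra lineages to include as zero columns.
    """
    df = assignments
    for col in ("group", "haplotype"):
        if col not in df.columns:
            raise ValueError(f"assignments table needs a {col!r} column")
        missing = df[col].isna()
        if missing.any():
            rows = df.index[missing].tolist()
            raise ValueError(f"missing {col} labels in rows {rows}")
    table = pd.crosstab(df["group"], df["haplotype"])
    haps = sorted(set(table.columns) | set(haplotypes or []))
    table = table.reindex(columns=haps, fill_value=0)
    return HaplotypeCounts(
        groups=[str(g) for g in table.index],
        haplotypes=[str(h) for h in table.columns],
        counts=table.to_numpy(np.int64),
    )


def gene_diversity(counts_row: np.ndarray, unbiased: bool = True) -> float:
    """Gene (haplotype) diversity of one group: 1 - sum(p^2), with the
    small-sample correction n/(n-1) when ``unbiased``."""
    c = np.asarray(counts_row, float)
    n = c.sum()
    if n < 1:
        raise ValueError("empty count row")
    h = 1.0 - np.sum((c / n) ** 2)
    if unbiased:
        if n < 2:
            raise ValueError("unbiased gene diversity needs n >= 2")
        h *= n / (n - 1.0)
    return float(h)


def fst(counts: HaplotypeCounts | np.ndarray, unbiased: bool = True) -> float:
    """F_ST in G_ST form: (H_T - H_S) / H_T.

    H_S is the sample-size-weighted mean of within-group diversities and H_T
    the diversity of the pooled haplotype frequencies.  Returns 0 when the
    pooled sample is monomorphic (H_T = 0).
    """
    c = counts.counts if isinstance(counts, HaplotypeCounts) else np.asarray(counts)
    c = np.asarray(c, float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("F_ST needs counts for at least 2 groups")
    row_n = c.sum(axis=1)
    if np.any(row_n <= 0):
        raise ValueError("every group needs a positive total count")
    h_within = np.array([gene_diversity(row, unbiased=unbiased) for row in c])
    h_s = float(np.sum(row_n * h_within) / row_n.sum())
    pooled = c.sum(axis=0)
    h_t = gene_diversity(pooled, unbiased=unbiased)
    if h_t <= 0:
        return 0.0
    return float((h_t - h_s) / h_t)


def fst_permutation_test(
    assignments: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    unbiased: bool = False,
) -> FstResult:
    """Label-permutation significance test for F_ST.

    Specimen group labels are shuffled; p = (1 + #{permuted F_ST >= observed})
    / (n_perm + 1).  The plug-in (biased) diversity is the default here so the
    statistic is a pure frequency contrast.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse")
    counts = build_counts(assignments)
    observed = fst(counts, unbiased=unbiased)

    group_labels = assignments["group"].to_numpy()
    hap_labels = assignments["haplotype"].to_numpy()
    groups = sorted(set(group_labels.tolist()))
    haps = sorted(set(hap_labels.tolist()))
    g_idx = np.array([groups.index(g) for g in group_labels])
    h_idx = np.array([haps.index(h) for h in hap_labels])
    n = len(assignments)
    n_g, n_h = len(groups), len(haps)
    one_hot = np.zeros((n, n_h))
    one_hot[np.arange(n), h_idx] = 1.0
    row_n = np.bincount(g_idx, minlength=n_g).astype(float)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        g_perm = g_idx[perm]
        c = np.zeros((n_g, n_h))
        np.add.at(c, g_perm, one_hot)
        h_w = 1.0 - np.sum((c / row_n[:, None]) ** 2, axis=1)
        if unbiased:
            h_w *= row_n / (row_n - 1.0)
        h_s = np.sum(row_n * h_w) / row_n.sum()
        pooled = c.sum(axis=0)
        h_t = 1.0 - np.sum((pooled / pooled.sum()) ** 2)
        if unbiased:
            tot = pooled.sum()
            h_t *= tot / (tot - 1.0)
        f = 0.0 if h_t <= 0 else (h_t - h_s) / h_t
        if f >= observed - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (n_perm + 1)
    return FstResult(
        estimate=float(observed), p_value=float(p), n_perm=n_perm, seed=seed,
        estimator=("G_ST (haplotype frequencies, unbiased)" if unbiased
                   else "G_ST (haplotype frequencies, plug-in)"),
    )


def subclade_frequency_table(
    assignments: pd.DataFrame, grouping: str = "group"
) -> pd.DataFrame:
    """Per-group percentage of each subclade; rows sum to 100%.

    ``grouping`` names the column to aggregate by (e.g. a period or region
    column); empty groups are dropped with a warning.
    """
    if grouping not in assignments.columns:
        raise ValueError(f"no column {grouping!r} in assignments")
    table = pd.crosstab(assignments[grouping], assignments["haplotype"])
    totals = table.sum(axis=1)
    empty = totals.index[totals == 0]
    if len(empty):
        warnings.warn(f"omitting empty groups: {list(empty)}")
        table = table.loc[totals > 0]
        totals = totals[totals > 0]
    return table.div(totals, axis=0) * 100.0
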