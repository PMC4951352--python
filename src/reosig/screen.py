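"""Differential expression and gene-pair reversal screening.

Screening works on within-sample relative expression orderings (REOs): for a
gene pair (a, b) and one sample, the REO is whether Ea > Eb.  A pair is
"reversed" between two sample groups when the fraction of samples showing
Ea > Eb differs significantly (two-sided Fisher exact test on the 2x2 table
of orderings by group, Benjamini-Hochberg FDR over all tested pairs).

Because only orderings enter, every statistic here is invariant under any
strictly increasing per-sample transform of the expression values — the
property that makes REO signatures robust to batch effects and normalization.

Pairs are canonicalized as unordered pairs with gene ids sorted
lexicographically; frequencies and directions always refer to the canonical
first gene being the larger one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "de_genes",
    "reo_frequency",
    "reversed_pairs",
    "consistent_overlap",
    "OverlapResult",
]


def _check_groups(expr: pd.DataFrame, group1: Sequence[str], group2: Sequence[str]) -> None:
    overlap = set(group1) & set(group2)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    missing = (set(group1) | set(group2)) - set(expr.columns)
    if missing:
        raise ValueError(f"unknown sample ids: {sorted(missing)[:5]}")


def de_genes(
    expr: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    fdr_threshold: float = 0.1,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-group differential expression by t-test with BH-FDR control.

    The default is the pooled-variance (Student) t-test; set
    ``equal_var=False`` for Welch.  BH adjustment runs over all tested genes;
    only genes with fdr below the threshold are returned.  Genes constant
    within both groups get p = 1 (no evidence) unless their group means still
    differ, in which case p = 0 by convention.

    Returns a DataFrame indexed by gene_id with columns t, p, fdr and
    direction ("up" when the group-1 mean exceeds the group-2 mean).
    """
    _check_groups(expr, group1, group2)
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 samples")
    x1 = expr[list(group1)].to_numpy(dtype=float)
    x2 = expr[list(group2)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x1, x2, axis=1, equal_var=equal_var)
    mean_diff = x1.mean(axis=1) - x2.mean(axis=1)
    zero_var = (x1.var(axis=1) == 0) & (x2.var(axis=1) == 0)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var & (mean_diff == 0), 1.0, p)
    p = np.where(zero_var & (mean_diff != 0), 0.0, p)
    p = np.nan_to_num(p, nan=1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    result = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "fdr": fdr,
            "direction": np.where(mean_diff > 0, "up", "down"),
        },
        index=expr.index,
    )
    significant = result[result["fdr"] < fdr_threshold].sort_values("p")
    log.info("de_genes: %d / %d genes at FDR < %g", len(significant), len(result), fdr_threshold)
    return significant


def reo_frequency(
    expr: pd.DataFrame, pair: tuple[str, str], samples: Sequence[str]
) -> float:
    """Fraction of the listed samples with strictly Ea > Eb.

    Ties (Ea == Eb) count as "not greater" — a deterministic, conservative
    convention; ties have measure zero for continuous intensities but do
    occur in small fixtures.
    """
    gene_a, gene_b = pair
    for g in (gene_a, gene_b):
        if g not in expr.index:
            raise KeyError(f"unknown gene id: {g!r}")
    missing = set(samples) - set(expr.columns)
    if missing:
        raise KeyError(f"unknown sample ids: {sorted(missing)[:5]}")
    samples = list(samples)
    a = expr.loc[gene_a, samples].to_numpy(dtype=float)
    b = expr.loc[gene_b, samples].to_numpy(dtype=float)
    return float((a > b).mean())


class _FisherCache:
    """Two-sided Fisher exact p for tables [[x1, n1-x1], [x2, n2-x2]].

    Group sizes are fixed across one screening run, so p-values are cached on
    the pair of success counts; the cache typically collapses tens of
    thousands of pair tests to a few thousand distinct tables.
    """

    def __init__(self, n1: int, n2: int):
        self.n1, self.n2 = n1, n2
        self._cache: dict[tuple[int, int], float] = {}

    def p(self, x1: int, x2: int) -> float:
        key = (x1, x2)
        if key not in self._cache:
            table = [[x1, self.n1 - x1], [x2, self.n2 - x2]]
            self._cache[key] = float(stats.fisher_exact(table, alternative="two-sided")[1])
        return self._cache[key]


def reversed_pairs(
    expr: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    candidate_genes: Iterable[str],
    fdr_threshold: float = 0.2,
) -> pd.DataFrame:
    """Screen for gene pairs whose REO frequency differs between two groups.

    The pair universe is every unordered pair with at least one member in
    ``candidate_genes`` (both members measured).  For each pair the 2x2 table
    of (Ea > Eb vs not) by group is tested with the two-sided Fisher exact
    test; BH adjustment runs over all tested pairs and pairs with fdr below
    the threshold are returned.

    Returns a DataFrame with canonical gene_a < gene_b, freq1, freq2 (the
    Ea > Eb fraction per group), fisher_p, fdr and direction
    (sign of freq1 - freq2).  ``.attrs["n_tested"]`` records the universe
    size used as the BH family.
    """
    _check_groups(expr, group1, group2)
    genes = expr.index.to_list()
    gene_pos = {g: i for i, g in enumerate(genes)}
    cand = [g for g in genes if g in set(candidate_genes)]
    if not cand:
        raise ValueError("no candidate gene is present in the expression matrix")
    v1 = expr[list(group1)].to_numpy(dtype=float)
    v2 = expr[list(group2)].to_numpy(dtype=float)
    n1, n2 = v1.shape[1], v2.shape[1]
    cand_set = set(cand)

    rows_a, rows_b, cnt1, cnt2 = [], [], [], []
    for a in cand:
        ia = gene_pos[a]
        # strictly-greater counts of gene a over every other gene, per group
        gt1 = (v1[ia][None, :] > v1).sum(axis=1)
        gt2 = (v2[ia][None, :] > v2).sum(axis=1)
        lt1 = (v1[ia][None, :] < v1).sum(axis=1)
        lt2 = (v2[ia][None, :] < v2).sum(axis=1)
        for b in genes:
            if b == a or (b in cand_set and b < a):
                continue  # each unordered pair tested once
            ib = gene_pos[b]
            if a < b:
                first, x1, x2 = a, int(gt1[ib]), int(gt2[ib])
                second = b
            else:
                # canonical first gene is b; count Eb > Ea = n - (Ea >= Eb)
                first, second = b, a
                x1, x2 = int(lt1[ib]), int(lt2[ib])
            rows_a.append(first)
            rows_b.append(second)
            cnt1.append(x1)
            cnt2.append(x2)

    fisher = _FisherCache(n1, n2)
    pvals = np.array([fisher.p(x1, x2) for x1, x2 in zip(cnt1, cnt2)])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    freq1 = np.array(cnt1) / n1
    freq2 = np.array(cnt2) / n2
    result = pd.DataFrame(
        {
            "gene_a": rows_a,
            "gene_b": rows_b,
            "freq1": freq1,
            "freq2": freq2,
            "fisher_p": pvals,
            "fdr": fdr,
            "direction": np.sign(freq1 - freq2).astype(int),
        }
    )
    retained = result[result["fdr"] < fdr_threshold].sort_values("fisher_p")
    retained = retained.reset_index(drop=True)
    retained.attrs["n_tested"] = len(result)
    log.info(
        "reversed_pairs: %d / %d pairs at FDR < %g", len(retained), len(result), fdr_threshold
    )
    return retained


@dataclass
class OverlapResult:
    """Cross-dataset consistency of two reversed-pair lists."""

    survivors: pd.DataFrame  # same-direction overlapped pairs (fields from list A)
    k: int  # overlapped pairs
    s: int  # overlapped pairs with the same reversal direction
    score: float | None  # s / k, None when k == 0


def consistent_overlap(list_a: pd.DataFrame, list_b: pd.DataFrame) -> OverlapResult:
    """Intersect two reversed-pair lists and keep direction-consistent pairs.

    Pairs are matched as unordered gene-id pairs (both inputs are already
    canonical).  The surviving set — the pairs carried forward as reproducible
    reversals — is the same-direction subset, reported with list A's
    statistics plus list B's frequency columns.
    """
    key_cols = ["gene_a", "gene_b"]
    merged = list_a.merge(list_b, on=key_cols, suffixes=("", "_b"))
    k = len(merged)
    same = merged[merged["direction"] == merged["direction_b"]]
    s = len(same)
    survivors = same[
        key_cols + ["freq1", "freq2", "fisher_p", "fdr", "direction", "freq1_b", "freq2_b"]
    ].reset_index(drop=True)
    score = s / k if k else None
    if k:
        log.info("consistent_overlap: %d overlaps, %d (%.2f%%) same direction", k, s, 100 * s / k)
    else:
        log.info("consistent_overlap: no overlapping pairs")
    return OverlapResult(survivors=survivors, k=k, s=s, score=score)
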