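"""Closed-form consistency statistics: binomial concordance, hypergeometric
overlap and gene-set enrichment.

Two directed gene lists (gene → up/down) drawn from independent datasets are
compared by their concordance score s/k: of the k genes present in both
lists, s agree in direction.  Under the null each overlapping gene agrees
with probability Pe (0.5 unless stated otherwise), so the chance of observing
at least s agreements is the upper-tail cumulative binomial

    P = 1 - sum_{i=0}^{s-1} C(k, i) Pe^i (1 - Pe)^(k-i).

Set overlap and category enrichment use the upper-tail hypergeometric: with
N annotated measured genes, n of them differentially expressed, and a
category of M measured genes containing m DE genes,

    P = 1 - sum_{i=0}^{m-1} C(n, i) C(N-n, M-i) / C(N, M).

Tail sums are accumulated in log space so scores over lists with thousands of
members do not underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ConcordanceResult",
    "concordance_pvalue",
    "concordance_score",
    "overlap_test",
    "read_gmt",
    "enrich_categories",
    "integrate_de_lists",
]

_DIRECTION = {"up": 1, "down": -1, 1: 1, -1: -1, "+": 1, "-": -1}


@dataclass
class ConcordanceResult:
    """Agreement of two directed gene (or pair) lists.

    score and p_value are None when the lists do not overlap (k = 0).
    log10_p carries the tail probability even when it underflows a float.
    """

    k: int
    s: int
    score: float | None
    pe: float
    p_value: float | None
    log10_p: float | None

    @property
    def score_pct(self) -> float | None:
        """The concordance score as a percentage, rounded to 2 decimals."""
        return None if self.score is None else round(100.0 * self.score, 2)


def concordance_pvalue(k: int, s: int, pe: float = 0.5) -> tuple[float, float]:
    """Upper-tail binomial probability of >= s agreements among k trials.

    Returns ``(p, log10_p)``; the sum runs in log space, so ``log10_p``
    remains meaningful for k in the thousands where ``p`` underflows to 0.
    """
    if not 0 <= s <= k:
        raise ValueError("need 0 <= s <= k")
    if not 0.0 < pe < 1.0:
        raise ValueError("pe must be in (0, 1)")
    if k == 0:
        raise ValueError("k must be positive")
    i = np.arange(s, k + 1)
    log_p = float(logsumexp(stats.binom.logpmf(i, k, pe)))
    log_p = min(log_p, 0.0)  # guard rounding above 1
    return float(np.exp(log_p)), log_p / np.log(10.0)


def _normalize(directed: Mapping[str, object]) -> dict[str, int]:
    out = {}
    for gene, direction in directed.items():
        if direction not in _DIRECTION:
            raise ValueError(f"unrecognised direction {direction!r} for gene {gene!r}")
        out[gene] = _DIRECTION[direction]
    return out


def concordance_score(
    list_a: Mapping[str, object],
    list_b: Mapping[str, object],
    pe: float = 0.5,
) -> ConcordanceResult:
    """Concordance score s/k of two directed lists with its binomial p-value.

    Inputs map gene (or canonical pair) ids to a direction: "up"/"down",
    +1/-1 or "+"/"-".  With no overlap the score and p-value are reported as
    not applicable (None).
    """
    a = _normalize(list_a)
    b = _normalize(list_b)
    shared = sorted(set(a) & set(b))
    k = len(shared)
    if k == 0:
        return ConcordanceResult(k=0, s=0, score=None, pe=pe, p_value=None, log10_p=None)
    s = sum(a[g] == b[g] for g in shared)
    p, log10_p = concordance_pvalue(k, s, pe)
    return ConcordanceResult(k=k, s=s, score=s / k, pe=pe, p_value=p, log10_p=log10_p)


def overlap_test(set_a: Iterable[str], set_b: Iterable[str], universe_size: int) -> float:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    Probability of drawing at least ``|A ∩ B|`` members of A when ``|B|``
    genes are sampled without replacement from a universe of
    ``universe_size``.
    """
    a, b = set(set_a), set(set_b)
    if max(len(a), len(b)) > universe_size:
        raise ValueError("universe smaller than one of the sets")
    m = len(a & b)
    return float(stats.hypergeom.sf(m - 1, universe_size, len(a), len(b)))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into a dict of set name → member genes."""
    from gseapy.parser import read_gmt as _gseapy_read_gmt

    sets = _gseapy_read_gmt(str(path))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return {name: set(genes) for name, genes in sets.items()}


def enrich_categories(
    de_genes: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    measured_genes: Iterable[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric category enrichment of a DE gene list with BH-FDR.

    Every category is first intersected with the measured genes; the
    annotated universe N is the union of the intersected categories, n the
    annotated DE genes, and per category M (annotated members) and m (DE
    members) give the upper-tail p.  BH adjustment runs across all tested
    categories.

    Returns a DataFrame sorted by p with columns N, n, M, m, p, adjusted_p
    and significant (adjusted_p < fdr_threshold).
    """
    measured = set(measured_genes)
    de = set(de_genes) & measured
    trimmed = {name: set(genes) & measured for name, genes in categories.items()}
    trimmed = {name: genes for name, genes in trimmed.items() if genes}
    if not trimmed:
        raise ValueError("no category overlaps the measured genes")
    annotated = set().union(*trimmed.values())
    n_universe = len(annotated)
    n_de = len(de & annotated)
    rows = []
    for name, genes in sorted(trimmed.items()):
        m_cat = len(genes)
        m_hit = len(genes & de)
        p = float(stats.hypergeom.sf(m_hit - 1, n_universe, n_de, m_cat))
        rows.append((name, n_universe, n_de, m_cat, m_hit, p))
    result = pd.DataFrame(rows, columns=["category_id", "N", "n", "M", "m", "p"])
    result["adjusted_p"] = multipletests(result["p"], method="fdr_bh")[1]
    result["significant"] = result["adjusted_p"] < fdr_threshold
    result = result.sort_values(["p", "category_id"]).reset_index(drop=True)
    log.info(
        "enrich_categories: %d / %d categories at FDR < %g",
        int(result["significant"].sum()),
        len(result),
        fdr_threshold,
    )
    return result


def integrate_de_lists(
    lists: Sequence[Mapping[str, object]],
    min_lists: int = 2,
) -> dict[str, int]:
    """Consensus of several directed DE lists.

    A gene is kept when it appears in at least ``min_lists`` of the input
    lists and no two lists disagree on its direction; the consensus maps the
    gene to its shared direction (+1 up, -1 down).
    """
    normalized = [_normalize(lst) for lst in lists]
    counts: dict[str, list[int]] = {}
    for lst in normalized:
        for gene, direction in lst.items():
            counts.setdefault(gene, []).append(direction)
    consensus = {
        gene: dirs[0]
        for gene, dirs in counts.items()
        if len(dirs) >= min_lists and len(set(dirs)) == 1
    }
    log.info("integrate_de_lists: %d consensus genes from %d lists", len(consensus), len(lists))
    return consensus
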