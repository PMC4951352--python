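"""Oriented gene-pair signatures: Cox filtering, forward selection, voting.

A signature is an ordered set of oriented gene pairs plus a strict-majority
vote threshold.  Each pair has a ``high_risk_reo``: the within-sample ordering
("a<b" means Ea < Eb) that votes "high risk" for that sample.  A sample is
called high risk when at least ``vote_threshold`` pairs vote high — for a
three-pair signature, at least two.

Classification of one sample uses only that sample's own values, so the call
is identical whether the sample is classified alone or inside any cohort, and
is invariant to any strictly increasing per-sample transform.  The
percentile-vote classifier at the bottom of this module is the contrasting
baseline: its cutoffs are percentiles over the analyzed cohort, so the same
sample's label can change with the company it keeps.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import survival as surv

log = logging.getLogger(__name__)

__all__ = [
    "OrientedGenePair",
    "Signature",
    "prognostic_pairs",
    "forward_select",
    "classify_gps",
    "percentile_vote_classify",
    "load_signature",
    "save_signature",
    "load_3gps",
]

@dataclass(frozen=True)
class OrientedGenePair:
    """A gene pair with the ordering that votes high risk.

    ``high_risk_reo`` is "a<b" when Ea < Eb votes high risk, "a>b" otherwise.
    """

    gene_a: str
    gene_b: str
    high_risk_reo: str = "a<b"
    cox_p: float | None = None
    cox_hr: float | None = None

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"gene pair with identical members: {self.gene_a!r}")
        if self.high_risk_reo not in ("a<b", "a>b"):
            raise ValueError(f"high_risk_reo must be 'a<b' or 'a>b', got {self.high_risk_reo!r}")

    def key(self) -> tuple[str, str]:
        """Canonical unordered identity (sorted gene ids)."""
        return tuple(sorted((self.gene_a, self.gene_b)))

    def votes_high(self, ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
        """Per-sample high-risk votes given the two genes' values."""
        lt = np.asarray(ea) < np.asarray(eb)
        return lt if self.high_risk_reo == "a<b" else ~lt


@dataclass
class Signature:
    """An ordered set of oriented pairs with a strict-majority threshold."""

    pairs: list[OrientedGenePair]
    vote_threshold: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("a signature needs at least one pair")
        majority = len(self.pairs) // 2 + 1
        if self.vote_threshold is None:
            self.vote_threshold = majority
        elif self.vote_threshold != majority:
            raise ValueError(
                f"vote_threshold must be the strict majority {majority} "
                f"for {len(self.pairs)} pairs, got {self.vote_threshold}"
            )

    def genes(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            out += [p.gene_a, p.gene_b]
        return out


def classify_gps(
    expr: pd.DataFrame,
    signature: Signature,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Majority-vote risk classification of samples by a gene-pair signature.

    Returns a DataFrame indexed by sample_id with columns votes_high and
    label ("high"/"low").  Each sample's call depends only on its own values.
    """
    if samples is None:
        samples = list(expr.columns)
    else:
        samples = list(samples)
        missing = set(samples) - set(expr.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)[:5]}")
    for g in signature.genes():
        if g not in expr.index:
            raise KeyError(f"signature gene missing from expression matrix: {g!r}")
    votes = np.zeros(len(samples), dtype=int)
    for pair in signature.pairs:
        ea = expr.loc[pair.gene_a, samples].to_numpy(dtype=float)
        eb = expr.loc[pair.gene_b, samples].to_numpy(dtype=float)
        votes += pair.votes_high(ea, eb).astype(int)
    label = np.where(votes >= signature.vote_threshold, "high", "low")
    return pd.DataFrame({"votes_high": votes, "label": label}, index=pd.Index(samples, name="sample_id"))


def _pairs_iter(pairs) -> list[tuple[str, str]]:
    if isinstance(pairs, pd.DataFrame):
        return list(zip(pairs["gene_a"], pairs["gene_b"]))
    out = []
    for p in pairs:
        if isinstance(p, OrientedGenePair):
            out.append((p.gene_a, p.gene_b))
        else:
            a, b = p
            out.append((a, b))
    return out


def prognostic_pairs(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    pairs,
    p_threshold: float = 0.01,
    samples: Sequence[str] | None = None,
    min_group_frac: float = 0.1,
) -> list[OrientedGenePair]:
    """Filter pairs to those whose REO partition predicts survival.

    For each pair the cohort is split by the within-sample ordering
    (Ea > Eb vs not) and a univariate Cox model is fitted on the binary
    indicator (all pairs at once, via :func:`reosig.survival.cox_binary_batch`);
    pairs with Wald p below ``p_threshold`` are retained and oriented so that
    ``high_risk_reo`` is the ordering of the worse-survival group.  Under
    monotone likelihood (perfect separation of an immortal from an all-event
    group) the log-rank (score) test p-value is used instead, with a surfaced
    warning.

    Pairs whose partition is degenerate are skipped with a log entry.  A
    partition counts as degenerate when either ordering covers fewer than
    ``min_group_frac`` of the cohort (one sample against two hundred is not a
    usable classifier, and both the log-rank statistic and the Cox Wald test
    are unstable there); set ``min_group_frac=0`` to skip only empty groups.
    ``pairs`` may be a DataFrame with gene_a/gene_b columns (as produced by
    the reversal screen), an iterable of (gene_a, gene_b) tuples, or
    OrientedGenePair objects.
    """
    if samples is None:
        samples = list(clinical.index)
    missing = set(samples) - set(expr.columns)
    if missing:
        raise KeyError(f"samples not in expression matrix: {sorted(missing)[:5]}")
    times = clinical.loc[samples, "rfs_time"].to_numpy(dtype=float)
    events = clinical.loc[samples, "rfs_event"].to_numpy(dtype=int)

    pair_list = _pairs_iter(pairs)
    if not pair_list:
        return []
    values = expr[list(samples)]
    a_rows = values.loc[[a for a, _ in pair_list]].to_numpy(dtype=float)
    b_rows = values.loc[[b for _, b in pair_list]].to_numpy(dtype=float)
    indicators = a_rows > b_rows
    counts = indicators.sum(axis=1)
    n = indicators.shape[1]
    min_group = max(1, int(np.ceil(min_group_frac * n)))
    keep = (counts >= min_group) & (counts <= n - min_group)
    n_degenerate = int((~keep).sum())
    if n_degenerate:
        log.info("prognostic_pairs: skipped %d pairs with degenerate REO partitions", n_degenerate)
    kept_pairs = [p for p, k in zip(pair_list, keep) if k]
    if not kept_pairs:
        return []
    indicators = indicators[keep]
    fits = surv.cox_binary_batch(times, events, indicators)

    retained: list[OrientedGenePair] = []
    for i, ((gene_a, gene_b), (_, fit)) in enumerate(zip(kept_pairs, fits.iterrows())):
        if fit["separated"]:
            warnings.warn(
                f"pair ({gene_a}, {gene_b}): monotone Cox partial likelihood; "
                "using log-rank score test",
                stacklevel=2,
            )
            _, p = surv.logrank_test(times, events, indicators[i])
            hr = np.inf if fit["coef"] > 0 else 1e-12
        else:
            p, hr = float(fit["p"]), float(fit["hr"])
        if p < p_threshold:
            if hr > 1:  # Ea > Eb group fares worse
                reo, pair_hr = "a>b", hr
            else:
                reo, pair_hr = "a<b", 1.0 / hr if hr > 0 else np.inf
            retained.append(
                OrientedGenePair(gene_a, gene_b, high_risk_reo=reo, cox_p=p, cox_hr=pair_hr)
            )
    retained.sort(key=lambda q: (q.cox_p, -abs(np.log(q.cox_hr)), q.key()))
    log.info("prognostic_pairs: retained %d pairs at p < %g", len(retained), p_threshold)
    return retained


def _vote_matrix(
    expr: pd.DataFrame, pairs: Sequence[OrientedGenePair], samples: Sequence[str]
) -> np.ndarray:
    """(n_pairs, n_samples) boolean high-risk votes, one row per pair."""
    values = expr[list(samples)]
    ea = values.loc[[p.gene_a for p in pairs]].to_numpy(dtype=float)
    eb = values.loc[[p.gene_b for p in pairs]].to_numpy(dtype=float)
    lt = ea < eb
    flip = np.array([p.high_risk_reo == "a>b" for p in pairs])
    lt[flip] = ~lt[flip]
    return lt


def forward_select(
    candidates: Sequence[OrientedGenePair],
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    samples: Sequence[str] | None = None,
    min_group_frac: float = 0.1,
    strategy: str = "ranked",
) -> Signature:
    """Forward selection of a majority-vote signature.

    The seed is the candidate whose single-pair classification has the
    smallest log-rank p.  Then one prognosis-associated pair is added per
    iteration until the log-rank p of the majority-vote classification does
    not decrease, so the selected set's p is non-increasing across accepted
    iterations by construction.  Two addition rules are available:

    - ``"ranked"`` (default): candidates are tried one at a time in the
      order given (``prognostic_pairs`` returns them ranked by Cox p);
      selection stops at the first candidate whose addition fails to
      strictly decrease the p-value.
    - ``"greedy"``: every unused candidate is evaluated each iteration and
      the best-improving one is added; stops when no addition strictly
      decreases p.  With candidate lists in the hundreds this rule
      optimizes the in-sample log-rank p so aggressively that it absorbs
      noise pairs, which is why it is not the default.  Ties break on
      smaller p, then larger |log HR| from the Cox filter, then
      lexicographic pair id, so runs are deterministic.

    Under either rule, a classification that puts fewer than
    ``min_group_frac`` of the cohort on either side scores p = 1
    (degenerate): the log-rank statistic on a near-empty stratum is wildly
    unstable and rewards candidate sets that merely isolate the few earliest
    relapses, and a stratifier that flags almost nobody (or everybody) is
    not a usable risk classifier.
    """
    if strategy not in ("ranked", "greedy"):
        raise ValueError(f"unknown strategy {strategy!r}")
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate pairs")
    if samples is None:
        samples = list(clinical.index)
    times = clinical.loc[samples, "rfs_time"].to_numpy(dtype=float)
    events = clinical.loc[samples, "rfs_event"].to_numpy(dtype=int)
    votes = _vote_matrix(expr, candidates, samples)
    n = votes.shape[1]
    min_group = max(1, int(np.ceil(min_group_frac * n)))

    def logrank_p(vote_sum: np.ndarray, n_pairs: int) -> float:
        high = vote_sum >= (n_pairs // 2 + 1)
        n_high = int(high.sum())
        if n_high < min_group or n - n_high < min_group:
            return 1.0  # degenerate classification carries no survival signal
        _, p = surv.logrank_test(times, events, high)
        return p

    def tiebreak(i: int):
        pair = candidates[i]
        hr = pair.cox_hr if pair.cox_hr and np.isfinite(pair.cox_hr) and pair.cox_hr > 0 else 1.0
        return (-abs(np.log(hr)), pair.key())

    scored = sorted(
        (logrank_p(votes[i].astype(int), 1), *tiebreak(i), i) for i in range(len(candidates))
    )
    best_p = scored[0][0]
    if all(s[0] >= 1.0 for s in scored):
        raise ValueError("all candidate pairs give degenerate classifications")
    seed_idx = scored[0][-1]
    selected = [seed_idx]
    vote_sum = votes[seed_idx].astype(int)

    if strategy == "ranked":
        for i in range(len(candidates)):
            if i == seed_idx:
                continue
            p_try = logrank_p(vote_sum + votes[i], len(selected) + 1)
            if p_try < best_p:
                best_p = p_try
                selected.append(i)
                vote_sum = vote_sum + votes[i]
            else:
                break
    else:
        remaining = [s[-1] for s in scored[1:]]
        while remaining:
            trials = sorted(
                (logrank_p(vote_sum + votes[i], len(selected) + 1), *tiebreak(i), i)
                for i in remaining
            )
            if trials[0][0] < best_p:
                best_p = trials[0][0]
                chosen = trials[0][-1]
                selected.append(chosen)
                vote_sum = vote_sum + votes[chosen]
                remaining.remove(chosen)
            else:
                break
    log.info("forward_select[%s]: %d pairs, final log-rank p = %.3g", strategy, len(selected), best_p)
    return Signature(pairs=[candidates[i] for i in selected])


def percentile_vote_classify(
    expr: pd.DataFrame,
    gene_directions: Mapping[str, str],
    vote_min: int,
    hi_pct: float = 80.0,
    lo_pct: float = 20.0,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percentile-cutoff voting classifier (risk-score-style baseline).

    For each gene, ``gene_directions[gene]`` says which expression extreme
    indicates poor prognosis: "high" flags samples strictly above the
    ``hi_pct`` percentile, "low" flags samples strictly below the ``lo_pct``
    percentile — percentiles computed over the *provided* sample set only.
    A sample is labelled high risk when at least ``vote_min`` genes flag it.

    This classifier intentionally violates single-sample invariance: because
    the cutoffs move with the analyzed cohort, re-classifying a subset can
    relabel samples.  It exists to demonstrate that instability, in contrast
    to :func:`classify_gps`.
    """
    if not gene_directions:
        raise ValueError("need at least one gene")
    if vote_min > len(gene_directions):
        raise ValueError("vote_min exceeds the number of genes")
    if samples is None:
        samples = list(expr.columns)
    samples = list(samples)
    flags = np.zeros(len(samples), dtype=int)
    for gene, direction in gene_directions.items():
        if direction not in ("high", "low"):
            raise ValueError(f"direction for {gene!r} must be 'high' or 'low'")
        vals = expr.loc[gene, samples].to_numpy(dtype=float)
        if direction == "high":
            flags += (vals > np.percentile(vals, hi_pct)).astype(int)
        else:
            flags += (vals < np.percentile(vals, lo_pct)).astype(int)
    label = np.where(flags >= vote_min, "high", "low")
    return pd.DataFrame(
        {"votes_high": flags, "label": label}, index=pd.Index(samples, name="sample_id")
    )


# ---------------------------------------------------------------------------
# signature serialization and the published three-pair signature

def save_signature(signature: Signature, path: str | Path) -> None:
    doc = {
        "pairs": [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "high_risk_reo": p.high_risk_reo,
                "cox_p": p.cox_p,
                "cox_hr": p.cox_hr,
            }
            for p in signature.pairs
        ],
        "vote_threshold": signature.vote_threshold,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_signature(path: str | Path) -> Signature:
    with open(path) as fh:
        doc = json.load(fh)
    pairs = [
        OrientedGenePair(
            p["gene_a"],
            p["gene_b"],
            high_risk_reo=p["high_risk_reo"],
            cox_p=p.get("cox_p"),
            cox_hr=p.get("cox_hr"),
        )
        for p in doc["pairs"]
    ]
    return Signature(pairs=pairs, vote_threshold=doc.get("vote_threshold"))


def load_3gps() -> Signature:
    """The published three-pair relapse-risk signature for stage II CRC.

    Pairs ORC1-OLR1, MTNR1A-VGLL1 and RFX5-MMP14; for each, Ea < Eb votes
    high risk, and at least two high votes classify a sample as high risk.
    Shipped for the classify-only workflow on user data keyed by gene symbol.
    """
    ref = resources.files("reosig").joinpath("data/threegps.json")
    with resources.as_file(ref) as path:
        return load_signature(path)
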