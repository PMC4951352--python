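"""Synthetic cohorts with planted reversed gene pairs and censored survival.

The generator emulates the structure of a multi-stage colorectal-cancer
microarray cohort: stage I (non-metastatic) samples, stage II samples split
into no-chemotherapy and chemotherapy arms, and stage III/IV (metastatic)
samples.  A latent high/low relapse-risk label drives both

* the within-sample ordering of the planted gene pairs — a planted pair shows
  its high-risk orientation (gene *a* below gene *b*) with probability
  ``f_high`` in metastatic or latent-high-risk samples and ``f_low``
  otherwise, and
* the relapse hazard of stage II samples, exponential with rate
  ``baseline_hazard * hr_true**[latent == high]``, under independent
  exponential censoring.

Planting is done by swapping the two realized values within a sample whenever
the drawn orientation contradicts them.  Swapping controls the ordering
directly and leaves every sample's value multiset untouched, so the marginal
intensity distributions are not distorted the way mean shifts would distort
them.

Each planted pair's second gene, plus a configurable number of extra genes,
receives a fixed log2 mean shift in metastatic samples; these are the planted
differentially expressed genes, and they guarantee each planted pair contains
a metastasis-DE member so it enters the screening pair universe.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .signature import OrientedGenePair

__all__ = ["SyntheticConfig", "GroundTruth", "generate_cohort", "write_fixture", "read_fixture"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Cohort sizes default to the stage margins of a large public
    colorectal-cancer series (33 stage I / 203 stage II without CTX /
    56 stage II with CTX / 50 stage III-IV); the latent high-risk fraction
    among stage II defaults to 0.25, matching the reported 25-30% relapse
    rate of resected stage II disease.  Hazards are per month.
    """

    n_genes: int = 1000
    n_stage1: int = 33
    n_stage2_noctx: int = 203
    n_stage2_ctx: int = 56
    n_stage34: int = 50
    n_planted_pairs: int = 30
    n_planted_de_extra: int = 20
    f_high: float = 0.9
    f_low: float = 0.1
    frac_stage2_highrisk: float = 0.25
    baseline_hazard: float = 0.01
    hr_true: float = 4.0
    censor_rate: float = 0.015
    noise_sd: float = 1.0
    de_shift: float = 1.0
    #: optional coupling of the latent stage II risk label to the metastatic
    #: mean shift (fraction of de_shift applied to latent-high stage II
    #: samples); 0 keeps planted pairs the only prognostic structure
    risk_shift: float = 0.0
    #: multiplicative hazard of the chemotherapy arm within each risk stratum
    ctx_hr_low: float = 2.8
    ctx_hr_high: float = 0.55
    mean_low: float = 4.0
    mean_high: float = 12.0
    #: independent within-pair noise of planted pair members around their
    #: shared per-sample level; see generate_cohort for why this is small
    pair_noise_sd: float = 0.25
    seed: int = 0
    #: seed of the "biology" (gene roles and per-gene means).  Defaults to
    #: ``seed``; give several cohorts the same assignment_seed and different
    #: seeds to emulate independent datasets measuring the same disease —
    #: identical planted pairs and DE genes, independent patients and noise.
    assignment_seed: int | None = None

    def validate(self) -> None:
        # equality of f_low/f_high and hr_true == 1 are allowed: they are the
        # null configurations used for type-I-error calibration
        if not (0.0 <= self.f_low <= self.f_high <= 1.0):
            raise ValueError("need 0 <= f_low <= f_high <= 1")
        if self.hr_true < 1.0:
            raise ValueError("hr_true must be >= 1")
        counts = (
            self.n_genes,
            self.n_stage1,
            self.n_stage2_noctx,
            self.n_stage2_ctx,
            self.n_stage34,
            self.n_planted_pairs,
            self.n_planted_de_extra,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if 2 * self.n_planted_pairs + self.n_planted_de_extra > self.n_genes:
            raise ValueError(
                "n_planted_pairs*2 + n_planted_de_extra exceeds n_genes"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """Truth labels for recovery tests: what was planted and where."""

    planted_pairs: list[OrientedGenePair]
    latent_risk: dict[str, str]  # sample_id -> "high" | "low"
    planted_de_genes: list[str]
    config: SyntheticConfig = field(default=None)  # type: ignore[assignment]

    def pair_keys(self) -> set[tuple[str, str]]:
        """Canonical (sorted) gene-id tuples of the planted pairs."""
        return {tuple(sorted((p.gene_a, p.gene_b))) for p in self.planted_pairs}

    def to_dict(self) -> dict:
        return {
            "planted_pairs": [
                {"gene_a": p.gene_a, "gene_b": p.gene_b, "high_risk_reo": p.high_risk_reo}
                for p in self.planted_pairs
            ],
            "latent_risk": self.latent_risk,
            "planted_de_genes": self.planted_de_genes,
            "config": self.config.to_dict() if self.config is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_pairs=[
                OrientedGenePair(p["gene_a"], p["gene_b"], p["high_risk_reo"])
                for p in d["planted_pairs"]
            ],
            latent_risk=dict(d["latent_risk"]),
            planted_de_genes=list(d["planted_de_genes"]),
            config=SyntheticConfig.from_dict(d["config"]) if d.get("config") else None,
        )


def _sample_frame(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign sample ids, stages, chemotherapy arms and latent risk labels."""
    blocks = [
        ("I", False, config.n_stage1),
        ("II", False, config.n_stage2_noctx),
        ("II", True, config.n_stage2_ctx),
    ]
    n34 = config.n_stage34
    blocks += [("III", False, n34 - n34 // 2), ("IV", False, n34 // 2)]
    rows = []
    for stage, ctx, n in blocks:
        rows += [(stage, ctx)] * n
    frame = pd.DataFrame(rows, columns=["stage", "ctx"])
    frame.index = pd.Index([f"S{i + 1:04d}" for i in range(len(frame))], name="sample_id")

    latent = np.where(frame["stage"].isin(["III", "IV"]), "high", "low")
    is2 = (frame["stage"] == "II").to_numpy()
    latent[is2] = np.where(
        rng.random(is2.sum()) < config.frac_stage2_highrisk, "high", "low"
    )
    frame["latent"] = latent
    return frame


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates with realistic marginals and explicit unknowns."""
    def with_unknown(values, p_unknown=0.05):
        values = np.asarray(values, dtype=object)
        values[rng.random(n) < p_unknown] = "unknown"
        return values

    return pd.DataFrame(
        {
            "age": np.round(np.clip(rng.normal(68.0, 11.0, n), 30, 92), 1),
            "sex": rng.choice(["male", "female"], n),
            "msi": with_unknown(rng.choice(["MSI", "MSS"], n, p=[0.15, 0.85])),
            "localization": with_unknown(rng.choice(["distal", "proximal"], n)),
            "braf_mut": with_unknown(rng.choice([0, 1], n, p=[0.9, 0.1])),
            "kras_mut": with_unknown(rng.choice([0, 1], n, p=[0.6, 0.4])),
            "tp53_mut": with_unknown(rng.choice([0, 1], n, p=[0.5, 0.5])),
        }
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression, clinical, ground truth) from one integer seed.

    The seed is split into independent streams for sample labels, background
    intensities, pair orientations, survival and covariates, so changing
    e.g. the orientation probabilities never perturbs the background draw —
    the planted and unplanted realizations of a seed share each sample's
    value multiset.  Gene roles and per-gene means come from a separate
    stream keyed by ``assignment_seed`` so several cohorts can share one
    planted biology (see :class:`SyntheticConfig`).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_frame, rng_bg, rng_orient, rng_surv, rng_cov = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    assignment_seed = config.seed if config.assignment_seed is None else config.assignment_seed
    rng_assign = np.random.default_rng(np.random.SeedSequence(assignment_seed).spawn(6)[5])

    frame = _sample_frame(config, rng_frame)
    n_samples = len(frame)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]

    # planted structure: disjoint pair genes, then extra DE genes
    perm = rng_assign.permutation(config.n_genes)
    npp = config.n_planted_pairs
    pair_idx = [(perm[2 * i], perm[2 * i + 1]) for i in range(npp)]
    extra_idx = perm[2 * npp : 2 * npp + config.n_planted_de_extra]
    planted_pairs = [
        OrientedGenePair(genes[a], genes[b], high_risk_reo="a<b") for a, b in pair_idx
    ]
    de_idx = np.array([b for _, b in pair_idx] + list(extra_idx), dtype=int)
    planted_de = [genes[i] for i in de_idx]

    # background: per-gene mean drawn once, i.i.d. Gaussian noise per sample.
    # The two members of a planted pair are modelled as co-expressed: they
    # share one baseline mean and one per-sample level, plus a small
    # independent component (pair_noise_sd).  Enforcing an ordering by
    # swapping necessarily hands the larger of the two draws to one member,
    # which couples that member's *level* to the risk label; with tightly
    # co-expressed members a swap moves a value by at most the small
    # independent component, so the risk signal lives in the planted
    # orderings and not in any single gene's level — the planted pairs stay
    # the unambiguous ground truth (the same evaluation-clarity reasoning
    # that makes the pairs gene-disjoint).  Total variance matches the
    # background noise_sd.
    mu = rng_assign.uniform(config.mean_low, config.mean_high, config.n_genes)
    for ia, ib in pair_idx:
        mu[ib] = mu[ia]
    values = mu[:, None] + rng_bg.normal(0.0, config.noise_sd, (config.n_genes, n_samples))
    if config.n_planted_pairs:
        sd_e = min(config.pair_noise_sd, config.noise_sd)
        sd_shared = np.sqrt(config.noise_sd**2 - sd_e**2)
        for ia, ib in pair_idx:
            shared = rng_bg.normal(0.0, sd_shared, n_samples)
            values[ia] = mu[ia] + shared + rng_bg.normal(0.0, sd_e, n_samples)
            values[ib] = mu[ib] + shared + rng_bg.normal(0.0, sd_e, n_samples)

    metastatic = frame["stage"].isin(["III", "IV"]).to_numpy()
    latent_high = (frame["latent"] == "high").to_numpy()
    is_stage2 = (frame["stage"] == "II").to_numpy()

    # mean shifts: planted DE genes up in metastatic samples, optionally a
    # partial shift in latent-high stage II samples (micro-metastasis coupling)
    values[np.ix_(de_idx, metastatic)] += config.de_shift
    if config.risk_shift:
        values[np.ix_(de_idx, is_stage2 & latent_high)] += config.risk_shift

    # plant orientations by within-sample swaps
    p_high = np.where(metastatic | latent_high, config.f_high, config.f_low)
    for (ia, ib), pair in zip(pair_idx, planted_pairs):
        want_high = rng_orient.random(n_samples) < p_high  # target: Ea < Eb
        cur_high = values[ia] < values[ib]
        swap = want_high != cur_high
        va = values[ia, swap].copy()
        values[ia, swap] = values[ib, swap]
        values[ib, swap] = va

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=frame.index)
    expr = expr.sort_index()

    # survival: exponential event and censoring times, per-sample hazard
    hazard = np.full(n_samples, config.baseline_hazard)
    hazard[latent_high] *= config.hr_true
    ctx = frame["ctx"].to_numpy()
    hazard[ctx & latent_high] *= config.ctx_hr_high
    hazard[ctx & ~latent_high] *= config.ctx_hr_low
    t_event = rng_surv.exponential(1.0 / hazard)
    t_cens = rng_surv.exponential(1.0 / config.censor_rate, n_samples)
    rfs_time = np.minimum(t_event, t_cens)
    rfs_event = (t_event <= t_cens).astype(int)

    clinical = pd.DataFrame(
        {
            "stage": frame["stage"].to_numpy(),
            "ctx": ctx,
            "rfs_time": np.round(rfs_time, 4),
            "rfs_event": rfs_event,
        },
        index=frame.index,
    )
    covariates = _covariates(n_samples, rng_cov)
    covariates.index = frame.index
    clinical = pd.concat([clinical, covariates], axis=1)

    truth = GroundTruth(
        planted_pairs=planted_pairs,
        latent_risk=dict(zip(frame.index, frame["latent"])),
        planted_de_genes=sorted(planted_de),
        config=config,
    )
    return expr, clinical, truth


def write_fixture(
    outdir: str | Path,
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write expression.tsv, clinical.tsv and a truth.json sidecar.

    The sidecar records the full generator configuration (including the seed),
    so the fixture can be regenerated byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    rio.write_expression(expr, paths["expression"])
    rio.write_clinical(clinical, paths["clinical"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    return paths


def read_fixture(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    outdir = Path(outdir)
    expr = rio.read_expression(outdir / "expression.tsv")
    clinical = rio.read_clinical(outdir / "clinical.tsv")
    with open(outdir / "truth.json") as fh:
        truth = GroundTruth.from_dict(json.load(fh))
    return expr, clinical, truth
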