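"""End-to-end orchestration of the signature discovery/validation pipeline.

Stages, in order:

1. cohort selection per dataset (stage I vs stage III/IV for screening,
   stage II without chemotherapy for training/validation)
2. metastasis differential expression per training dataset (t-test, BH-FDR)
3. gene-pair reversal screening per training dataset (Fisher exact, BH-FDR)
4. cross-dataset consistent overlap of reversed pairs
5. univariate Cox filtering to prognosis-associated pairs
6. greedy forward selection of the majority-vote signature
7. classification and survival evaluation on training and validation cohorts
8. risk differential expression, concordance with the metastasis DE genes,
   hypergeometric overlap, optional gene-set enrichment
9. chemotherapy-stratified survival comparison within predicted risk groups

Inputs are either file-backed datasets or a synthetic-cohort block; every
threshold and seed is echoed to a machine-readable run log so a run can be
reproduced exactly from its log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import io as rio
from . import screen, signature as sig, simulate
from . import survival as surv

log = logging.getLogger(__name__)

__all__ = ["DatasetPaths", "PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class DatasetPaths:
    name: str
    expression: str
    clinical: str


@dataclass
class PipelineConfig:
    """Pipeline inputs and thresholds.

    Thresholds default to the published screening cascade: DE FDR 0.1,
    pair-reversal FDR 0.2, Cox p 0.01, enrichment FDR 0.05, null concordance
    probability 0.5.  Either ``training``/``validation`` file paths or a
    ``synthetic`` generator block must be given; with a synthetic block, two
    training cohorts and one validation cohort are generated from seeds
    derived from ``seed``.
    """

    training: list[DatasetPaths] = field(default_factory=list)
    validation: list[DatasetPaths] = field(default_factory=list)
    synthetic: simulate.SyntheticConfig | None = None
    gmt: str | None = None
    de_fdr: float = 0.1
    pair_fdr: float = 0.2
    cox_p: float = 0.01
    enrich_fdr: float = 0.05
    pe: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name, value in (
            ("de_fdr", self.de_fdr),
            ("pair_fdr", self.pair_fdr),
            ("cox_p", self.cox_p),
            ("enrich_fdr", self.enrich_fdr),
        ):
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.synthetic is None and not self.training:
            raise ValueError("either training datasets or a synthetic block is required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["training"] = [DatasetPaths(**t) for t in d.get("training", [])]
        d["validation"] = [DatasetPaths(**t) for t in d.get("validation", [])]
        if d.get("synthetic"):
            d["synthetic"] = simulate.SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _load_datasets(config: PipelineConfig):
    """Return ordered [(name, expr, clinical)] for training and validation."""
    if config.synthetic is not None:
        base = config.synthetic
        cohorts = []
        assignment = base.seed if base.assignment_seed is None else base.assignment_seed
        for i, name in enumerate(["train1", "train2", "validation"]):
            # same planted biology, independent patients per dataset
            sub = dataclasses.replace(
                base,
                seed=(base.seed + 7919 * i) % (2**31),
                assignment_seed=assignment,
            )
            expr, clinical, truth = simulate.generate_cohort(sub)
            cohorts.append((name, expr, clinical, truth))
        training = [c[:3] for c in cohorts[:2]]
        validation = [cohorts[2][:3]]
        truths = {c[0]: c[3] for c in cohorts}
        return training, validation, truths
    training = [
        (d.name, rio.read_expression(d.expression), rio.read_clinical(d.clinical))
        for d in config.training
    ]
    validation = [
        (d.name, rio.read_expression(d.expression), rio.read_clinical(d.clinical))
        for d in config.validation
    ]
    return training, validation, {}


def _risk_de(expr, clinical, calls, de_fdr):
    """Risk differential expression among stage II no-CTX samples."""
    cohort = rio.select_cohort(clinical, {"II"}, ctx=False)
    high = [s for s in cohort if calls.loc[s, "label"] == "high"]
    low = [s for s in cohort if calls.loc[s, "label"] == "low"]
    if len(high) < 2 or len(low) < 2:
        return None
    return screen.de_genes(expr, high, low, fdr_threshold=de_fdr)


def _de_directions(de: pd.DataFrame) -> dict[str, str]:
    return dict(zip(de.index, de["direction"]))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts under ``outdir``.

    Returns the run log (also written as ``run_log.json``): configuration
    echo plus per-stage summaries.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name):
        log.info("pipeline stage: %s", name)
        return name

    # -- load or generate data -------------------------------------------
    current = stage("load")
    try:
        training, validation, truths = _load_datasets(config)
        if config.synthetic is not None:
            for name, expr, clinical in training + validation:
                simulate.write_fixture(outdir / f"data_{name}", expr, clinical, truths[name])
        run_log["stages"][current] = {
            "training": [t[0] for t in training],
            "validation": [v[0] for v in validation],
        }

        # -- metastasis DE + reversal screening per training set ---------
        current = stage("screen")
        reversal_lists = []
        met_de_lists = {}
        for name, expr, clinical in training:
            nonmet = rio.select_cohort(clinical, {"I"}, ctx="any")
            met = rio.select_cohort(clinical, {"III", "IV"}, ctx="any")
            de = screen.de_genes(expr, met, nonmet, fdr_threshold=config.de_fdr)
            met_de_lists[name] = de
            de.to_csv(outdir / f"metastatic_de_{name}.tsv", sep="\t")
            rev = screen.reversed_pairs(
                expr, met, nonmet, de.index, fdr_threshold=config.pair_fdr
            )
            rev.to_csv(outdir / f"reversed_pairs_{name}.tsv", sep="\t", index=False)
            reversal_lists.append(rev)
            run_log["stages"].setdefault(current, {})[name] = {
                "n_de": len(de),
                "n_reversed": len(rev),
                "n_pairs_tested": rev.attrs.get("n_tested"),
            }

        # -- cross-dataset consistent overlap ----------------------------
        current = stage("overlap")
        if len(reversal_lists) >= 2:
            overlap = screen.consistent_overlap(reversal_lists[0], reversal_lists[1])
            survivors = overlap.survivors
            run_log["stages"][current] = {
                "k": overlap.k,
                "s": overlap.s,
                "score_pct": None if overlap.score is None else round(100 * overlap.score, 2),
            }
        else:
            survivors = reversal_lists[0]
            run_log["stages"][current] = {"note": "single training set; overlap skipped"}
        survivors.to_csv(outdir / "metastasis_pairs.tsv", sep="\t", index=False)
        if survivors.empty:
            raise PipelineError(current, "no metastasis-associated pairs survive")

        # -- prognostic filtering + forward selection --------------------
        current = stage("select")
        name1, expr1, clin1 = training[0]
        train_cohort = rio.select_cohort(clin1, {"II"}, ctx=False)
        candidates = sig.prognostic_pairs(
            expr1, clin1, survivors, p_threshold=config.cox_p, samples=train_cohort
        )
        if not candidates:
            raise PipelineError(current, "no prognosis-associated pairs at p < %g" % config.cox_p)
        chosen = sig.forward_select(candidates, expr1, clin1, samples=train_cohort)
        sig.save_signature(chosen, outdir / "signature.json")
        run_log["stages"][current] = {
            "n_candidates": len(candidates),
            "signature_pairs": [list(p.key()) for p in chosen.pairs],
            "vote_threshold": chosen.vote_threshold,
        }

        # -- classification + survival evaluation ------------------------
        current = stage("evaluate")
        run_log["stages"][current] = {}
        all_calls = {}
        for name, expr, clinical in training[:1] + validation:
            cohort = rio.select_cohort(clinical, {"II"}, ctx=False)
            calls = sig.classify_gps(expr, chosen, cohort)
            calls.to_csv(outdir / f"risk_calls_{name}.tsv", sep="\t")
            all_calls[name] = (expr, clinical, calls)
            high = (calls["label"] == "high").to_numpy()
            times = clinical.loc[cohort, "rfs_time"].to_numpy(dtype=float)
            events = clinical.loc[cohort, "rfs_event"].to_numpy(dtype=int)
            if high.any() and not high.all():
                comp = surv.compare_groups(times, events, high)
                run_log["stages"][current][name] = comp.to_dict()
            else:
                run_log["stages"][current][name] = {"note": "degenerate classification"}
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(run_log["stages"][current], fh, indent=1)

        # -- risk DE, concordance, overlap, enrichment -------------------
        current = stage("concordance")
        risk_de = {}
        for name, (expr, clinical, calls) in all_calls.items():
            de = _risk_de(expr, clinical, calls, config.de_fdr)
            if de is not None:
                risk_de[name] = de
                de.to_csv(outdir / f"risk_de_{name}.tsv", sep="\t")
        conc_summary = {}
        names = list(risk_de)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                res = conc.concordance_score(
                    _de_directions(risk_de[names[i]]),
                    _de_directions(risk_de[names[j]]),
                    pe=config.pe,
                )
                conc_summary[f"risk_de:{names[i]}|{names[j]}"] = dataclasses.asdict(res)
        for name in names:
            if name in met_de_lists:
                expr = all_calls[name][0]
                p_overlap = conc.overlap_test(
                    set(risk_de[name].index), set(met_de_lists[name].index), expr.shape[0]
                )
                res = conc.concordance_score(
                    _de_directions(risk_de[name]),
                    _de_directions(met_de_lists[name]),
                    pe=config.pe,
                )
                conc_summary[f"risk_vs_metastatic:{name}"] = {
                    "overlap_p": p_overlap,
                    **dataclasses.asdict(res),
                }
        with open(outdir / "concordance.json", "w") as fh:
            json.dump(conc_summary, fh, indent=1)
        run_log["stages"][current] = conc_summary

        current = stage("enrich")
        if config.gmt and risk_de:
            consensus = conc.integrate_de_lists(
                [_de_directions(d) for d in risk_de.values()], min_lists=min(2, len(risk_de))
            )
            categories = conc.read_gmt(config.gmt)
            measured = set(training[0][1].index)
            enrichment = conc.enrich_categories(
                set(consensus), categories, measured, fdr_threshold=config.enrich_fdr
            )
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            run_log["stages"][current] = {
                "n_consensus_de": len(consensus),
                "n_significant": int(enrichment["significant"].sum()),
            }
        else:
            run_log["stages"][current] = {"note": "no GMT provided or no risk-DE lists"}

        # -- chemotherapy-stratified comparison --------------------------
        current = stage("ctx_strata")
        run_log["stages"][current] = {}
        for name, expr, clinical in training[:1] + validation:
            both_arms = rio.select_cohort(clinical, {"II"}, ctx="any")
            if not both_arms:
                continue
            calls = sig.classify_gps(expr, chosen, both_arms)
            for risk_label in ("high", "low"):
                in_stratum = [s for s in both_arms if calls.loc[s, "label"] == risk_label]
                ctx_flag = clinical.loc[in_stratum, "ctx"].to_numpy(dtype=bool)
                if not ctx_flag.any() or ctx_flag.all():
                    continue
                times = clinical.loc[in_stratum, "rfs_time"].to_numpy(dtype=float)
                events = clinical.loc[in_stratum, "rfs_event"].to_numpy(dtype=int)
                comp = surv.compare_groups(times, events, ctx_flag)
                run_log["stages"][current][f"{name}:{risk_label}"] = comp.to_dict()

    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineError(current, str(err)) from err

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, default=str)
    return run_log
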