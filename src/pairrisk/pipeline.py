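"""End-to-end orchestration: one config, one seed, one run directory.

The run executes screen -> pairs -> model selection -> evaluation (and the
downstream TMB/score comparisons when a MAF or score table is supplied),
writing per-stage tables plus a manifest recording the seed, input
checksums, thresholds, and the record count entering and leaving every
filter — the selection funnel is the procedure's credibility, so it is
logged explicitly. Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import DEFAULT_REGULATORS
from .downstream import compare_scores_by_group, compute_tmb, mutation_frequency_by_group, surv_cutpoint
from .errors import ConfigError, DataError, PairriskError
from .evaluation import (
    clinical_auc_comparison,
    independence_cox,
    km_logrank,
    optimal_cutoff,
    time_dependent_roc,
)
from .io import read_clinical, read_expression, read_maf, read_scores, write_model
from .model_selection import fit_multivariate_cox, repeated_lasso_select, select_best_model, univariate_cox_screen
from .pairs import build_pair_matrix, stability_filter
from .screen import coexpression_screen, differential_expression

logger = logging.getLogger("pairrisk")


@dataclass
class RunConfig:
    """All thresholds of the procedure, with the published defaults.

    The zero-config behaviour IS the published procedure: co-expression
    |r| > 0.4 at P < 0.001; DE at FDR < 0.05 and |log2FC| >= 1; pair
    stability within [0.2, 0.8]; univariate Cox P < 0.001; 1000 LASSO
    repetitions at 80% subsampling with frequency threshold 100; ROC
    horizons 1/2/3 years; TMB over a 38 Mb capture.
    """

    # inputs
    expression: str = ""
    tissue: str = ""
    annotation: str = ""
    clinical: str = ""
    maf: str | None = None
    scores: str | None = None
    # screen
    regulators: tuple = DEFAULT_REGULATORS
    correlation: str = "pearson"
    r_min: float = 0.4
    p_max: float = 0.001
    fdr_max: float = 0.05
    lfc_min: float = 1.0
    moderation: bool = True
    # pairs
    stability_lo: float = 0.20
    stability_hi: float = 0.80
    # model selection
    unicox_p_max: float = 0.001
    lasso_repeats: int = 1000
    freq_min: int = 100
    freq_grid: tuple = ()
    subsample: float = 0.8
    cv_folds: int = 5
    lambda_rule: str = "1se"
    # evaluation
    horizons: tuple = (365.0, 730.0, 1095.0)
    # downstream
    min_prop: float = 0.1
    capture_mb: float = 38.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stability_lo >= self.stability_hi:
            raise ConfigError("stability_lo must be < stability_hi")
        if self.lasso_repeats < 1:
            raise ConfigError("lasso_repeats must be >= 1")
        if not 0 < self.subsample <= 1:
            raise ConfigError("subsample must be in (0, 1]")
        if self.correlation not in ("pearson", "spearman"):
            raise ConfigError(f"unknown correlation method {self.correlation!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regulators", "freq_grid", "horizons"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("regulators", "freq_grid", "horizons"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns the manifest (also written to
    ``outdir/manifest.json``). Any stage failure aborts with the stage name;
    tables written before the failure are left in place."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pairrisk_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config))),
        "inputs": {},
        "funnel": {},
        "results": {},
    }
    stage = "load"
    try:
        for name in ("expression", "tissue", "annotation", "clinical", "maf", "scores"):
            p = getattr(config, name)
            if p:
                manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
        if not (config.expression and config.clinical and config.tissue):
            raise DataError("config must name expression, tissue and clinical inputs")
        expr, annotation = read_expression(
            config.expression,
            annotation_path=config.annotation or None,
            tissue_path=config.tissue,
        )
        clinical = read_clinical(config.clinical)
        n_lnc = int((annotation.loc[list(expr.values.index), "biotype"] == "lncRNA").sum())
        manifest["funnel"]["lncRNAs"] = n_lnc

        stage = "screen"
        edges, coexpressed = coexpression_screen(
            expr, annotation, config.regulators,
            r_min=config.r_min, p_max=config.p_max, method=config.correlation,
        )
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        manifest["funnel"]["coexpressed_lncRNAs"] = len(coexpressed)
        de = differential_expression(
            expr, coexpressed, fdr_max=config.fdr_max, lfc_min=config.lfc_min,
            moderation=config.moderation,
        )
        de.to_csv(outdir / "de_results.tsv", sep="\t")
        de_set = sorted(de.index[de["significant"]])
        manifest["funnel"]["de_lncRNAs"] = len(de_set)
        manifest["results"]["de_up"] = int((de["significant"] & (de["direction"] == "up")).sum())
        manifest["results"]["de_down"] = int((de["significant"] & (de["direction"] == "down")).sum())

        stage = "pairs"
        tumor_samples = [s for s in expr.tumor_samples() if s in clinical.index]
        if len(clinical.index.difference(tumor_samples)):
            logger.info(
                "%d clinical samples without tumor expression excluded",
                len(clinical.index.difference(tumor_samples)),
            )
        clinical = clinical.loc[tumor_samples]
        pm_all = build_pair_matrix(expr.values[tumor_samples], de_set)
        manifest["funnel"]["pairs"] = int(pm_all.shape[0])
        pm, freq = stability_filter(pm_all, config.stability_lo, config.stability_hi)
        freq.to_csv(outdir / "freq.tsv", sep="\t")
        pm.to_csv(outdir / "pair_matrix.tsv", sep="\t")
        manifest["funnel"]["stable_pairs"] = int(pm.shape[0])

        stage = "model_selection"
        unicox, candidates = univariate_cox_screen(pm, clinical, p_max=config.unicox_p_max)
        unicox.to_csv(outdir / "unicox.tsv", sep="\t")
        manifest["funnel"]["unicox_candidates"] = len(candidates)
        if len(candidates) < 2:
            raise DataError(f"only {len(candidates)} univariate candidates; cannot run LASSO")
        freq_table, _ = repeated_lasso_select(
            pm.loc[candidates], clinical,
            R=config.lasso_repeats, freq_min=0, subsample=config.subsample,
            seed=config.seed, cv_folds=config.cv_folds, lambda_rule=config.lambda_rule,
        )
        freq_table.to_csv(outdir / "freq_table.tsv", sep="\t")
        thresholds = list(config.freq_grid) or [config.freq_min]
        models = []
        for fm in thresholds:
            sel = list(freq_table.index[freq_table["count"] > fm])
            if not sel:
                continue
            m = fit_multivariate_cox(pm.loc[sel], clinical)
            m.provenance.update(
                {"R": config.lasso_repeats, "freq_min": int(fm), "seed": config.seed}
            )
            models.append(m)
        if not models:
            raise DataError("no pairs exceeded any selection-frequency threshold")
        model = select_best_model(models, pm, clinical, horizon=config.horizons[0])
        manifest["funnel"]["lasso_selected"] = len(model.pairs)
        manifest["funnel"]["model_pairs"] = len(model.pairs)

        stage = "evaluation"
        scores = model.score(pm)
        roc1 = time_dependent_roc(scores, clinical, config.horizons[0])
        model.cutoff = optimal_cutoff(roc1)
        write_model(model, outdir / "model.txt")
        groups = model.assign_groups(scores)
        pd.DataFrame({"riskScore": scores, "group": groups}).to_csv(
            outdir / "groups.tsv", sep="\t", index_label="sample"
        )
        aucs = {}
        for h in config.horizons:
            roc = time_dependent_roc(scores, clinical, h)
            pd.DataFrame(
                {"threshold": roc.thresholds, "sens": roc.sens, "spec": roc.spec}
            ).to_csv(outdir / f"roc_{int(round(h / 365))}y.tsv", sep="\t", index=False)
            aucs[f"auc_{int(round(h / 365))}y"] = roc.auc
        curves, chi2, logrank_p = km_logrank(groups, clinical)
        km = pd.concat(curves.values(), axis=1)
        km.to_csv(outdir / "km.tsv", sep="\t")
        cox_table = independence_cox(scores, clinical)
        cox_table.to_csv(outdir / "cox_table.tsv", sep="\t", index=False)
        auc_cmp = clinical_auc_comparison(clinical, scores, config.horizons[0])
        auc_cmp.to_csv(outdir / "clinical_auc.tsv", sep="\t", index=False)
        manifest["results"].update(
            {
                **aucs,
                "cutoff": model.cutoff,
                "n_high": int((groups == "high").sum()),
                "n_low": int((groups == "low").sum()),
                "logrank_chi2": chi2,
                "logrank_p": logrank_p,
            }
        )

        if config.maf:
            stage = "downstream"
            maf = read_maf(config.maf)
            tmb = compute_tmb(maf, tumor_samples, capture_mb=config.capture_mb)
            tmb.to_csv(outdir / "tmb.tsv", sep="\t")
            cp = surv_cutpoint(tmb["tmb"], clinical, min_prop=config.min_prop)
            (outdir / "cutpoint.txt").write_text(
                f"cutpoint\t{cp.cutpoint!r}\nmax_stat\t{cp.max_stat!r}\n"
            )
            mutfreq, overall = mutation_frequency_by_group(maf, groups)
            mutfreq.to_csv(outdir / "mutfreq.tsv", sep="\t")
            manifest["results"]["tmb_cutpoint"] = cp.cutpoint
            manifest["results"]["mutated_sample_rate"] = overall.to_dict()
        if config.scores:
            stage = "downstream"
            score_table = read_scores(config.scores)
            immune = compare_scores_by_group(score_table, groups, scores)
            immune.to_csv(outdir / "immune_tests.tsv", sep="\t", index=False)
    except PairriskError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
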