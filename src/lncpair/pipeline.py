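"""Workflow orchestration: staged artifacts, manifest, determinism.

Each stage reads only on-disk artifacts (its upstream outputs plus the
original inputs), so running stages individually composes to the same
results as :func:`run_all`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from lncpair import __version__, association, evaluate, ingest, pairing, screen, signature
from lncpair.config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ("screen", "pair", "fit", "evaluate", "associate")


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing required artifact {path} ({hint})")
    return path


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_screen(config: PipelineConfig) -> dict:
    """Correlation screen + differential expression over lncRNAs."""
    out = _outdir(config)
    expr = ingest.read_expression(_require(Path(config.expression), "expression TSV"))
    annot = ingest.read_gtf_biotypes(_require(Path(config.gtf), "GTF annotation"))
    immune_ids = ingest.read_immune_genes(
        _require(Path(config.immune_genes), "immune gene list")
    )
    mrna, lnc = ingest.split_lncrna(expr, annot)
    present = [g for g in immune_ids if g in set(mrna.gene_ids)]
    if not present:
        raise ValueError("no immune genes found in the mRNA expression matrix")
    immune = mrna.subset_genes(present)

    hits = screen.pearson_screen(
        lnc,
        immune,
        r_threshold=config.r_threshold,
        p_threshold=config.corr_p_threshold,
        mode=config.corr_mode,
    )
    hit_ids = [h.lncrna_id for h in hits]
    pd.DataFrame([asdict(h) for h in hits]).to_csv(
        out / "immune_lncrna_hits.tsv", sep="\t", index=False
    )

    if not hit_ids:
        raise ValueError("no immune-related lncRNAs pass the correlation screen")
    immune_lnc = lnc.subset_genes(hit_ids)
    de = screen.moderated_t_de(
        immune_lnc.tumor(),
        immune_lnc.normal(),
        lfc_threshold=config.lfc_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    pd.DataFrame([asdict(r) for r in de]).to_csv(
        out / "de_results.tsv", sep="\t", index=False
    )
    de_ids = screen.de_gene_ids(de)
    (out / "de_lncrna_ids.txt").write_text("\n".join(de_ids) + "\n")
    return {
        "n_lncrna": len(lnc.gene_ids),
        "n_immune_lncrna": len(hit_ids),
        "n_de_lncrna": len(de_ids),
    }


def run_pair(config: PipelineConfig) -> dict:
    """Pair-indicator construction and effective-match filtering."""
    out = _outdir(config)
    expr = ingest.read_expression(_require(Path(config.expression), "expression TSV"))
    de_ids = [
        line.strip()
        for line in _require(out / "de_lncrna_ids.txt", "run the screen stage first")
        .read_text()
        .splitlines()
        if line.strip()
    ]
    pairs = pairing.build_pairs(expr.subset_genes(de_ids), tumor_only=True)
    n_candidates = pairs.n_pairs
    pairs = pairing.filter_effective(pairs, min_minority_frac=config.min_minority_frac)
    pairs.to_tsv(out / "pair_matrix.tsv")
    return {"n_candidate_pairs": n_candidates, "n_effective_pairs": pairs.n_pairs}


def run_fit(config: PipelineConfig) -> dict:
    """Univariate screen, LASSO stability selection, joint Cox fit, RS."""
    out = _outdir(config)
    pairs = pairing.read_pair_matrix(
        _require(out / "pair_matrix.tsv", "run the pair stage first")
    )
    clin = ingest.read_clinical(_require(Path(config.clinical), "clinical TSV"))

    uni = signature.univariate_cox_screen(pairs, clin, p_threshold=config.cox_p_threshold)
    pd.DataFrame([asdict(r) for r in uni]).to_csv(out / "unicox.tsv", sep="\t", index=False)
    if not uni:
        raise ValueError("no pairs pass the univariate Cox screen")
    screened = pairs.subset_pairs([r.pair for r in uni])

    counts, selected = signature.lasso_stability_select(
        screened,
        clin,
        n_reps=config.n_reps,
        n_folds=config.n_folds,
        freq_threshold=config.freq_threshold,
        seed=config.seed,
    )
    pd.DataFrame([asdict(c) for c in counts]).to_csv(
        out / "stability_counts.tsv", sep="\t", index=False
    )
    if not selected:
        raise ValueError(
            f"no pair exceeds the selection frequency threshold {config.freq_threshold}"
        )

    model = signature.fit_multivariate_cox(pairs.subset_pairs(selected), clin)
    model.to_tsv(out / "signature.tsv")
    (out / "model_meta.json").write_text(json.dumps(model.meta, indent=2, sort_keys=True))
    profile = signature.risk_score(model, pairs)
    profile.rs.to_csv(out / "risk_scores.tsv", sep="\t", index_label="sample_id")
    return {
        "n_unicox_pass": len(uni),
        "n_selected_pairs": len(selected),
    }


def _read_profile(out: Path) -> signature.RiskProfile:
    rs = pd.read_csv(
        _require(out / "risk_scores.tsv", "run the fit stage first"),
        sep="\t",
        index_col=0,
    ).iloc[:, 0]
    return signature.RiskProfile(rs=rs)


def _read_grouped_profile(out: Path) -> signature.RiskProfile:
    df = pd.read_csv(
        _require(out / "groups.tsv", "run the evaluate stage first"),
        sep="\t",
        index_col=0,
    )
    return signature.RiskProfile(rs=df["risk_score"], group=df["group"])


def run_evaluate(config: PipelineConfig) -> dict:
    """tdROC/AUC per horizon, cutoff, groups, KM/log-rank, independence."""
    out = _outdir(config)
    profile = _read_profile(out)
    clin = ingest.read_clinical(_require(Path(config.clinical), "clinical TSV"))

    aucs = {}
    roc_one_year = None
    for years in config.horizons_years:
        horizon = years * evaluate.YEAR_DAYS
        roc = evaluate.td_roc(profile, clin, horizon)
        aucs[years] = roc.auc
        pd.DataFrame(
            {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
        ).to_csv(out / f"roc_{years:g}y.tsv", sep="\t", index=False)
        if roc_one_year is None:
            roc_one_year = roc
    pd.Series(aucs, name="auc").to_csv(out / "auc.tsv", sep="\t", index_label="horizon_years")

    cut = evaluate.optimal_cutoff(roc_one_year)
    # criterion labeled per the source convention; computed as max(TPR - FPR)
    (out / "cutoff.json").write_text(
        json.dumps(
            {
                "cutoff": cut.cutoff,
                "criterion": cut.criterion,
                "criterion_rule": "youden_j_max",
                "horizon_days": cut.horizon,
            },
            indent=2,
            sort_keys=True,
        )
    )
    profile = evaluate.assign_groups(profile, cut.cutoff)
    pd.DataFrame({"risk_score": profile.rs, "group": profile.group}).to_csv(
        out / "groups.tsv", sep="\t", index_label="sample_id"
    )

    comp = evaluate.km_logrank(profile, clin)
    (out / "logrank.json").write_text(
        json.dumps(
            {
                "n_high": comp.n_high,
                "n_low": comp.n_low,
                "statistic": comp.logrank_stat,
                "p": comp.p,
            },
            indent=2,
            sort_keys=True,
        )
    )
    km = pd.concat(
        [df.assign(group=label) for label, df in comp.km_curves.items()],
        ignore_index=True,
    )
    km.to_csv(out / "km_curves.tsv", sep="\t", index=False)

    uni, multi = evaluate.independence_analysis(profile, clin)
    uni.to_csv(out / "independence_univariate.tsv", sep="\t")
    multi.to_csv(out / "independence_multivariate.tsv", sep="\t")
    auc_cmp = evaluate.compare_auc(
        profile, clin, horizon=config.horizons_years[0] * evaluate.YEAR_DAYS
    )
    auc_cmp.to_csv(out / "auc_compare.tsv", sep="\t")
    return {
        "auc": {f"{k:g}y": round(v, 6) for k, v in aucs.items()},
        "cutoff": cut.cutoff,
        "n_high": comp.n_high,
        "n_low": comp.n_low,
        "logrank_p": comp.p,
    }


def run_associate(config: PipelineConfig) -> dict:
    """Clinical / infiltration / checkpoint / IC50 association statistics."""
    out = _outdir(config)
    profile = _read_grouped_profile(out)
    clin = ingest.read_clinical(_require(Path(config.clinical), "clinical TSV"))

    clin_assoc = association.clinical_association(profile, clin)
    pd.DataFrame([asdict(a) for a in clin_assoc]).to_csv(
        out / "clinical_association.tsv", sep="\t", index=False
    )
    subgroup = []
    for a in clin_assoc:
        try:
            subgroup.append(asdict(association.subgroup_rs_comparison(profile, clin, a.feature)))
        except ValueError:
            continue
    pd.DataFrame(subgroup).to_csv(out / "subgroup_tests.tsv", sep="\t", index=False)
    counts = {"n_clinical_features": len(clin_assoc)}

    if config.infiltration:
        infil = pd.read_csv(_require(Path(config.infiltration), "infiltration TSV"),
                            sep="\t", index_col=0)
        rows = association.infiltration_association(profile, infil)
        pd.DataFrame([asdict(r) for r in rows]).to_csv(
            out / "infiltration_association.tsv", sep="\t", index=False
        )
        counts["n_infiltration_rows"] = len(rows)

    if config.expression:
        expr = ingest.read_expression(Path(config.expression))
        rows = association.expression_comparison(profile, expr.tumor())
        pd.DataFrame([asdict(r) for r in rows]).to_csv(
            out / "checkpoint_comparison.tsv", sep="\t", index=False
        )
        counts["n_checkpoint_genes"] = len(rows)

    if config.ic50:
        ic50 = pd.read_csv(_require(Path(config.ic50), "IC50 TSV"), sep="\t", index_col=0)
        rows = association.ic50_comparison(profile, ic50)
        pd.DataFrame([asdict(r) for r in rows]).to_csv(
            out / "ic50_comparison.tsv", sep="\t", index=False
        )
        counts["n_drugs"] = len(rows)
    return counts


_STAGE_FUNCS = {
    "screen": run_screen,
    "pair": run_pair,
    "fit": run_fit,
    "evaluate": run_evaluate,
    "associate": run_associate,
}


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and write a machine-readable manifest.

    A stage failure leaves earlier artifacts in place and re-raises with
    the stage name attached.
    """
    config.validate()
    out = _outdir(config)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    for stage in STAGES:
        try:
            manifest["stages"][stage] = _STAGE_FUNCS[stage](config)
        except Exception as err:
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True, default=str)
            )
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        logger.info("stage %s complete", stage)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest
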