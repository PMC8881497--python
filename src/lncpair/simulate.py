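"""Seeded synthetic cohort generator with known ground truth.

Builds a TCGA-like expression matrix (FPKM-like values for mRNAs and
lncRNAs), a minimal GTF, a clinical table and an immune-gene list so every
pipeline stage can be exercised and checked against recorded truth:

* a shared latent immune factor drives immune genes and immune lncRNAs so
  the Pearson screen recovers them;
* a subset of immune lncRNAs receives a tumor-only log2 shift so the DE
  gates fire;
* survival follows an exponential hazard proportional to
  exp(sum_k beta_k * S_k) over known pair indicators, with independent
  uniform censoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lncpair.ingest import (
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotation,
)
from lncpair.pairing import PAIR_SEP

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    n_tumor: int = 414
    n_normal: int = 19
    n_mrna: int = 200
    n_lncrna: int = 80
    n_immune_genes: int = 40
    n_immune_lncrna: int = 20
    n_de_lncrna: int = 8
    de_log2_shift: float = 2.0
    factor_loading: float = 0.7
    n_true_pairs: int = 3
    true_betas: tuple = (0.9, -0.8, 0.8)
    baseline_hazard: float = 0.0008  # events per day
    censor_max: float = 2500.0  # days
    stage_association: float = 0.0  # ties stage to true-RS quantile
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tumor", "n_normal", "n_mrna", "n_lncrna",
                     "n_immune_genes", "n_immune_lncrna", "n_de_lncrna",
                     "n_true_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_de_lncrna > self.n_immune_lncrna:
            raise ValueError("n_de_lncrna must be <= n_immune_lncrna")
        if self.n_immune_lncrna > self.n_lncrna:
            raise ValueError("n_immune_lncrna must be <= n_lncrna")
        if self.n_immune_genes > self.n_mrna:
            raise ValueError("n_immune_genes must be <= n_mrna")
        max_pairs = self.n_de_lncrna * (self.n_de_lncrna - 1) // 2
        if self.n_true_pairs > max_pairs:
            raise ValueError("n_true_pairs exceeds n_de_lncrna*(n_de_lncrna-1)/2")
        if len(self.true_betas) != self.n_true_pairs:
            raise ValueError("true_betas length must equal n_true_pairs")
        if not (0 < self.factor_loading <= 1):
            raise ValueError("factor_loading must be in (0, 1]")
        if self.censor_max <= 0:
            raise ValueError("censor_max must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0 <= self.stage_association <= 1):
            raise ValueError("stage_association must be in [0, 1]")


@dataclass
class TruthRecord:
    immune_lncrna_ids: list
    de_lncrna_ids: list
    true_pairs: list  # (lncRNA-A, lncRNA-B) tuples
    true_betas: list
    per_sample_true_rs: pd.Series

    def pair_names(self) -> list[str]:
        return [f"{a}{PAIR_SEP}{b}" for a, b in self.true_pairs]


def _true_pair_indices(n_de: int, n_pairs: int) -> list[tuple[int, int]]:
    """Disjoint pairs first, then remaining combinations in index order."""
    pairs = [(2 * k, 2 * k + 1) for k in range(n_de // 2)]
    if len(pairs) < n_pairs:
        from itertools import combinations

        used = set(pairs)
        for combo in combinations(range(n_de), 2):
            if combo not in used:
                pairs.append(combo)
                used.add(combo)
            if len(pairs) >= n_pairs:
                break
    return pairs[:n_pairs]


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, GeneAnnotation, ClinicalTable, list, TruthRecord]:
    """Generate a seeded cohort with recorded ground truth.

    Expression is built on the log2 scale (latent factor + noise + shifts)
    then mapped through max(2^x - 1, 0) so the values look FPKM-like while
    log2(x + 1) recovers the generated scale. Genes belonging to true
    pairs share one baseline mean and one shift direction so their pair
    indicators stay near 50% prevalence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mrna_ids = [f"PCG{i:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC{i:04d}" for i in range(config.n_lncrna)]
    immune_genes = mrna_ids[: config.n_immune_genes]
    immune_lnc = lnc_ids[: config.n_immune_lncrna]
    de_lnc = lnc_ids[: config.n_de_lncrna]

    tumor_ids = [f"SYN-{i:04d}-01" for i in range(config.n_tumor)]
    normal_ids = [f"SYN-{config.n_tumor + i:04d}-11" for i in range(config.n_normal)]
    samples = tumor_ids + normal_ids
    n_samples = len(samples)

    gene_ids = mrna_ids + lnc_ids
    n_genes = len(gene_ids)
    mu = rng.uniform(2.0, 8.0, size=n_genes)

    pair_idx = _true_pair_indices(config.n_de_lncrna, config.n_true_pairs)
    true_pairs = [(de_lnc[i], de_lnc[j]) for i, j in pair_idx]
    pair_members = sorted({g for ab in true_pairs for g in ab})
    shared_mu = rng.uniform(3.0, 7.0)
    for g in pair_members:
        mu[gene_ids.index(g)] = shared_mu

    # latent immune factor; pairwise corr between two loaded genes is
    # 1 / (1 + sigma^2) = factor_loading
    z = rng.standard_normal(n_samples)
    rho = config.factor_loading
    sigma = np.sqrt(1.0 / rho - 1.0)

    loaded = set(immune_genes) | set(immune_lnc)
    X = np.empty((n_genes, n_samples))
    for gi, gene in enumerate(gene_ids):
        eps = rng.standard_normal(n_samples)
        if gene in loaded:
            X[gi] = mu[gi] + z + sigma * eps
        else:
            X[gi] = mu[gi] + eps

    # tumor-only DE shifts; true-pair members all shift up so the pair
    # indicator is unaffected, remaining DE genes alternate direction
    directions = {}
    flip = -1
    for g in de_lnc:
        if g in pair_members:
            directions[g] = 1
        else:
            directions[g] = flip
            flip = -flip
    n_tumor = config.n_tumor
    for g, d in directions.items():
        X[gene_ids.index(g), :n_tumor] += d * config.de_log2_shift

    values = np.maximum(np.exp2(X) - 1.0, 0.0)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples),
        pd.Series({s: ("tumor" if s in set(tumor_ids) else "normal") for s in samples}),
    )

    classes = {g: "mRNA" for g in mrna_ids}
    classes.update({g: "lncRNA" for g in lnc_ids})
    annot = GeneAnnotation(classes)

    # survival from the true pair indicators over tumor samples
    tumor_vals = values[:, :n_tumor]
    S = np.zeros((config.n_true_pairs, n_tumor))
    for k, (a, b) in enumerate(true_pairs):
        S[k] = (tumor_vals[gene_ids.index(a)] > tumor_vals[gene_ids.index(b)]).astype(float)
    betas = np.asarray(config.true_betas, dtype=float)
    true_rs = betas @ S
    rate = config.baseline_hazard * np.exp(true_rs)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, config.censor_max, size=n_tumor)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    age = np.clip(np.round(rng.normal(68, 9, size=n_tumor)), 35, 90).astype(int)
    gender = rng.choice(["male", "female"], size=n_tumor, p=[0.75, 0.25])
    grade = rng.choice(["low", "high"], size=n_tumor, p=[0.2, 0.8])
    u = pd.Series(true_rs).rank(pct=True).to_numpy()
    p_late = np.clip(0.5 + config.stage_association * (u - 0.5), 0.0, 1.0)
    late = rng.uniform(size=n_tumor) < p_late
    stage = np.where(late, rng.choice(["III", "IV"], size=n_tumor),
                     rng.choice(["I", "II"], size=n_tumor))
    t_cat = rng.choice(["T1", "T2", "T3", "T4"], size=n_tumor, p=[0.1, 0.25, 0.35, 0.3])
    n_cat = rng.choice(["N0", "N1", "N2", "N3", "Nx"], size=n_tumor,
                       p=[0.55, 0.15, 0.15, 0.05, 0.10])
    m_cat = rng.choice(["M0", "M1", "Mx"], size=n_tumor, p=[0.7, 0.1, 0.2])

    clin = ClinicalTable(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "age": age,
                "gender": gender,
                "grade": grade,
                "stage": stage,
                "T": t_cat,
                "N": n_cat,
                "M": m_cat,
            },
            index=pd.Index(tumor_ids, name="sample_id"),
        )
    )

    truth = TruthRecord(
        immune_lncrna_ids=list(immune_lnc),
        de_lncrna_ids=list(de_lnc),
        true_pairs=true_pairs,
        true_betas=list(betas),
        per_sample_true_rs=pd.Series(true_rs, index=tumor_ids, name="true_rs"),
    )
    logger.info(
        "generated cohort: %d tumor / %d normal samples, %d genes, %d true pairs",
        config.n_tumor, config.n_normal, n_genes, config.n_true_pairs,
    )
    return expr, annot, clin, list(immune_genes), truth


def write_cohort(config: GeneratorConfig, outdir) -> dict:
    """Generate a cohort and write the standard pipeline input files.

    Produces expression.tsv, annotation.gtf, clinical.tsv,
    immune_genes.txt and truth.json under ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, annot, clin, immune_genes, truth = generate_cohort(config)

    paths = {
        "expression": outdir / "expression.tsv",
        "gtf": outdir / "annotation.gtf",
        "clinical": outdir / "clinical.tsv",
        "immune_genes": outdir / "immune_genes.txt",
        "truth": outdir / "truth.json",
    }
    expr.to_tsv(paths["expression"])
    with open(paths["gtf"], "w") as fh:
        for i, gene in enumerate(expr.gene_ids):
            biotype = "protein_coding" if annot.classify(gene) == "mRNA" else "lncRNA"
            start = 1000 * i + 1
            fh.write(
                "chr1\tsynthetic\tgene\t{}\t{}\t.\t+\t.\t"
                'gene_id "{}"; gene_type "{}";\n'.format(start, start + 500, gene, biotype)
            )
    clin.to_tsv(paths["clinical"])
    paths["immune_genes"].write_text("\n".join(immune_genes) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "immune_lncrna_ids": truth.immune_lncrna_ids,
                "de_lncrna_ids": truth.de_lncrna_ids,
                "true_pairs": [list(p) for p in truth.true_pairs],
                "true_betas": truth.true_betas,
                "per_sample_true_rs": truth.per_sample_true_rs.to_dict(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return {k: str(v) for k, v in paths.items()}
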