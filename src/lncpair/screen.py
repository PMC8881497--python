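"""Immune-correlation screen and moderated-t differential expression.

Both computations run on log2(x + 1) values. The correlation screen keeps
lncRNAs whose Pearson r against at least one immune gene exceeds a signed
(default) or absolute threshold at the given p-value. Differential
expression uses empirical-Bayes variance shrinkage (moderated t) with a
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from lncpair.ingest import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationHit:
    lncrna_id: str
    best_partner: str
    r: float
    p: float


@dataclass
class DEResult:
    lncrna_id: str
    log2fc: float
    t_mod: float
    p: float
    fdr: float
    direction: str
    significant: bool


def pearson_correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the exact t-distribution transform."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pearson_screen(
    lnc: ExpressionMatrix,
    immune: ExpressionMatrix,
    r_threshold: float = 0.4,
    p_threshold: float = 0.001,
    mode: str = "signed",
) -> list[CorrelationHit]:
    """Select lncRNAs correlated with at least one immune gene.

    A lncRNA passes when any immune gene satisfies ``r > r_threshold``
    (``mode="signed"``, default) or ``|r| > r_threshold`` (``mode="absolute"``)
    together with ``p < p_threshold``. The reported partner is the immune
    gene maximizing the screened statistic. Constant-variance genes are
    skipped with a warning.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown correlation mode {mode!r}")
    if list(lnc.sample_ids) != list(immune.sample_ids):
        if set(lnc.sample_ids) != set(immune.sample_ids):
            raise ValueError("lncRNA and immune matrices cover different samples")
        immune = immune.subset_samples(lnc.sample_ids)
    n = lnc.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples for correlation, got {n}")

    L = lnc.log2_values().to_numpy()
    G = immune.log2_values().to_numpy()
    l_sd = L.std(axis=1)
    g_sd = G.std(axis=1)
    if (l_sd == 0).any():
        warnings.warn(
            f"{int((l_sd == 0).sum())} constant lncRNA(s) skipped in correlation screen",
            stacklevel=2,
        )
    if (g_sd == 0).any():
        warnings.warn(
            f"{int((g_sd == 0).sum())} constant immune gene(s) skipped in correlation screen",
            stacklevel=2,
        )
    g_ok = g_sd > 0
    if not g_ok.any():
        return []
    Gs = (G[g_ok] - G[g_ok].mean(axis=1, keepdims=True)) / g_sd[g_ok, None]
    immune_ids = np.asarray(immune.gene_ids)[g_ok]

    hits: list[CorrelationHit] = []
    for i, gene in enumerate(lnc.gene_ids):
        if l_sd[i] == 0:
            continue
        x = (L[i] - L[i].mean()) / l_sd[i]
        r = Gs @ x / n
        p = pearson_correlation_pvalues(r, n)
        score = r if mode == "signed" else np.abs(r)
        passing = (score > r_threshold) & (p < p_threshold)
        if passing.any():
            best = int(np.argmax(score))
            hits.append(
                CorrelationHit(
                    lncrna_id=gene,
                    best_partner=str(immune_ids[best]),
                    r=float(r[best]),
                    p=float(p[best]),
                )
            )
    logger.info("correlation screen: %d/%d lncRNAs pass", len(hits), len(lnc.gene_ids))
    return hits


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Estimate the prior df d0 and prior variance s0^2 for shrinkage.

    Moment-matching on log s^2: the scaled F-distribution of the sample
    variances implies E[log s^2] and Var[log s^2] in terms of digamma /
    trigamma functions of (d0/2, df/2), inverted here. Returns
    ``(inf, s0^2)`` when the observed spread is at or below the sampling
    noise floor, and ``(0, geometric mean)`` when fewer than two positive
    variances are available.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if (~ok).any():
        logger.info("%d zero-variance genes excluded from prior estimation", int((~ok).sum()))
    z = np.log(s2[ok])
    if z.size == 0:
        return 0.0, 1.0
    if z.size < 2:
        return 0.0, float(np.exp(z.mean()))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    evar0 = evar - float(special.polygamma(1, df / 2.0))
    if evar0 <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar0)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_t_de(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    lfc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    prior_df: float | None = None,
) -> list[DEResult]:
    """Tumor-vs-normal moderated-t tests on log2(x + 1) values.

    Per gene: logFC = tumor mean - normal mean; the pooled residual
    variance is shrunk toward an empirical-Bayes prior,
    ``s~^2 = (d0 s0^2 + d s^2) / (d0 + d)``, and the moderated t statistic
    is referenced to d0 + d degrees of freedom. ``prior_df`` overrides the
    estimated d0 (0 recovers the ordinary pooled t; inf pins every
    posterior variance at s0^2). A gene is flagged significant when
    ``|logFC| > lfc_threshold`` (strict) and ``fdr < fdr_threshold``.
    """
    if list(tumor.gene_ids) != list(normal.gene_ids):
        if set(tumor.gene_ids) != set(normal.gene_ids):
            raise ValueError("tumor and normal matrices cover different genes")
        normal = normal.subset_genes(tumor.gene_ids)
    n1, n2 = tumor.n_samples, normal.n_samples
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} tumor / {n2} normal")

    Xt = tumor.log2_values().to_numpy()
    Xn = normal.log2_values().to_numpy()
    m1 = Xt.mean(axis=1)
    m2 = Xn.mean(axis=1)
    logfc = m1 - m2
    d = n1 + n2 - 2
    ss = ((Xt - m1[:, None]) ** 2).sum(axis=1) + ((Xn - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    d0, s02 = fit_variance_prior(s2, d)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    c = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(s2_post) * c)
    t = np.where(np.isnan(t), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(np.isinf(t), 0.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]

    results = []
    for i, gene in enumerate(tumor.gene_ids):
        sig = bool((abs(logfc[i]) > lfc_threshold) and (fdr[i] < fdr_threshold))
        results.append(
            DEResult(
                lncrna_id=gene,
                log2fc=float(logfc[i]),
                t_mod=float(t[i]),
                p=float(p[i]),
                fdr=float(fdr[i]),
                direction="down" if logfc[i] < 0 else "up",
                significant=sig,
            )
        )
    logger.info(
        "differential expression: %d/%d genes significant",
        sum(r.significant for r in results),
        len(results),
    )
    return results


def de_gene_ids(results: list[DEResult]) -> list[str]:
    """Ids of genes passing the DE gates, in input order."""
    return [r.lncrna_id for r in results if r.significant]
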