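"""Downstream association statistics for the risk model.

Chi-square tests of risk group vs clinical categories, rank-based
comparisons of risk scores across clinical subgroups, Spearman/Wilcoxon
statistics against immune-infiltration matrices, and Wilcoxon comparisons
of checkpoint-gene expression and drug IC50 between risk groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lncpair.ingest import ClinicalTable, ExpressionMatrix
from lncpair.signature import RiskProfile

logger = logging.getLogger(__name__)

#: Checkpoint genes compared between risk groups, with alias resolution
#: (figure-legend symbols -> HGNC symbols).
DEFAULT_CHECKPOINT_GENES = (
    "CTLA4", "LAG3", "PDL1", "PD1", "TIGIT", "GAL9", "TIM-3", "PD1LG2",
)
DEFAULT_GENE_ALIASES = {
    "PDL1": ("PDL1", "CD274"),
    "PD1": ("PD1", "PDCD1"),
    "GAL9": ("GAL9", "LGALS9"),
    "TIM-3": ("TIM-3", "HAVCR2"),
    "PD1LG2": ("PD1LG2", "PDCD1LG2"),
}


@dataclass
class FeatureAssociation:
    feature: str
    test: str
    statistic: float
    p: float
    stars: str = "ns"
    direction: str | None = None
    flag: str | None = None


@dataclass
class InfiltrationAssociation:
    cell_type: str
    method: str
    spearman_rho: float
    p: float
    wilcoxon_p: float
    significant: bool


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration for combined n <= 20 without ties, otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    exact = len(combined) <= 20 and len(np.unique(combined)) == len(combined)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def _split_groups(profile: RiskProfile, values: pd.Series):
    """Values for high/low risk groups over the shared samples."""
    if profile.group is None:
        raise ValueError("risk profile has no group assignment")
    common = [s for s in profile.sample_ids if s in values.index]
    if not common:
        raise ValueError("no samples shared with the risk profile")
    g = profile.group[common]
    v = pd.to_numeric(values[common], errors="coerce")
    hi = v[(g == "high") & v.notna()]
    lo = v[(g == "low") & v.notna()]
    return hi.to_numpy(), lo.to_numpy()


def _feature_categories(clin: ClinicalTable, feature: str) -> pd.Series:
    """Categorical view of a clinical feature; numeric age is binned at 65."""
    if feature not in clin.data.columns:
        raise KeyError(f"feature {feature!r} not in clinical table")
    vals = clin.data[feature]
    if feature == "age" or (
        np.issubdtype(vals.dtype, np.number) and vals.nunique() > 5
    ):
        vals = pd.Series(
            np.where(pd.to_numeric(vals, errors="coerce") > 65, ">65", "<=65"),
            index=vals.index,
        )
    return vals.astype(str)


def clinical_association(
    profile: RiskProfile, clin: ClinicalTable, features=None
) -> list[FeatureAssociation]:
    """Chi-square tests of risk group x clinical category tables.

    Single-category features are skipped with a warning; tables with any
    expected count < 5 trigger a warning but are still tested.
    """
    if profile.group is None:
        raise ValueError("risk profile has no group assignment")
    if features is None:
        features = [
            c for c in ("event", "age", "gender", "grade", "stage", "T", "N", "M")
            if c in clin.data.columns
        ]
    common = [s for s in profile.sample_ids if s in set(clin.sample_ids)]
    sub = clin.subset(common)
    group = profile.group[common]

    out: list[FeatureAssociation] = []
    for feature in features:
        cats = _feature_categories(sub, feature).dropna()
        if cats.nunique() < 2:
            warnings.warn(f"feature {feature!r} has a single category; skipped",
                          stacklevel=2)
            continue
        table = pd.crosstab(group[cats.index], cats)
        if (stats.contingency.expected_freq(table.to_numpy()) < 5).any():
            warnings.warn(
                f"feature {feature!r}: expected count < 5 in chi-square table",
                stacklevel=2,
            )
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        out.append(
            FeatureAssociation(
                feature=feature,
                test="chi-square",
                statistic=float(chi2),
                p=float(p),
                stars=significance_stars(p),
            )
        )
    return out


def subgroup_rs_comparison(
    profile: RiskProfile, clin: ClinicalTable, feature: str
) -> FeatureAssociation:
    """Compare RS across the levels of one clinical feature.

    Two levels -> Wilcoxon rank-sum; three or more -> Kruskal-Wallis.
    """
    common = [s for s in profile.sample_ids if s in set(clin.sample_ids)]
    sub = clin.subset(common)
    cats = _feature_categories(sub, feature).dropna()
    rs = profile.rs[cats.index].to_numpy(dtype=float)
    levels = sorted(cats.unique())
    if len(levels) < 2:
        raise ValueError(f"feature {feature!r} has fewer than 2 levels")
    groups = [rs[(cats == lv).to_numpy()] for lv in levels]
    if np.ptp(rs) == 0:
        warnings.warn("all risk scores identical; comparison is degenerate",
                      stacklevel=2)
        return FeatureAssociation(feature=feature, test="degenerate",
                                  statistic=0.0, p=1.0)
    if len(levels) == 2:
        stat, p = rank_sum_test(groups[0], groups[1])
        test = "wilcoxon"
    else:
        stat, p = stats.kruskal(*groups)
        test = "kruskal-wallis"
    return FeatureAssociation(
        feature=feature, test=test, statistic=float(stat), p=float(p),
        stars=significance_stars(p),
    )


def infiltration_association(
    profile: RiskProfile, infiltration: pd.DataFrame
) -> list[InfiltrationAssociation]:
    """Spearman rho of each infiltration score vs RS, plus high/low Wilcoxon.

    ``infiltration`` is indexed by cell type with an optional ``method``
    column; remaining columns are per-sample scores. Rows significant at
    p < 0.05 (Spearman) are flagged. Constant rows are skipped.
    """
    method = infiltration["method"] if "method" in infiltration.columns else None
    scores = infiltration.drop(columns=["method"], errors="ignore")
    common = [s for s in profile.sample_ids if s in set(scores.columns)]
    if len(common) < 3:
        raise ValueError(f"need >= 3 overlapping samples, got {len(common)}")
    rs = profile.rs[common].to_numpy(dtype=float)

    out: list[InfiltrationAssociation] = []
    for cell in scores.index:
        v = scores.loc[cell, common].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"constant infiltration row {cell!r}; skipped", stacklevel=2)
            continue
        rho, p = stats.spearmanr(rs, v)
        if profile.group is not None:
            hi, lo = _split_groups(profile, scores.loc[cell])
            w_p = rank_sum_test(hi, lo)[1] if len(hi) and len(lo) else np.nan
        else:
            w_p = np.nan
        out.append(
            InfiltrationAssociation(
                cell_type=str(cell),
                method=str(method[cell]) if method is not None else "",
                spearman_rho=float(rho),
                p=float(p),
                wilcoxon_p=float(w_p),
                significant=bool(p < 0.05),
            )
        )
    return out


def expression_comparison(
    profile: RiskProfile,
    expr: ExpressionMatrix,
    genes=DEFAULT_CHECKPOINT_GENES,
    aliases=None,
) -> list[FeatureAssociation]:
    """Wilcoxon comparison of gene expression between high and low risk.

    Gene symbols resolve through the alias map; genes absent under every
    alias are reported via a warning and omitted from the output.
    ``direction`` is the sign of the high-minus-low median difference.
    """
    if aliases is None:
        aliases = DEFAULT_GENE_ALIASES
    available = set(expr.gene_ids)
    out: list[FeatureAssociation] = []
    missing = []
    for gene in genes:
        resolved = next(
            (a for a in aliases.get(gene, (gene,)) if a in available), None
        )
        if resolved is None:
            missing.append(gene)
            continue
        hi, lo = _split_groups(profile, expr.values.loc[resolved])
        stat, p = rank_sum_test(hi, lo)
        diff = float(np.median(hi) - np.median(lo))
        out.append(
            FeatureAssociation(
                feature=gene,
                test="wilcoxon",
                statistic=stat,
                p=float(p),
                stars=significance_stars(p),
                direction="up_in_high" if diff > 0 else ("up_in_low" if diff < 0 else "none"),
            )
        )
    if missing:
        warnings.warn(f"checkpoint gene(s) not found: {missing}", stacklevel=2)
    return out


def ic50_comparison(profile: RiskProfile, ic50: pd.DataFrame) -> list[FeatureAssociation]:
    """Wilcoxon comparison of per-drug IC50 between risk groups.

    The group with the lower median IC50 is flagged as more sensitive.
    """
    out: list[FeatureAssociation] = []
    for drug in ic50.index:
        hi, lo = _split_groups(profile, ic50.loc[drug])
        if len(hi) == 0 or len(lo) == 0:
            warnings.warn(f"drug {drug!r}: a risk group has no samples; skipped",
                          stacklevel=2)
            continue
        stat, p = rank_sum_test(hi, lo)
        diff = float(np.median(hi) - np.median(lo))
        if diff < 0:
            flag = "high-risk more sensitive"
        elif diff > 0:
            flag = "low-risk more sensitive"
        else:
            flag = "no difference"
        out.append(
            FeatureAssociation(
                feature=str(drug),
                test="wilcoxon",
                statistic=stat,
                p=float(p),
                stars=significance_stars(p),
                direction="up_in_high" if diff > 0 else ("up_in_low" if diff < 0 else "none"),
                flag=flag,
            )
        )
    return out
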