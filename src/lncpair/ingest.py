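"""Input parsing and validation.

Reads wide expression TSVs, GTF gene annotations and clinical tables;
separates lncRNA from mRNA genes; applies the sample-exclusion rules
(no clinical record, zero survival time).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

#: Gencode-dialect biotypes classified as lncRNA (configurable).
DEFAULT_LNCRNA_BIOTYPES = frozenset(
    {
        "lncRNA",
        "antisense",
        "lincRNA",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
    }
)

#: TCGA-style sample type codes used as a fallback for group inference.
_BARCODE_SUFFIX = re.compile(r"-(\d{2})[A-Z]?$")
_BARCODE_GROUPS = {"01": TUMOR, "11": NORMAL}

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')
_GENE_TYPE_RE = re.compile(r'gene_type "([^"]+)"')


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative FPKM-like values.

    ``values`` is indexed by gene id with sample-id columns;
    ``sample_group`` maps every sample id to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    sample_group: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if np.isnan(arr).any():
            gene = v.index[np.isnan(arr).any(axis=1)][0]
            raise ValueError(f"missing expression value for gene {gene!r}")
        if (arr < 0).any():
            gene = v.index[(arr < 0).any(axis=1)][0]
            raise ValueError(f"negative expression value for gene {gene!r}")
        groups = self.sample_group.reindex(v.columns)
        if groups.isna().any():
            missing = groups.index[groups.isna()][0]
            raise ValueError(f"sample {missing!r} has no group label")
        bad = set(groups.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"invalid sample group label(s): {sorted(bad)}")
        object.__setattr__(self, "sample_group", groups)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.sample_group)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.sample_group[ids])

    def tumor(self) -> "ExpressionMatrix":
        ids = self.sample_ids[self.sample_group[self.sample_ids] == TUMOR]
        return self.subset_samples(ids)

    def normal(self) -> "ExpressionMatrix":
        ids = self.sample_ids[self.sample_group[self.sample_ids] == NORMAL]
        return self.subset_samples(ids)

    def log2_values(self) -> pd.DataFrame:
        """log2(x + 1) transform used by all correlation/DE computations."""
        return np.log2(self.values + 1.0)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GeneAnnotation:
    """Gene id -> biotype class map; unknown ids resolve to ``"other"``."""

    classes: dict = field(default_factory=dict)

    def classify(self, gene_id: str) -> str:
        return self.classes.get(gene_id, "other")

    def __len__(self) -> int:
        return len(self.classes)


@dataclass
class ClinicalTable:
    """Per-sample survival and covariate table, indexed by sample id.

    Mandatory columns: ``time`` (days, > 0) and ``event`` (0/1).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        for col in ("time", "event"):
            if col not in d.columns:
                raise ValueError(f"clinical table missing mandatory column {col!r}")
        if d.index.duplicated().any():
            dup = d.index[d.index.duplicated()][0]
            raise ValueError(f"duplicate clinical sample id: {dup!r}")
        if (d["time"] <= 0).any() or d["time"].isna().any():
            raise ValueError("clinical table contains non-positive survival time")
        if not d["event"].isin([0, 1]).all():
            raise ValueError("clinical event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


def _infer_groups(sample_ids, group_map=None) -> pd.Series:
    """Assign tumor/normal labels from a sidecar map or barcode suffix."""
    if group_map is not None:
        if isinstance(group_map, (str, Path)):
            gm = pd.read_csv(group_map, sep="\t", index_col=0).iloc[:, 0]
            group_map = gm.to_dict()
        groups = pd.Series({s: group_map.get(s) for s in sample_ids})
        if groups.isna().any():
            missing = groups.index[groups.isna()][0]
            raise ValueError(f"sample {missing!r} absent from group map")
        return groups
    labels = {}
    for s in sample_ids:
        m = _BARCODE_SUFFIX.search(str(s))
        code = m.group(1) if m else None
        if code not in _BARCODE_GROUPS:
            raise ValueError(
                f"cannot infer tumor/normal group for sample {s!r}; "
                "provide an explicit group map"
            )
        labels[s] = _BARCODE_GROUPS[code]
    return pd.Series(labels)


def read_expression(path, group_map=None) -> ExpressionMatrix:
    """Parse a genes x samples TSV into an :class:`ExpressionMatrix`.

    Duplicate gene rows are collapsed by mean; duplicate sample columns and
    non-numeric or negative cells are errors. Groups come from ``group_map``
    (path or dict) when given, otherwise from TCGA-style barcode suffixes.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for s in header:
        if s in seen:
            raise ValueError(f"duplicate sample id in header: {s!r}")
        seen.add(s)

    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            gene = df.index[bad][0] if bad.any() else df.index[coerced.isna()][0]
            raise ValueError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}"
            )
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    groups = _infer_groups(df.columns, group_map)
    return ExpressionMatrix(df.astype(float), groups)


def read_gtf_biotypes(
    path, lncrna_biotypes=DEFAULT_LNCRNA_BIOTYPES
) -> GeneAnnotation:
    """Build a gene -> {mRNA, lncRNA, other} map from GTF gene_type attributes.

    Conflicting records for one gene resolve in favor of protein_coding
    (classified mRNA) with a warning; the result is independent of record
    order. Records without parseable attributes are skipped with a log entry.
    """
    biotypes: dict[str, set] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                n_skipped += 1
                logger.warning("skipping malformed GTF line %d", lineno)
                continue
            gid = _GENE_ID_RE.search(fields[8])
            gtype = _GENE_TYPE_RE.search(fields[8])
            if gid is None or gtype is None:
                n_skipped += 1
                logger.warning("skipping GTF line %d without gene_id/gene_type", lineno)
                continue
            biotypes.setdefault(gid.group(1), set()).add(gtype.group(1))
    if not biotypes:
        raise ValueError(f"no genes parsed from GTF {path!r}")
    if n_skipped:
        logger.warning("skipped %d unparseable GTF records", n_skipped)

    classes = {}
    for gene, types in biotypes.items():
        if "protein_coding" in types:
            if types & lncrna_biotypes:
                warnings.warn(
                    f"gene {gene!r} has both protein_coding and lncRNA records; "
                    "classified as mRNA",
                    stacklevel=2,
                )
            classes[gene] = "mRNA"
        elif types & lncrna_biotypes:
            classes[gene] = "lncRNA"
        else:
            classes[gene] = "other"
    return GeneAnnotation(classes)


def split_lncrna(
    expr: ExpressionMatrix, annot: GeneAnnotation
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition an expression matrix into (mRNA, lncRNA) sub-matrices.

    Genes classified ``other`` (including ids absent from the annotation)
    are dropped with a logged count.
    """
    coding, lnc, dropped = [], [], 0
    for gene in expr.gene_ids:
        cls = annot.classify(gene)
        if cls == "mRNA":
            coding.append(gene)
        elif cls == "lncRNA":
            lnc.append(gene)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d genes with non-mRNA/lncRNA biotype", dropped)
    if not lnc:
        raise ValueError("no lncRNA genes found after biotype split")
    return expr.subset_genes(coding), expr.subset_genes(lnc)


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV, dropping rows that violate the retention rules.

    Rows with missing sample id, time or event, non-positive survival time,
    or an event flag outside {0, 1} are removed (counts logged).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing mandatory column {col!r}")
    n_in = len(df)
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    keep = (
        df["sample_id"].notna()
        & df["time"].notna()
        & (df["time"] > 0)
        & df["event"].isin([0, 1])
    )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d/%d clinical rows failing retention rules", n_removed, n_in)
    df = df.loc[keep].set_index("sample_id")
    df["event"] = df["event"].astype(int)
    return ClinicalTable(df)


def read_immune_genes(path) -> list[str]:
    """Read an immune-gene list (one id per line, blank lines ignored)."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValueError(f"empty immune gene list {path!r}")
    return genes
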