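"""Binary rank-pair feature construction.

For every unordered pair (A, B) of input genes the feature value in a
sample is 1 iff expression(A) > expression(B) there (ties map to 0), so
the features depend only on within-sample expression ranks and are
invariant to any strictly monotone per-sample transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lncpair.ingest import ExpressionMatrix

logger = logging.getLogger(__name__)

PAIR_SEP = "|"


@dataclass
class PairMatrix:
    """Binary pair-indicator features: rows "A|B", columns samples."""

    indicators: pd.DataFrame
    members: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.indicators.index.duplicated().any():
            dup = self.indicators.index[self.indicators.index.duplicated()][0]
            raise ValueError(f"duplicate pair name: {dup!r}")
        arr = self.indicators.to_numpy()
        if arr.size and not np.isin(arr, [0, 1]).all():
            raise ValueError("pair indicators must be 0 or 1")
        if not self.members:
            self.members = {
                name: tuple(name.split(PAIR_SEP, 1)) for name in self.indicators.index
            }

    @property
    def pair_names(self) -> pd.Index:
        return self.indicators.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.indicators.columns

    @property
    def n_pairs(self) -> int:
        return len(self.indicators)

    @property
    def prevalence(self) -> pd.Series:
        """Fraction of samples with indicator 1, per pair."""
        return self.indicators.mean(axis=1)

    def subset_pairs(self, names) -> "PairMatrix":
        names = list(names)
        return PairMatrix(
            self.indicators.loc[names],
            {n: self.members[n] for n in names if n in self.members},
        )

    def subset_samples(self, sample_ids) -> "PairMatrix":
        return PairMatrix(self.indicators[list(sample_ids)], dict(self.members))

    def to_tsv(self, path) -> None:
        self.indicators.to_csv(path, sep="\t", index_label="pair")


def read_pair_matrix(path) -> PairMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairMatrix(df.astype(np.int8))


def build_pairs(lnc: ExpressionMatrix, tumor_only: bool = True) -> PairMatrix:
    """Emit all n(n-1)/2 unordered pair indicators over the input genes.

    Member order within each pair follows the input gene order; the
    indicator is 1 iff the first member's expression strictly exceeds the
    second's (ties -> 0). By default only tumor samples are used, matching
    the survival-modeling domain of the downstream fit.
    """
    expr = lnc.tumor() if tumor_only else lnc
    genes = list(expr.gene_ids)
    if len(genes) < 2:
        raise ValueError(f"need >= 2 lncRNAs to build pairs, got {len(genes)}")
    X = expr.values.to_numpy()
    ai, bi = np.triu_indices(len(genes), k=1)
    ind = (X[ai] > X[bi]).astype(np.int8)
    names = [f"{genes[i]}{PAIR_SEP}{genes[j]}" for i, j in zip(ai, bi)]
    members = {n: (genes[i], genes[j]) for n, i, j in zip(names, ai, bi)}
    df = pd.DataFrame(ind, index=pd.Index(names, name="pair"), columns=expr.sample_ids)
    logger.info("built %d candidate pairs from %d lncRNAs", len(names), len(genes))
    return PairMatrix(df, members)


def filter_effective(pairs: PairMatrix, min_minority_frac: float = 0.2) -> PairMatrix:
    """Keep pairs whose minority indicator value covers > min_minority_frac.

    Equivalently, prevalence must lie strictly inside
    (min_minority_frac, 1 - min_minority_frac); near-constant pairs carry
    no rank information and are dropped (count logged).
    """
    prev = pairs.prevalence
    minority = np.minimum(prev, 1.0 - prev)
    keep = pairs.pair_names[minority > min_minority_frac]
    n_dropped = pairs.n_pairs - len(keep)
    logger.info("effective-match filter: kept %d, dropped %d", len(keep), n_dropped)
    if len(keep) == 0:
        warnings.warn("no pairs survive the effective-match filter", stacklevel=2)
    return pairs.subset_pairs(keep)
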