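import numpy as np
import pandas as pd
import pytest

from lncpair.ingest import ClinicalTable, ExpressionMatrix
from lncpair.pairing import PairMatrix
from lncpair.signature import RiskProfile


def make_expr(values, gene_ids=None, sample_ids=None, groups=None):
    """Build an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(g)]
    sample_ids = sample_ids or [f"S{i}" for i in range(s)]
    if groups is None:
        groups = ["tumor"] * s
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        pd.Series(dict(zip(sample_ids, groups))),
    )


def make_clinical(time, event, sample_ids=None, **covariates):
    time = np.asarray(time, dtype=float)
    sample_ids = sample_ids or [f"S{i}" for i in range(len(time))]
    data = {"time": time, "event": np.asarray(event, dtype=int)}
    data.update(covariates)
    return ClinicalTable(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))


def make_pairs(indicators, pair_names=None, sample_ids=None):
    indicators = np.asarray(indicators, dtype=np.int8)
    p, s = indicators.shape
    pair_names = pair_names or [f"A{i}|B{i}" for i in range(p)]
    sample_ids = sample_ids or [f"S{i}" for i in range(s)]
    return PairMatrix(pd.DataFrame(indicators, index=pair_names, columns=sample_ids))


def make_profile(scores, sample_ids=None, group=None):
    scores = np.asarray(scores, dtype=float)
    sample_ids = sample_ids or [f"S{i}" for i in range(len(scores))]
    g = None
    if group is not None:
        g = pd.Series(list(group), index=sample_ids)
    return RiskProfile(rs=pd.Series(scores, index=sample_ids), group=g)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-config synthetic cohort shared across read-only tests."""
    from lncpair.simulate import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(n_tumor=150, n_normal=30, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
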