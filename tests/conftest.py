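import numpy as np
import pandas as pd
import pytest

from microgeo import SimConfig, simulate_community
from microgeo.consensus import set_qc_metrics
from microgeo.formats import CoverageTable


@pytest.fixture(scope="session")
def default_community():
    """One default synthetic community shared across read-only tests."""
    cfg = SimConfig(seed=11)
    coverage, pileup, meta, truth = simulate_community(cfg)
    return cfg, coverage, pileup, meta, truth


@pytest.fixture(scope="session")
def qc_consensus(default_community):
    """Consensus sequences of the shared community, QC flags attached."""
    from microgeo import call_consensus, qc_filter

    _, _, pileup, meta, _ = default_community
    cons = call_consensus(pileup)
    set_qc_metrics(cons, meta)
    qc_filter(cons)
    return cons


def make_coverage(values: np.ndarray, sample_ids=None, gene_ids=None,
                  sccg=None, nutrient=None, normalized=False) -> CoverageTable:
    """Small coverage-table builder for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j}" for j in range(p)]
    sccg = sccg if sccg is not None else [j == 0 for j in range(p)]
    nutrient = nutrient or ["none"] * p
    gm = pd.DataFrame({
        "is_sccg": sccg,
        "nutrient_group": nutrient,
        "cog_category": ["unknown"] * p,
    }, index=pd.Index(gene_ids, name="gene_id"))
    vals = pd.DataFrame(values, index=sample_ids, columns=gene_ids)
    return CoverageTable(values=vals, gene_meta=gm, normalized=normalized)
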