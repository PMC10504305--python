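"""Genomic nutrient-stress indicator (Ω) from gene coverage tables.

Gene coverage is first normalized by each sample's mean single-copy
core-gene (SCCG) coverage, which roughly estimates gene copies per genome.
Each gene is then z-scored across samples, and Ω for a nutrient type
(P, N, Fe) is the mean z-score over that type's acquisition-gene set.
By construction each Ω column has zero mean over the sample set used for
standardization, and Ω is exactly invariant to per-sample sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import CoverageTable, ValidationError
from .synthdata import DEFAULT_GENE_GROUPS

logger = logging.getLogger(__name__)


def normalize_by_sccg(t: CoverageTable) -> CoverageTable:
    """Divide every gene's coverage by the sample's mean SCCG coverage."""
    if t.normalized:
        raise ValidationError("coverage table is already normalized")
    sccg = t.sccg_genes
    if not sccg:
        raise ValidationError("no SCCG genes present")
    mean_sccg = t.values[sccg].mean(axis=1)
    zero = mean_sccg[mean_sccg <= 0]
    if len(zero):
        raise ValidationError(
            f"sample {zero.index[0]!r} has zero mean SCCG coverage"
        )
    values = t.values.div(mean_sccg, axis=0)
    return CoverageTable(values=values, gene_meta=t.gene_meta.copy(),
                         normalized=True)


def zscore_genes(t: CoverageTable) -> pd.DataFrame:
    """Per-gene z-scores across samples (sample sd, n-1 denominator).

    Genes with zero variance get an all-zero column and a warning.
    """
    if not t.normalized:
        raise ValidationError("zscore_genes expects an SCCG-normalized table")
    if len(t.samples) < 2:
        raise ValidationError("z-scoring needs >=2 samples")
    x = t.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant gene(s) z-scored to 0: %s",
                       int(constant.sum()),
                       ", ".join(map(str, x.columns[constant][:5])))
    sd_safe = sd.where(~constant, 1.0)
    z = (x - mean) / sd_safe
    z.loc[:, constant] = 0.0
    return z


@dataclass
class OmegaTable:
    omega: pd.DataFrame                  # samples x groups
    gene_lists: dict[str, list[str]]     # group -> genes actually used
    n_genes_used: dict[str, int]

    @property
    def samples(self) -> list[str]:
        return list(self.omega.index)


def compute_omega(z: pd.DataFrame,
                  groups: dict[str, list[str]] | None = None,
                  gene_meta: pd.DataFrame | None = None) -> OmegaTable:
    """Average z-scores over each nutrient type's gene set.

    ``groups`` defaults to the nutrient_group assignments in ``gene_meta``
    when given, else to the canonical acquisition-gene lists. Genes missing
    from the z table are skipped with a log message; a group resolving to
    zero genes is an error.
    """
    if groups is None:
        if gene_meta is not None:
            groups = {
                g: list(gene_meta.index[gene_meta["nutrient_group"] == g])
                for g in ("P", "N", "Fe")
            }
        else:
            groups = {g: list(v) for g, v in DEFAULT_GENE_GROUPS.items()}
    omega = {}
    gene_lists: dict[str, list[str]] = {}
    for group, genes in groups.items():
        present = [g for g in genes if g in z.columns]
        missing = sorted(set(genes) - set(present))
        if missing:
            logger.info("omega %s: skipping %d absent gene(s): %s",
                        group, len(missing), ", ".join(missing[:5]))
        if not present:
            raise ValidationError(f"nutrient group {group!r} resolves to zero genes")
        omega[group] = z[present].mean(axis=1)
        gene_lists[group] = present
    table = pd.DataFrame(omega)
    return OmegaTable(omega=table, gene_lists=gene_lists,
                      n_genes_used={g: len(v) for g, v in gene_lists.items()})


def omega_from_coverage(t: CoverageTable,
                        groups: dict[str, list[str]] | None = None,
                        use_gene_meta: bool = True) -> OmegaTable:
    """Full route: SCCG normalization -> z-scores -> group means."""
    norm = normalize_by_sccg(t) if not t.normalized else t
    z = zscore_genes(norm)
    meta = norm.gene_meta if (use_gene_meta and groups is None) else None
    return compute_omega(z, groups=groups, gene_meta=meta)
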