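"""PCA of flexible-genome content with environmental vector fitting.

The samples x genes matrix of SCCG-normalized coverage is z-scored per gene
(correlation-matrix PCA) and decomposed by SVD. Loadings are orthonormal
eigenvectors with a deterministic sign convention (each component's
largest-magnitude loading is positive). Environmental variables are fitted
post hoc as arrows in a chosen two-component plane with permutation
significance, mirroring vegan's envfit; nutrient-gene eigenvectors are
summarized per nutrient type by mean magnitude and circular-mean angle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import CoverageTable, ValidationError
from .omega import zscore_genes

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame         # samples x components
    loadings: pd.DataFrame       # genes x components, orthonormal columns
    var_explained: np.ndarray    # fraction per retained component
    component_count: int
    input_gene_ids: list[str]

    def plane(self, pc_a: int, pc_b: int) -> np.ndarray:
        """Score columns for two 1-based component indices, as (n, 2)."""
        for pc in (pc_a, pc_b):
            if not 1 <= pc <= self.component_count:
                raise ValidationError(f"component {pc} not retained")
        return self.scores.iloc[:, [pc_a - 1, pc_b - 1]].to_numpy()


def genomic_pca(t: CoverageTable, exclude_sccg: bool = True,
                n_components: int | None = None) -> OrdinationResult:
    """Correlation-matrix PCA of (flexible) gene content via SVD."""
    if len(t.samples) < 3:
        raise ValidationError("PCA needs >=3 samples")
    if exclude_sccg:
        keep = [g for g in t.genes if not t.gene_meta.loc[g, "is_sccg"]]
        t = CoverageTable(values=t.values[keep], gene_meta=t.gene_meta.loc[keep],
                          normalized=t.normalized)
    z = zscore_genes(t)
    x = z.to_numpy(dtype=float)
    n, p = x.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    elif n_components > max_comp:
        logger.warning("clamping n_components from %d to %d", n_components, max_comp)
        n_components = max_comp
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s ** 2
    var_explained = (eigvals / eigvals.sum())[:n_components]
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention: the largest-|loading| entry of each component positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(u * s, index=z.index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=z.columns, columns=comp_names)
    return OrdinationResult(scores=scores, loadings=loadings,
                            var_explained=var_explained,
                            component_count=n_components,
                            input_gene_ids=list(z.columns))


def top_loadings(o: OrdinationResult, pc: int, n: int = 100,
                 gene_meta: pd.DataFrame | None = None
                 ) -> tuple[list[str], dict[str, int] | None]:
    """Genes ranked by |loading| on one component, plus COG counts of the top n.

    Ties in |loading| are broken by gene_id; n is clamped to the gene count.
    """
    if not 1 <= pc <= o.component_count:
        raise ValidationError(f"component {pc} not retained")
    col = o.loadings.iloc[:, pc - 1]
    if n > len(col):
        logger.warning("n=%d exceeds %d genes; clamping", n, len(col))
        n = len(col)
    order = sorted(col.index, key=lambda g: (-abs(col[g]), str(g)))
    top = order[:n]
    cog_counts = None
    if gene_meta is not None:
        cogs = gene_meta.loc[top, "cog_category"]
        cog_counts = cogs.value_counts().to_dict()
    return top, cog_counts


@dataclass
class EnvArrow:
    variable_name: str
    direction: np.ndarray   # unit vector in the chosen plane
    r_squared: float
    p_value: float
    n_perm: int


def envfit(o: OrdinationResult, env, plane: tuple[int, int] = (1, 2),
           n_perm: int = 999, seed: int | None = None,
           variable_name: str = "env") -> EnvArrow:
    """Fit an environmental variable as an arrow in a two-component plane.

    The variable is regressed on the two score columns; the arrow is the
    normalized coefficient vector, r_squared the OLS R², and the p-value the
    permutation fraction (1 + #{permuted R² >= observed}) / (n_perm + 1).
    """
    env = np.asarray(env, dtype=float)
    if np.ptp(env) == 0:
        raise ValidationError("environmental variable is constant")
    xy = o.plane(*plane)
    if len(env) != len(xy):
        raise ValidationError("env length does not match sample count")
    X = np.column_stack([np.ones(len(env)), xy])
    # hat matrix lets every permutation reuse one factorization
    H = X @ np.linalg.pinv(X)

    def r2(y: np.ndarray) -> float:
        yc = y - y.mean()
        denom = float(yc @ yc)
        fitted = H @ y
        fc = fitted - fitted.mean()
        return float(fc @ fc) / denom

    obs = r2(env)
    coef, *_ = np.linalg.lstsq(X, env, rcond=None)
    beta = coef[1:]
    norm = np.linalg.norm(beta)
    direction = beta / norm if norm > 0 else beta
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r2(rng.permutation(env)) >= obs - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return EnvArrow(variable_name=variable_name, direction=direction,
                    r_squared=obs, p_value=p, n_perm=n_perm)


@dataclass
class NutrientVector:
    group: str
    mean_angle: float        # radians, circular mean in the plane
    mean_magnitude: float
    n_genes: int


def nutrient_vectors(o: OrdinationResult, gene_meta: pd.DataFrame,
                     plane: tuple[int, int] = (1, 2)) -> dict[str, NutrientVector]:
    """Average loading vectors per nutrient group in a two-component plane.

    Magnitude is the mean Euclidean norm of each gene's (loading_a, loading_b);
    the angle is the circular mean of the genes' atan2 angles. Groups with no
    genes among the ordination inputs are omitted with a warning.
    """
    pc_a, pc_b = plane
    for pc in plane:
        if not 1 <= pc <= o.component_count:
            raise ValidationError(f"component {pc} not retained")
    out: dict[str, NutrientVector] = {}
    for group in ("P", "N", "Fe"):
        genes = [g for g in gene_meta.index
                 if gene_meta.loc[g, "nutrient_group"] == group
                 and g in o.loadings.index]
        if not genes:
            logger.warning("nutrient group %s: no genes in ordination; omitted",
                           group)
            continue
        vecs = o.loadings.loc[genes].iloc[:, [pc_a - 1, pc_b - 1]].to_numpy()
        norms = np.linalg.norm(vecs, axis=1)
        angles = np.arctan2(vecs[:, 1], vecs[:, 0])
        mean_angle = math.atan2(np.sin(angles).mean(), np.cos(angles).mean())
        out[group] = NutrientVector(group=group, mean_angle=mean_angle,
                                    mean_magnitude=float(norms.mean()),
                                    n_genes=len(genes))
    return out
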