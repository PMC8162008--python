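"""Population-structure adjustment of expression.

The diversity panel has strong subpopulation structure; marker collinearity
with expression clusters would inflate heritability if left in place. The
remedy used here: PCA of the column-centered dosage matrix, then, for every
gene, ordinary least squares of expression on the top-k principal components
fitted separately within each condition x replicate stratum, keeping the
residuals as adjusted expression. Masked cells never enter the fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger("expherit")


@dataclass
class PCAResult:
    genotype_ids: list[str]
    components: np.ndarray  # genotypes x k score matrix
    variance_explained: np.ndarray  # k proportions of total variance
    all_variance_explained: np.ndarray  # proportions for every component

    def scores_for(self, genotype_id: str) -> np.ndarray:
        return self.components[self.genotype_ids.index(genotype_id)]


def genotype_pca(geno: GenotypeMatrix, k: int) -> PCAResult:
    """PCA of the mean-centered (not variance-scaled) dosage matrix.

    Sign convention: within each component the score of largest magnitude is
    positive, so results are reproducible across LAPACK builds.
    """
    n, m = geno.n_genotypes, geno.n_markers
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n_genotypes-1, n_markers)")
    X = geno.dosages - geno.dosages.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ValueError("constant dosage matrix: no genetic variance to decompose")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    share = var / var.sum()
    scores = U[:, :k] * s[:k]
    for j in range(k):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] = -scores[:, j]
    return PCAResult(list(geno.genotype_ids), scores, share[:k], share)


def residualize_expression(
    expr: ExpressionMatrix, pca: PCAResult, k: int = 3
) -> ExpressionMatrix:
    """Replace expression with per-stratum OLS residuals on PC1..PCk.

    Strata are condition x replicate. A stratum with fewer than k + 2
    unmasked samples for a gene cannot support the fit; its cells are marked
    missing with a warning (such genes fail the downstream missingness
    filter regardless).
    """
    if k > pca.components.shape[1]:
        raise ValueError(f"k={k} exceeds available components {pca.components.shape[1]}")
    scores = {g: pca.components[i, :k] for i, g in enumerate(pca.genotype_ids)}
    for s in expr.samples:
        if s.genotype_id not in scores:
            raise KeyError(f"genotype {s.genotype_id!r} has no PC scores")

    values = expr.values.copy()
    mask = expr.missing_mask.copy()
    n_undefined = 0
    for cond in expr.conditions:
        for rep in expr.replicates:
            cols = expr.sample_columns(condition=cond, replicate=rep)
            if cols.size == 0:
                continue
            X = np.column_stack(
                [np.ones(cols.size)]
                + [np.array([scores[expr.samples[j].genotype_id][c] for j in cols]) for c in range(k)]
            )
            Y = values[:, cols]
            M = mask[:, cols]
            complete = ~M.any(axis=1)
            if complete.any():
                beta, *_ = np.linalg.lstsq(X, Y[complete].T, rcond=None)
                values[np.ix_(complete, cols)] = (Y[complete].T - X @ beta).T
            for gi in np.nonzero(~complete)[0]:
                obs = ~M[gi]
                if obs.sum() < k + 2:
                    mask[gi, cols] = True
                    n_undefined += 1
                    continue
                beta, *_ = np.linalg.lstsq(X[obs], Y[gi, obs], rcond=None)
                values[gi, cols[obs]] = Y[gi, obs] - X[obs] @ beta
    if n_undefined:
        logger.warning(
            "structure adjustment: %d gene-stratum fits had < k+2 unmasked samples; "
            "marked missing", n_undefined,
        )
    values[mask] = 0.0
    return ExpressionMatrix(list(expr.gene_ids), list(expr.samples), values, mask)
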