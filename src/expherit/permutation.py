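"""Permutation null for heritability and condition-specific classification.

Shuffling expression values breaks the association between phenotype and
kinship, so single-step GREML on shuffled vectors yields the null h2
distribution; its empirical (1 - alpha) quantile is the significance
threshold applied to every gene (one pooled null, one threshold). A gene is
then 'general' if significant in both conditions, condition-specific if in
exactly one, otherwise not heritable.

The default shuffle permutes genotype labels with replicate pairs kept
intact: this nulls the genotype-kinship association (the hypothesis GREML
tests) without destroying the replicate error structure. Shuffling all
samples independently — a stricter null that also destroys within-genotype
correlation — is available via permute_mode="samples".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import GRM
from .greml import DegenerateGeneError, SpectralREML, heritability_gene_filter
from .io import ExpressionMatrix

logger = logging.getLogger("expherit")


@dataclass
class NullDistribution:
    values: np.ndarray
    n_iterations: int
    alpha: float
    threshold: float

    @classmethod
    def from_values(cls, values: np.ndarray, alpha: float) -> "NullDistribution":
        values = np.asarray(values, dtype=float)
        # empirical quantile, linear (type-7) interpolation
        thr = float(np.quantile(values, 1.0 - alpha))
        return cls(values, len(values), alpha, thr)


def build_null(
    expr: ExpressionMatrix,
    grm: GRM,
    n_iterations: int = 40_000,
    alpha: float = 0.01,
    seed: int | None = None,
    condition: str | None = None,
    permute_mode: str = "genotype",
    max_missing: float = 0.05,
) -> NullDistribution:
    """Null h2 distribution from shuffled expression.

    Each iteration draws one gene uniformly at random (with replacement),
    shuffles its expression, and re-estimates single-step GREML h2.
    ``condition=None`` draws the condition at random each iteration too.
    """
    if seed is None:
        raise ValueError("a seed is required: the null must be reproducible")
    if n_iterations < 1000:
        logger.warning(
            "n_iterations=%d < 1000: the %.3g quantile will be unstable",
            n_iterations, 1 - alpha,
        )
    if permute_mode not in ("genotype", "samples"):
        raise ValueError(f"unknown permute_mode {permute_mode!r}")
    rng = np.random.default_rng(seed)
    genes = heritability_gene_filter(expr, max_missing)
    if not genes:
        raise ValueError("no genes pass the missingness filter")
    conditions = [condition] if condition is not None else list(expr.conditions)

    gid_of = {g: i for i, g in enumerate(grm.genotype_ids)}
    # per (gene, condition): genotype-major observation layout + workspace
    layouts: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, SpectralREML]] = {}
    ws_cache: dict[tuple, SpectralREML] = {}

    def layout(gene: str, cond: str):
        key = (gene, cond)
        if key in layouts:
            return layouts[key]
        i = expr.gene_index(gene)
        cols = expr.sample_columns(condition=cond)
        by_geno: dict[str, list[float]] = {}
        for j in cols:
            if expr.missing_mask[i, j]:
                continue
            by_geno.setdefault(expr.samples[j].genotype_id, []).append(expr.values[i, j])
        gs = sorted(by_geno)
        y = np.concatenate([np.asarray(by_geno[g]) for g in gs])
        counts = tuple(len(by_geno[g]) for g in gs)
        gidx = np.repeat([gid_of[g] for g in gs], counts)
        wkey = (cond, tuple(gs), counts)
        if wkey not in ws_cache:
            ws_cache[wkey] = SpectralREML(grm.K, gidx)
        layouts[key] = (y, np.asarray(counts), ws_cache[wkey])
        return layouts[key]

    vals = np.empty(n_iterations)
    for it in range(n_iterations):
        gene = genes[int(rng.integers(len(genes)))]
        cond = conditions[int(rng.integers(len(conditions)))]
        y, counts, ws = layout(gene, cond)
        if permute_mode == "samples":
            y_perm = rng.permutation(y)
        else:
            # permute genotype blocks, replicate pairs kept intact
            splits = np.cumsum(counts)[:-1]
            blocks = np.split(y, splits)
            order = rng.permutation(len(blocks))
            y_perm = np.concatenate([blocks[k] for k in order])
        try:
            fit = ws.fit(y_perm)
            vals[it] = fit.h2
        except DegenerateGeneError:
            vals[it] = 0.0
    return NullDistribution.from_values(vals, alpha)


HERITABILITY_CLASSES = ("general", "control_specific", "salt_specific", "not_heritable")


def classify_heritability(
    h2_control: pd.Series | dict,
    h2_salt: pd.Series | dict,
    null: NullDistribution,
) -> pd.DataFrame:
    """Per-gene significance class from the pooled permutation threshold.

    Significance is strict (h2 > threshold). Genes with an estimate in only
    one condition are flagged unclassifiable rather than silently dropped.
    """
    hc = pd.Series(h2_control, dtype=float)
    hs = pd.Series(h2_salt, dtype=float)
    genes = sorted(set(hc.index) | set(hs.index))
    rows = []
    for g in genes:
        c = hc.get(g, np.nan)
        s = hs.get(g, np.nan)
        if np.isnan(c) or np.isnan(s):
            rows.append({"gene_id": g, "h2_control": c, "h2_salt": s,
                         "heritability_class": "unclassifiable"})
            continue
        sig_c = c > null.threshold
        sig_s = s > null.threshold
        if sig_c and sig_s:
            cls = "general"
        elif sig_c:
            cls = "control_specific"
        elif sig_s:
            cls = "salt_specific"
        else:
            cls = "not_heritable"
        rows.append({"gene_id": g, "h2_control": c, "h2_salt": s,
                     "heritability_class": cls})
    return pd.DataFrame(rows)
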