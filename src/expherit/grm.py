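"""Minor-allele-frequency filtering and genomic relationship matrix (GRM).

The GRM K is VanRaden's first method: with dosage matrix M (genotypes x
markers) and per-marker alt-allele frequency p,

    W = M - 2p,    K = W W' / (2 * sum_j p_j (1 - p_j)).

K is symmetrised and its (numerically) negative eigenvalues clipped at zero,
because the spectral REML solver downstream requires K to be positive
semidefinite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

PSD_TOL = 1e-8


@dataclass
class GRM:
    genotype_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.genotype_ids)
        if self.K.shape != (n, n):
            raise ValueError("K shape does not match genotype_ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.K, index=self.genotype_ids, columns=self.genotype_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "GRM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float))


def maf_filter(geno: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop markers whose minor-allele frequency is below min_maf (strict <)."""
    p = geno.allele_freq
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= min_maf
    if not keep.any():
        raise ValueError(f"no markers left after MAF >= {min_maf} filter")
    return GenotypeMatrix(
        list(geno.genotype_ids),
        geno.markers.loc[keep].reset_index(drop=True),
        geno.dosages[:, keep],
    )


def compute_grm(geno: GenotypeMatrix) -> GRM:
    p = geno.allele_freq
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM denominator is zero")
    W = geno.dosages - 2.0 * p
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    w, V = np.linalg.eigh(K)
    if w.min() < -PSD_TOL * max(1.0, w.max()):
        # WW'/c is PSD in exact arithmetic; anything beyond roundoff is a bug
        raise ValueError(f"GRM unexpectedly indefinite (min eig {w.min():.3g})")
    if w.min() < 0:
        K = (V * np.clip(w, 0.0, None)) @ V.T
        K = (K + K.T) / 2.0
    return GRM(list(geno.genotype_ids), K)
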