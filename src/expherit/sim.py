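"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the study system — an inbred rice diversity panel of
84 accessions in five subpopulations, assayed by RNA-seq under control and
salt conditions with two biological replicates — at a scale a laptop can
analyse:

* genotypes: Balding-Nichols drift. Each marker has an ancestral frequency
  p ~ Uniform(0.1, 0.9); each subpopulation draws its own frequency from
  Beta(p(1-F)/F, (1-p)(1-F)/F) with F the divergence parameter, and inbred
  dosages are Binomial(2, p_subpop). This reproduces PCA-separable
  subpopulations without simulating demography.
* expression: per gene and condition, genetic values u ~ N(0, sg2 K) with K
  the VanRaden GRM of the simulated markers, plus independent replicate
  noise; sg2/(sg2+se2) is set to the gene's target h2 with se =
  replicate_sd. Zero-inflation overwrites the latent values: constitutive
  genes have ~0.3% zero probability, repressed ~99.5%, mixed uniform
  between, reproducing the bimodal presence/absence pattern of the real
  matrix with margin enough that realized missingness stays in each class's
  defining band even at a few dozen samples per condition.
* geography: repressed genes concentrate in a central pericentromeric
  interval per chromosome, constitutive genes avoid it, and planted hotspot
  intervals carry genes heritable only under salt (h2 pairs like 0/0.6).
* tracks: an A/B-compartment-like eigenvector equal to the standardised
  constitutive-gene density per fixed bin plus Gaussian noise (positive = A).

What it deliberately does not emulate: read counts and library-size effects,
isoform structure, linkage disequilibrium beyond subpopulation drift, and
cis/trans eQTL architecture — the analysis consumes only K-level signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import grm as grm_mod
from .io import (
    ExpressionMatrix,
    GeneCatalog,
    GenomicTrack,
    GenotypeMatrix,
    SampleKey,
    write_expression,
    write_gene_catalog,
    write_genotypes,
    write_track,
)

CLASS_NAMES = ("constitutive", "mixed", "repressed")


@dataclass
class SimulationSpec:
    """Knobs of the generator; defaults mirror the study design."""

    n_genotypes: int = 84
    n_subpops: int = 5
    n_markers: int = 2000
    n_chromosomes: int = 4
    chromosome_length_bp: int = 30_000_000
    subpop_divergence: float = 0.2
    n_genes: int = 3000
    # constitutive/mixed/repressed fractions; ~ the observed genome-wide mix
    class_fractions: tuple[float, float, float] = (0.30, 0.47, 0.23)
    h2_grid: tuple[float, ...] = (0.0, 0.2, 0.5, 0.8)
    hotspot_spec: tuple[tuple[str, int, int, int], ...] = (
        ("Chr1", 10_000_001, 11_500_000, 17),
    )
    hotspot_h2: tuple[float, float] = (0.0, 0.6)  # (control, salt)
    replicate_sd: float = 1.0
    eigenvector_noise_sd: float = 0.5
    pericentromere_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.subpop_divergence < 1.0):
            raise ValueError("subpop_divergence must lie in (0, 1)")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(not (0.0 <= h < 1.0) for h in self.h2_grid):
            raise ValueError("all heritabilities must lie in [0, 1)")
        if not all(0.0 <= h < 1.0 for h in self.hotspot_h2):
            raise ValueError("hotspot heritabilities must lie in [0, 1)")
        for chrom, start, end, _n in self.hotspot_spec:
            if not self._valid_chrom(chrom) or start < 1 or end > self.chromosome_length_bp:
                raise ValueError(f"hotspot {chrom}:{start}-{end} outside simulated genome")

    def _valid_chrom(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    @property
    def chromosomes(self) -> list[str]:
        return [f"Chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length_bp for c in self.chromosomes}

    def pericentromere(self, chrom: str) -> tuple[int, int]:
        L = self.chromosome_length_bp
        half = self.pericentromere_fraction / 2.0
        return int(L * (0.5 - half)) + 1, int(L * (0.5 + half))


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, stream]))


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Balding-Nichols subpopulation-structured inbred dosages."""
    rng = _rng(spec.seed, 1)
    F = spec.subpop_divergence
    p_anc = rng.uniform(0.1, 0.9, size=spec.n_markers)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    p_sub = rng.beta(a, b, size=(spec.n_subpops, spec.n_markers))

    # near-equal subpopulation blocks
    sizes = np.full(spec.n_subpops, spec.n_genotypes // spec.n_subpops)
    sizes[: spec.n_genotypes % spec.n_subpops] += 1
    subpop_of = np.repeat(np.arange(spec.n_subpops), sizes)
    dos = rng.binomial(2, p_sub[subpop_of]).astype(float)

    chrom = rng.integers(0, spec.n_chromosomes, size=spec.n_markers)
    pos = rng.integers(1, spec.chromosome_length_bp + 1, size=spec.n_markers)
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i:05d}" for i in range(spec.n_markers)],
            "chromosome": [spec.chromosomes[c] for c in chrom],
            "position_bp": pos,
        }
    )
    order = markers.sort_values(["chromosome", "position_bp"], kind="stable").index.to_numpy()
    markers = markers.loc[order].reset_index(drop=True)
    ids = [f"G{i + 1:03d}" for i in range(spec.n_genotypes)]
    return GenotypeMatrix(ids, markers, dos[:, order])


# ---------------------------------------------------------------------------
# gene plan (classes, heritabilities, positions) — shared by catalog and
# expression so each can be generated independently yet consistently


def _gene_plan(spec: SimulationSpec) -> pd.DataFrame:
    rng = _rng(spec.seed, 2)
    n_hot = sum(h[3] for h in spec.hotspot_spec)
    if n_hot > spec.n_genes:
        raise ValueError("hotspot genes exceed n_genes")
    n_rest = spec.n_genes - n_hot

    counts = np.floor(np.asarray(spec.class_fractions) * n_rest).astype(int)
    counts[0] += n_rest - counts.sum()
    classes = np.repeat(np.arange(3), counts)
    rng.shuffle(classes)

    rows = []
    gi = 0
    for chrom, start, end, n in spec.hotspot_spec:
        for _ in range(n):
            pos = int(rng.integers(start, end + 1))
            rows.append((f"g{gi:05d}", "constitutive", chrom, pos,
                         spec.hotspot_h2[0], spec.hotspot_h2[1], True))
            gi += 1
    for c in classes:
        cls = CLASS_NAMES[c]
        chrom = spec.chromosomes[int(rng.integers(spec.n_chromosomes))]
        lo_p, hi_p = spec.pericentromere(chrom)
        L = spec.chromosome_length_bp
        if cls == "repressed" and rng.random() < 0.8:
            pos = int(rng.integers(lo_p, hi_p + 1))
        else:
            # constitutive genes mostly avoid the pericentromere
            while True:
                pos = int(rng.integers(1, L + 1))
                if cls != "constitutive" or not (lo_p <= pos <= hi_p) or rng.random() < 0.2:
                    break
        if cls == "constitutive":
            h2 = float(spec.h2_grid[int(rng.integers(len(spec.h2_grid)))])
        else:
            h2 = 0.0
        rows.append((f"g{gi:05d}", cls, chrom, pos, h2, h2, False))
        gi += 1
    plan = pd.DataFrame(
        rows,
        columns=["gene_id", "gene_class", "chromosome", "midpoint",
                 "h2_control", "h2_salt", "hotspot"],
    )
    # per-gene presence/abundance parameters
    n = len(plan)
    mu = np.where(
        plan["gene_class"] == "constitutive", rng.normal(4.0, 1.0, n),
        np.where(plan["gene_class"] == "mixed", rng.normal(-2.0, 0.7, n),
                 rng.normal(-3.0, 0.7, n)),
    )
    p0 = np.where(
        plan["gene_class"] == "constitutive", 0.003,
        np.where(plan["gene_class"] == "mixed", rng.uniform(0.15, 0.85, n), 0.995),
    )
    plan["mu"] = mu
    plan["p_zero"] = p0
    return plan


def gene_truth(spec: SimulationSpec) -> pd.DataFrame:
    """The per-gene ground truth (class, h2 per condition, hotspot flag)
    implied by a spec, without simulating the expression matrix. Identical
    to the truth table simulate_expression returns for the same spec."""
    plan = _gene_plan(spec)
    truth = plan[
        ["gene_id", "gene_class", "chromosome", "midpoint",
         "h2_control", "h2_salt", "hotspot"]
    ].copy()
    truth["class_control"] = truth["gene_class"]
    truth["class_salt"] = truth["gene_class"]
    return truth


def simulate_gene_catalog(spec: SimulationSpec, gene_length_bp: int = 3000) -> GeneCatalog:
    """Gene coordinates consistent with the plan used by simulate_expression."""
    plan = _gene_plan(spec)
    half = gene_length_bp // 2
    start = np.maximum(plan["midpoint"].to_numpy() - half, 1)
    end = np.minimum(start + gene_length_bp - 1, spec.chromosome_length_bp)
    table = pd.DataFrame(
        {
            "gene_id": plan["gene_id"],
            "chromosome": plan["chromosome"],
            "start_bp": start.astype(int),
            "end_bp": end.astype(int),
            "strand": "+",
        }
    ).sort_values(["chromosome", "start_bp"], kind="stable").reset_index(drop=True)
    return GeneCatalog(table, chrom_lengths=spec.chrom_lengths)


# ---------------------------------------------------------------------------
# expression


def _k_sqrt(K: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(K)
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_gene_values(
    Ksqrt: np.ndarray, h2: float, n_rep: int, rng: np.random.Generator,
    sigma_e: float = 1.0, mu: float = 0.0,
) -> np.ndarray:
    """One gene's genotype x replicate values under the GREML model."""
    n = Ksqrt.shape[0]
    if not (0.0 <= h2 < 1.0):
        raise ValueError("target h2 must lie in [0, 1)")
    sg = sigma_e * np.sqrt(h2 / (1.0 - h2))
    u = Ksqrt @ rng.standard_normal(n) * sg
    eps = rng.standard_normal((n, n_rep)) * sigma_e
    return mu + u[:, None] + eps


def simulate_expression(
    geno: GenotypeMatrix, catalog: GeneCatalog, spec: SimulationSpec
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Polygenic expression with replicate noise and class zero-inflation.

    Returns the expression matrix (log2-TPM scale) and the truth table:
    per-gene class per condition, target h2 per condition, hotspot flag.
    """
    plan = _gene_plan(spec)
    if set(plan["gene_id"]) != set(catalog.table["gene_id"]):
        raise ValueError("catalog does not match this spec's gene plan")
    if len(catalog) == 0:
        raise ValueError("empty gene catalog")
    rng = _rng(spec.seed, 3)

    K = grm_mod.compute_grm(grm_mod.maf_filter(geno)).K
    Ksqrt = _k_sqrt(K)
    n_g = geno.n_genotypes
    conditions = ("control", "salt")
    reps = (1, 2)
    samples = [
        SampleKey(g, c, r) for c in conditions for r in reps for g in geno.genotype_ids
    ]
    col_of = {(c, r): np.arange(n_g) + (ci * 2 + ri) * n_g
              for ci, c in enumerate(conditions) for ri, r in enumerate(reps)}

    n_genes = len(plan)
    values = np.empty((n_genes, len(samples)))
    mask = np.zeros_like(values, dtype=bool)
    se = spec.replicate_sd
    for i, row in enumerate(plan.itertuples(index=False)):
        for c, h2 in (("control", row.h2_control), ("salt", row.h2_salt)):
            v = simulate_gene_values(Ksqrt, h2, 2, rng, sigma_e=se, mu=row.mu)
            z = rng.random((n_g, 2)) < row.p_zero
            for ri, r in enumerate(reps):
                cols = col_of[(c, r)]
                values[i, cols] = v[:, ri]
                mask[i, cols] = z[:, ri]
    values[mask] = 0.0

    expr = ExpressionMatrix(list(plan["gene_id"]), samples, values, mask)
    truth = plan[
        ["gene_id", "gene_class", "chromosome", "midpoint",
         "h2_control", "h2_salt", "hotspot"]
    ].copy()
    truth["class_control"] = truth["gene_class"]
    truth["class_salt"] = truth["gene_class"]
    return expr, truth


# ---------------------------------------------------------------------------
# tracks


def simulate_tracks(
    catalog: GeneCatalog,
    truth: pd.DataFrame,
    bin_bp: int = 500_000,
    seed: int = 0,
    noise_sd: float = 0.5,
    pericentromere_fraction: float = 0.3,
) -> tuple[GenomicTrack, GenomicTrack]:
    """A/B-eigenvector and pericentromere tracks for the simulated genome.

    The eigenvector per fixed bin is the per-chromosome standardised
    constitutive-gene density plus N(0, noise_sd) noise; positive values mean
    the A (gene-dense, euchromatic) compartment.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if len(catalog) == 0:
        raise ValueError("empty gene catalog")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    lengths = catalog.lengths()
    mid = catalog.midpoints
    const_genes = set(truth.loc[truth["class_control"] == "constitutive", "gene_id"])
    cat = catalog.table

    eig_rows, peri_rows = [], []
    for chrom in sorted(lengths):
        L = int(lengths[chrom])
        n_bins = max(L // bin_bp, 1)
        dens = np.zeros(n_bins)
        genes_here = cat.loc[cat["chromosome"] == chrom, "gene_id"]
        for g in genes_here:
            if g in const_genes:
                b = min(int((mid[g] - 1) // bin_bp), n_bins - 1)
                dens[b] += 1
        sd = dens.std()
        z = (dens - dens.mean()) / sd if sd > 0 else dens * 0.0
        eig = z + rng.normal(0.0, noise_sd, n_bins) if noise_sd > 0 else z
        for b in range(n_bins):
            start = b * bin_bp + 1
            end = min((b + 1) * bin_bp, L)
            eig_rows.append((chrom, start, end, float(eig[b])))
        half = pericentromere_fraction / 2.0
        peri_rows.append((chrom, int(L * (0.5 - half)) + 1, int(L * (0.5 + half)), 1.0))

    eig = GenomicTrack(
        "AB_eigenvector",
        pd.DataFrame(eig_rows, columns=["chromosome", "start_bp", "end_bp", "value"]),
    )
    peri = GenomicTrack(
        "pericentromere",
        pd.DataFrame(peri_rows, columns=["chromosome", "start_bp", "end_bp", "value"]),
    )
    return eig, peri


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    genotypes: GenotypeMatrix
    catalog: GeneCatalog
    expression: ExpressionMatrix
    truth: pd.DataFrame
    eigenvector: GenomicTrack
    pericentromere: GenomicTrack


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    geno = simulate_genotypes(spec)
    catalog = simulate_gene_catalog(spec)
    expr, truth = simulate_expression(geno, catalog, spec)
    eig, peri = simulate_tracks(
        catalog, truth, seed=spec.seed, noise_sd=spec.eigenvector_noise_sd,
        pericentromere_fraction=spec.pericentromere_fraction,
    )
    return SimulatedDataset(spec, geno, catalog, expr, truth, eig, peri)


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(ds.expression, out / "expression.tsv")
    write_genotypes(ds.genotypes, out / "genotypes.tsv")
    write_gene_catalog(ds.catalog, out / "genes.gff3")
    write_track(ds.eigenvector, out / "eigenvector.bedgraph", bedgraph=True)
    write_track(ds.pericentromere, out / "pericentromere.bed", bedgraph=False)
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
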