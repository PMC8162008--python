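"""Domain containers and readers/writers for the standard on-disk formats.

All genomic coordinates held in memory are 1-based and inclusive (the GFF3
convention). BED and bedGraph files, which are 0-based half-open on disk, are
converted at the boundary in both directions so no other module ever sees a
0-based coordinate.

Expression is stored as log2(TPM) with an explicit missing mask: a raw TPM of
exactly zero is *missing* (the gene was not observed in that sample), and the
cell under the mask carries no numeric meaning. No pseudocount is added.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("expherit")

CONDITIONS = ("control", "salt")

_SAMPLE_RE = re.compile(r"^(?P<genotype>.+)__(?P<condition>[A-Za-z]+)__rep(?P<rep>\d+)$")


class SampleKey(NamedTuple):
    """Identity of one RNA-seq sample: accession, treatment, replicate."""

    genotype_id: str
    condition: str
    replicate: int

    def label(self) -> str:
        return f"{self.genotype_id}__{self.condition}__rep{self.replicate}"


class FormatError(ValueError):
    """A file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2(TPM) with a boolean missing mask.

    ``values`` is finite wherever ``missing_mask`` is False; masked entries
    are numerically meaningless. ``raw_tpm``, when present, holds the TPM
    matrix exactly as read so that writing the matrix back reproduces the
    input bit-for-bit (zeros stay zeros).
    """

    gene_ids: list[str]
    samples: list[SampleKey]
    values: np.ndarray
    missing_mask: np.ndarray
    raw_tpm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        shape = (len(self.gene_ids), len(self.samples))
        if self.values.shape != shape or self.missing_mask.shape != shape:
            raise ValueError(
                f"values/missing_mask shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.samples)} samples)"
            )
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-finite expression value outside the missing mask")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def genotype_ids(self) -> list[str]:
        """Distinct genotypes in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.genotype_id, None)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    @property
    def replicates(self) -> list[int]:
        return sorted({s.replicate for s in self.samples})

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def sample_columns(self, condition: str | None = None, replicate: int | None = None) -> np.ndarray:
        """Column indices matching a condition and/or replicate."""
        idx = [
            j
            for j, s in enumerate(self.samples)
            if (condition is None or s.condition == condition)
            and (replicate is None or s.replicate == replicate)
        ]
        return np.asarray(idx, dtype=int)

    def replicate_matrix(self, gene_id: str, condition: str) -> pd.DataFrame:
        """Genotype x replicate values for one gene; masked cells are NaN."""
        i = self.gene_index(gene_id)
        cols = self.sample_columns(condition=condition)
        if cols.size == 0:
            raise ValueError(f"condition {condition!r} absent from samples")
        genotypes = self.genotype_ids
        reps = self.replicates
        out = pd.DataFrame(np.nan, index=genotypes, columns=reps)
        for j in cols:
            s = self.samples[j]
            if not self.missing_mask[i, j]:
                out.loc[s.genotype_id, s.replicate] = self.values[i, j]
        return out


@dataclass
class GenotypeMatrix:
    """Genotypes x markers allele-dosage matrix with a sorted marker map."""

    genotype_ids: list[str]
    markers: pd.DataFrame  # columns marker_id, chromosome, position_bp
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.genotype_ids), len(self.markers)):
            raise ValueError("dosage matrix shape does not match ids/markers")
        if np.isnan(self.dosages).any():
            raise ValueError(
                "missing dosages are not allowed: impute genotypes upstream before loading"
            )
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker, mean(dosage)/2."""
        return self.dosages.mean(axis=0) / 2.0


@dataclass
class GeneCatalog:
    """Gene coordinates (1-based inclusive) plus optional chromosome lengths."""

    table: pd.DataFrame  # gene_id, chromosome, start_bp, end_bp, strand
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        t = self.table
        if t["gene_id"].duplicated().any():
            dups = t.loc[t["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if (t["start_bp"] > t["end_bp"]).any():
            raise ValueError("gene with start_bp > end_bp")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def midpoints(self) -> pd.Series:
        """Per-gene midpoint, floor((start+end)/2), indexed by gene_id."""
        t = self.table
        return pd.Series(
            ((t["start_bp"].to_numpy() + t["end_bp"].to_numpy()) // 2),
            index=t["gene_id"].to_numpy(),
        )

    def lengths(self) -> dict[str, int]:
        """Chromosome lengths: provided table, else max annotated end."""
        if self.chrom_lengths is not None:
            return dict(self.chrom_lengths)
        return self.table.groupby("chromosome")["end_bp"].max().astype(int).to_dict()


@dataclass
class GenomicTrack:
    """Labelled non-overlapping intervals with a value (1-based inclusive)."""

    label: str
    intervals: pd.DataFrame  # chromosome, start_bp, end_bp, value

    def __post_init__(self) -> None:
        iv = self.intervals.sort_values(["chromosome", "start_bp"]).reset_index(drop=True)
        if (iv["start_bp"] > iv["end_bp"]).any():
            raise ValueError(f"track {self.label!r}: interval with start > end")
        for chrom, grp in iv.groupby("chromosome"):
            starts = grp["start_bp"].to_numpy()
            ends = grp["end_bp"].to_numpy()
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError(f"track {self.label!r}: overlapping intervals on {chrom}")
        self.intervals = iv

    def chromosomes(self) -> list[str]:
        return sorted(self.intervals["chromosome"].unique())


# ---------------------------------------------------------------------------
# expression


def parse_sample_label(label: str) -> SampleKey:
    m = _SAMPLE_RE.match(label)
    if not m:
        raise FormatError(
            f"sample column {label!r} does not match '<genotype>__<condition>__rep<k>'"
        )
    cond = m.group("condition").lower()
    if cond not in CONDITIONS:
        raise FormatError(f"sample column {label!r}: unknown condition {cond!r}")
    return SampleKey(m.group("genotype"), cond, int(m.group("rep")))


def read_expression(path) -> ExpressionMatrix:
    """Read a raw-TPM TSV (genes x samples) into log2 space with a zero mask.

    Sample columns must be labelled ``<genotype>__<condition>__rep<k>``.
    Genotypes lacking any condition x replicate combination observed in the
    header are dropped with a warning, mirroring the study design in which
    only accessions with replicates in both conditions are usable.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    keys = [parse_sample_label(str(c)) for c in df.columns]

    combos = sorted({(k.condition, k.replicate) for k in keys})
    by_geno: dict[str, set] = {}
    for k in keys:
        by_geno.setdefault(k.genotype_id, set()).add((k.condition, k.replicate))
    complete = {g for g, have in by_geno.items() if have == set(combos)}
    dropped = sorted(set(by_geno) - complete)
    if dropped:
        logger.warning(
            "dropping %d genotype(s) without a full condition x replicate design: %s",
            len(dropped), ", ".join(dropped[:10]),
        )
    keep = [j for j, k in enumerate(keys) if k.genotype_id in complete]
    keys = [keys[j] for j in keep]
    tpm = df.iloc[:, keep].to_numpy(dtype=float)
    if np.isnan(tpm).any():
        raise ValueError("expression TSV contains empty/NaN cells; raw TPM expected")
    if (tpm < 0).any():
        raise ValueError("negative TPM value in expression TSV")

    mask = tpm == 0.0
    values = np.zeros_like(tpm)
    values[~mask] = np.log2(tpm[~mask])
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        samples=keys,
        values=values,
        missing_mask=mask,
        raw_tpm=tpm,
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write raw TPM back to TSV; masked cells become 0."""
    if expr.raw_tpm is not None:
        tpm = expr.raw_tpm
    else:
        tpm = np.where(expr.missing_mask, 0.0, np.exp2(expr.values))
    df = pd.DataFrame(tpm, index=expr.gene_ids, columns=[s.label() for s in expr.samples])
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genotypes


def _finish_genotypes(ids, markers: pd.DataFrame, dos: np.ndarray) -> GenotypeMatrix:
    order = markers.sort_values(["chromosome", "position_bp"], kind="stable")
    if not order.index.equals(markers.index):
        logger.info("markers were not sorted by (chromosome, position); sorting")
    dos = dos[:, order.index.to_numpy()]
    markers = order.reset_index(drop=True)
    return GenotypeMatrix(list(ids), markers, dos)


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Load an imputed dosage matrix from TSV or VCF.

    TSV rows are markers: ``marker_id  chromosome  position`` followed by one
    dosage column per genotype. VCF genotype calls are converted to
    alt-allele dosage (0/1/2); any missing call is an error because the
    pipeline requires imputed input.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        meta_cols = list(df.columns[:3])
        markers = df[meta_cols].copy()
        markers.columns = ["marker_id", "chromosome", "position_bp"]
        markers["position_bp"] = markers["position_bp"].astype(int)
        dos = df.iloc[:, 3:].to_numpy(dtype=float).T  # genotypes x markers
        if np.isnan(dos).any():
            raise ValueError("missing genotype dosage: impute upstream before loading")
        if dos.size and (dos.min() < 0 or dos.max() > 2):
            raise ValueError("dosage outside [0, 2] in genotype TSV")
        return _finish_genotypes(list(df.columns[3:]), markers, dos)
    if format == "vcf":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        ids = list(vcf.samples)
        rows, recs = [], []
        for var in vcf:
            gts = var.genotypes  # [a0, a1, phased] per sample
            d = np.empty(len(ids))
            for i, g in enumerate(gts):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    raise ValueError(
                        f"missing genotype call at {var.CHROM}:{var.POS} for sample "
                        f"{ids[i]}: impute upstream before loading"
                    )
                d[i] = sum(1 for a in alleles if a > 0)
            rows.append(d)
            recs.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, int(var.POS)))
        markers = pd.DataFrame(recs, columns=["marker_id", "chromosome", "position_bp"])
        dos = np.asarray(rows).T if rows else np.empty((len(ids), 0))
        return _finish_genotypes(ids, markers, dos)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = geno.markers.copy()
    for i, gid in enumerate(geno.genotype_ids):
        df[gid] = geno.dosages[i]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene catalog (GFF3)


def read_gene_catalog(path) -> GeneCatalog:
    """Read ``gene`` features from a GFF3 file; other feature types ignored."""
    import gffutils

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 9 and parts[2] == "gene" and "ID=" not in parts[8]:
                raise FormatError(f"gene feature without ID attribute at line {lineno}")

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    rows = [
        (f.id, f.seqid, int(f.start), int(f.end), f.strand)
        for f in db.features_of_type("gene")
    ]
    if not rows:
        logger.warning("GFF3 %s contains no 'gene' features; catalog is empty", path)
    table = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start_bp", "end_bp", "strand"]
    )
    lengths: dict[str, int] = {}
    for d in db.directives:
        if d.startswith("sequence-region"):
            _, chrom, _start, end = d.split()
            lengths[chrom] = int(end)
    return GeneCatalog(table, chrom_lengths=lengths or None)


def write_gene_catalog(catalog: GeneCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted((catalog.chrom_lengths or {}).items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for row in catalog.table.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\texpherit\tgene\t{row.start_bp}\t{row.end_bp}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# tracks (BED / bedGraph)


def read_track(path, label: str) -> GenomicTrack:
    """Read a BED or bedGraph track into 1-based inclusive coordinates.

    A numeric fourth column is interpreted as a bedGraph value; BED intervals
    without one get value 1.0 (presence/absence tracks such as
    pericentromeres).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            value = 1.0
            if len(parts) > 3:
                try:
                    value = float(parts[3])
                except ValueError:
                    value = 1.0  # BED name column
            rows.append((chrom, start0 + 1, end0, value))
    iv = pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "value"])
    return GenomicTrack(label, iv)


def write_track(track: GenomicTrack, path, bedgraph: bool = True) -> None:
    with open(path, "w") as fh:
        for row in track.intervals.itertuples(index=False):
            fields = [row.chromosome, str(row.start_bp - 1), str(row.end_bp)]
            if bedgraph:
                fields.append(repr(row.value))
            fh.write("\t".join(fields) + "\n")
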