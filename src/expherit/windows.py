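"""Chromosomal sliding-window scans and track correlation.

Enrichment of salt-specific heritable genes is scanned in overlapping
windows (default 1.5 Mb every 100 kb). For each window a one-tailed
Fisher's exact test compares [in-window vs out-of-window] x [salt-specific
vs other-heritable]; multiple testing is handled by a resampled null:
random subsets of the heritable genes, of the same size as the
salt-specific set, are drawn repeatedly, the per-window Fisher p is
recomputed, and the adjusted p is the (+1-corrected) fraction of null p's
at or below the observed one. Windows with zero null exceedances escalate
in batches to a larger iteration cap until the quantile stabilises.

Genes are assigned to windows by midpoint (floor((start+end)/2)), so a
non-overlapping tiling conserves the total gene count exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneCatalog, GenomicTrack

logger = logging.getLogger("expherit")


@dataclass(frozen=True)
class WindowSpec:
    window_bp: int = 1_500_000
    step_bp: int = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.step_bp <= self.window_bp):
            raise ValueError("require 0 < step_bp <= window_bp")


DENSITY_WINDOW = WindowSpec(3_000_000, 100_000)
ENRICHMENT_WINDOW = WindowSpec(1_500_000, 100_000)


def make_windows(chrom_lengths: dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Sliding windows per chromosome, 1-based inclusive.

    Starts are 1, 1+step, ...; the count is floor((L - window)/step) + 1. A
    chromosome shorter than one window yields a single window covering it.
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        L = int(chrom_lengths[chrom])
        if L < spec.window_bp:
            rows.append((chrom, 1, L))
            continue
        n = (L - spec.window_bp) // spec.step_bp + 1
        for i in range(n):
            start = 1 + i * spec.step_bp
            rows.append((chrom, start, start + spec.window_bp - 1))
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp"])


def _membership(windows: pd.DataFrame, catalog: GeneCatalog, gene_ids) -> np.ndarray:
    """Boolean windows x genes midpoint-containment matrix."""
    mid = catalog.midpoints
    chrom_of = dict(zip(catalog.table["gene_id"], catalog.table["chromosome"]))
    M = np.zeros((len(windows), len(gene_ids)), dtype=bool)
    wstart = windows["start_bp"].to_numpy()
    wend = windows["end_bp"].to_numpy()
    wchrom = windows["chromosome"].to_numpy()
    known_chroms = set(wchrom)
    for j, g in enumerate(gene_ids):
        if g not in mid.index:
            raise KeyError(f"labelled gene {g!r} absent from catalog")
        c = chrom_of[g]
        if c not in known_chroms:
            logger.warning("gene %s on chromosome %s without windows; excluded", g, c)
            continue
        m = mid[g]
        M[:, j] = (wchrom == c) & (wstart <= m) & (m <= wend)
    return M


def window_counts(
    windows: pd.DataFrame, catalog: GeneCatalog, labels: pd.Series | dict
) -> pd.DataFrame:
    """Per-window gene counts, total and per label value.

    labels maps gene_id -> label (expression class or heritability class).
    Overlapping windows each count any gene whose midpoint they cover.
    """
    labels = pd.Series(labels)
    genes = list(labels.index)
    M = _membership(windows, catalog, genes)
    out = windows.copy()
    out["n_genes_total"] = M.sum(axis=1)
    for lab in sorted(labels.unique()):
        sel = (labels == lab).to_numpy()
        out[f"n_{lab}"] = M[:, sel].sum(axis=1)
    return out


def _hypergeom_tail_tables(n_in_window: np.ndarray, N: int, K: int) -> list[np.ndarray]:
    """Per-window lookup: p[k] = one-tailed Fisher p for k successes."""
    tables = []
    for n in n_in_window:
        ks = np.arange(n + 1)
        tables.append(stats.hypergeom.sf(ks - 1, N, K, n))
    return tables


def fisher_enrichment(
    wt: pd.DataFrame, n_target_total: int, n_reference_total: int,
    target_col: str = "n_salt_specific", reference_col: str = "n_heritable",
) -> pd.DataFrame:
    """One-tailed (greater) Fisher exact p per window.

    The 2x2 table is [in-window vs out] x [target class vs other reference
    genes]; the p-value is the upper hypergeometric tail. Windows with no
    reference genes get p = 1.0 and are flagged.
    """
    out = wt.copy()
    n_ref = out[reference_col].to_numpy()
    n_tgt = out[target_col].to_numpy()
    if (n_tgt > n_ref).any():
        raise ValueError(f"{target_col} exceeds {reference_col} in some window")
    p = np.ones(len(out))
    nz = n_ref > 0
    p[nz] = stats.hypergeom.sf(n_tgt[nz] - 1, n_reference_total, n_target_total, n_ref[nz])
    out["fisher_p"] = np.clip(p, np.nextafter(0, 1), 1.0)
    out["empty_window"] = ~nz
    return out


def bootstrap_adjust(
    wt: pd.DataFrame,
    catalog: GeneCatalog,
    heritable_genes: list[str],
    n_salt: int,
    B: int = 4000,
    B_max: int = 50_000,
    seed: int | None = None,
    alpha: float = 0.001,
    batch: int = 500,
) -> pd.DataFrame:
    """Resampling-adjusted p per window.

    Each iteration draws n_salt genes without replacement from the heritable
    set and recomputes every window's Fisher p; adjusted_p = (1 + #{null p
    <= observed p}) / (1 + B_completed). Windows with zero exceedances after
    B iterations escalate in batches up to B_max. significant <=>
    adjusted_p < alpha (strict).
    """
    if seed is None:
        raise ValueError("a seed is required: the resampled null must be reproducible")
    N = len(heritable_genes)
    if n_salt > N:
        raise ValueError("n_salt exceeds the heritable gene set")
    out = wt.copy()
    M = _membership(out[["chromosome", "start_bp", "end_bp"]], catalog, heritable_genes)
    n_ref = M.sum(axis=1)  # heritable genes per window (fixed across draws)
    obs_p = out["fisher_p"].to_numpy()
    tables = _hypergeom_tail_tables(n_ref, N, n_salt)
    # null p <= obs p  <=>  null k >= smallest k with p[k] <= obs p
    k_crit = np.empty(len(out), dtype=int)
    for w in range(len(out)):
        le = np.nonzero(tables[w] <= obs_p[w] + 1e-15)[0]
        k_crit[w] = le[0] if le.size else n_ref[w] + 1

    rng = np.random.default_rng(seed)
    Mf = M.astype(np.float64)
    exceed = np.zeros(len(out), dtype=np.int64)
    done_iters = np.zeros(len(out), dtype=np.int64)
    active = np.ones(len(out), dtype=bool)
    total = 0
    while active.any() and total < B_max:
        target = B if total < B else min(B_max, total + max(batch * 4, 2000))
        nb = target - total
        for s0 in range(0, nb, batch):
            bsz = min(batch, nb - s0)
            D = np.zeros((N, bsz))
            for b in range(bsz):
                D[rng.choice(N, size=n_salt, replace=False), b] = 1.0
            counts = Mf[active] @ D  # active windows x bsz
            exceed[active] += (counts >= k_crit[active, None]).sum(axis=1).astype(np.int64)
            done_iters[active] += bsz
            total += bsz
        # escalate only windows whose quantile is still unanchored
        active = active & (exceed == 0) & (done_iters < B_max)
    out["adjusted_p"] = (1.0 + exceed) / (1.0 + done_iters)
    out["n_null_iterations"] = done_iters
    out["significant"] = out["adjusted_p"] < alpha
    return out


def merge_regions(
    wt: pd.DataFrame, step_bp: int, alpha: float = 0.001
) -> pd.DataFrame:
    """Merge significant windows that overlap or abut within one step."""
    sig = wt.loc[wt["adjusted_p"] < alpha].sort_values(["chromosome", "start_bp"])
    regions = []
    wt = wt.copy()
    wt["region_id"] = -1
    for chrom, grp in sig.groupby("chromosome", sort=True):
        cur_start = cur_end = None
        members = []
        for idx, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, members = row["start_bp"], row["end_bp"], [idx]
            elif row["start_bp"] <= cur_end + step_bp:
                cur_end = max(cur_end, row["end_bp"])
                members.append(idx)
            else:
                regions.append((chrom, cur_start, cur_end, members))
                cur_start, cur_end, members = row["start_bp"], row["end_bp"], [idx]
        if cur_start is not None:
            regions.append((chrom, cur_start, cur_end, members))
    rows = []
    for rid, (chrom, start, end, members) in enumerate(regions):
        wt.loc[members, "region_id"] = rid
        rows.append({"region_id": rid, "chromosome": chrom,
                     "start_bp": int(start), "end_bp": int(end),
                     "n_windows": len(members)})
    return pd.DataFrame(rows, columns=["region_id", "chromosome", "start_bp",
                                       "end_bp", "n_windows"])


# ---------------------------------------------------------------------------
# fixed-bin density vs. compartment-eigenvector correlation


def _rebin_track(track: GenomicTrack, chrom: str, n_bins: int, bin_bp: int) -> np.ndarray:
    """Length-weighted average of track values on a fixed-bin grid; NaN where
    the track has no coverage."""
    acc = np.zeros(n_bins)
    cov = np.zeros(n_bins)
    iv = track.intervals
    for row in iv.loc[iv["chromosome"] == chrom].itertuples(index=False):
        b0 = (row.start_bp - 1) // bin_bp
        b1 = (row.end_bp - 1) // bin_bp
        for b in range(b0, min(b1, n_bins - 1) + 1):
            lo = max(row.start_bp, b * bin_bp + 1)
            hi = min(row.end_bp, (b + 1) * bin_bp)
            ln = hi - lo + 1
            if ln > 0:
                acc[b] += row.value * ln
                cov[b] += ln
    with np.errstate(invalid="ignore"):
        return np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)


def compartment_correlation(
    catalog: GeneCatalog,
    labels: pd.Series | dict,
    track: GenomicTrack,
    bin_bp: int = 500_000,
    method: str = "spearman",
    label: str = "constitutive",
) -> pd.DataFrame:
    """Per-chromosome correlation of label-gene density with a track.

    Gene midpoints are counted in non-overlapping bins of bin_bp; the track
    is length-weight re-binned onto the same grid. Chromosomes with fewer
    than 5 usable bins are flagged unreliable.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    labels = pd.Series(labels)
    mid = catalog.midpoints
    chrom_of = dict(zip(catalog.table["gene_id"], catalog.table["chromosome"]))
    lengths = catalog.lengths()
    rows = []
    for chrom in sorted(lengths):
        L = int(lengths[chrom])
        n_bins = max(L // bin_bp, 1)
        dens = np.zeros(n_bins)
        for g, lab in labels.items():
            if lab != label or chrom_of.get(g) != chrom:
                continue
            b = min(int((mid[g] - 1) // bin_bp), n_bins - 1)
            dens[b] += 1
        track_vals = _rebin_track(track, chrom, n_bins, bin_bp)
        ok = ~np.isnan(track_vals)
        n_ok = int(ok.sum())
        if n_ok < 2 or dens[ok].std() == 0 or np.nanstd(track_vals[ok]) == 0:
            rho = np.nan
        elif method == "spearman":
            rho = float(stats.spearmanr(dens[ok], track_vals[ok]).statistic)
        else:
            rho = float(stats.pearsonr(dens[ok], track_vals[ok]).statistic)
        rows.append({"chromosome": chrom, "label": label, "method": method,
                     "rho": rho, "n_bins": n_ok, "reliable": n_ok >= 5})
    return pd.DataFrame(rows)
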