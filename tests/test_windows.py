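import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from expherit.io import GeneCatalog, GenomicTrack
from expherit.sim import SimulationSpec, simulate_dataset, simulate_tracks
from expherit.windows import (
    WindowSpec,
    bootstrap_adjust,
    compartment_correlation,
    fisher_enrichment,
    make_windows,
    merge_regions,
    window_counts,
)


def _catalog(midpoints, chrom="Chr1", length=10_000_000):
    table = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(midpoints))],
            "chromosome": chrom,
            "start_bp": [m - 1 for m in midpoints],
            "end_bp": [m + 1 for m in midpoints],
            "strand": "+",
        }
    )
    return GeneCatalog(table, chrom_lengths={chrom: length})


class TestMakeWindows:
    def test_count_formula(self):
        w = make_windows({"Chr1": 10_000_000}, WindowSpec(1_500_000, 100_000))
        assert len(w) == 86  # floor((10e6-1.5e6)/1e5) + 1

    def test_short_chromosome_single_window(self):
        w = make_windows({"Chr1": 1_000_000}, WindowSpec(1_500_000, 100_000))
        assert len(w) == 1
        assert (w.iloc[0]["start_bp"], w.iloc[0]["end_bp"]) == (1, 1_000_000)

    def test_step_equal_window_tiles_without_overlap(self):
        w = make_windows({"Chr1": 3_000_000}, WindowSpec(1_000_000, 1_000_000))
        assert w["start_bp"].tolist() == [1, 1_000_001, 2_000_001]
        assert (w["end_bp"] - w["start_bp"] + 1).eq(1_000_000).all()

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(1_000_000, 2_000_000)


class TestWindowCounts:
    def test_midpoint_containment(self):
        cat = _catalog([200_000, 250_000, 1_400_000, 9_999_000])
        w = make_windows(cat.lengths(), WindowSpec(1_500_000, 100_000))
        labels = pd.Series("constitutive", index=cat.table["gene_id"])
        wt = window_counts(w, cat, labels)
        first = wt.iloc[0]
        assert first["n_constitutive"] == 3  # genes within [1, 1.5e6]

    def test_boundary_midpoint_counted_in_every_covering_window(self):
        cat = _catalog([1_500_000])
        w = make_windows(cat.lengths(), WindowSpec(1_500_000, 100_000))
        wt = window_counts(w, cat, pd.Series({"g0": "x"}))
        covering = ((w["start_bp"] <= 1_500_000) & (w["end_bp"] >= 1_500_000)).sum()
        assert wt["n_x"].sum() == covering

    def test_tiling_conserves_gene_count(self):
        rng = np.random.default_rng(0)
        cat = _catalog(sorted(rng.integers(1, 10_000_000, 200).tolist()))
        w = make_windows(cat.lengths(), WindowSpec(1_000_000, 1_000_000))
        wt = window_counts(w, cat, pd.Series("c", index=cat.table["gene_id"]))
        assert wt["n_c"].sum() == 200

    def test_empty_label_set_gives_zero_totals(self):
        cat = _catalog([100])
        w = make_windows(cat.lengths(), WindowSpec(1_500_000, 100_000))
        wt = window_counts(w, cat, pd.Series(dtype=object))
        assert wt["n_genes_total"].sum() == 0


def exhaustive_one_tail_p(k, n, K, N):
    """Enumerate all 2x2 tables with the fixed margins; sum P(X >= k)."""
    total = comb(N, n, exact=True)
    num = sum(
        comb(K, j, exact=True) * comb(N - K, n - j, exact=True)
        for j in range(k, min(n, K) + 1)
    )
    return num / total


class TestFisher:
    def test_matches_enumeration_on_all_small_margins(self):
        """Exact agreement with the enumeration oracle for margins <= 30."""
        for N in (5, 11, 18, 30):
            for K in range(0, N + 1, max(1, N // 4)):
                for n in range(1, N + 1, max(1, N // 5)):
                    for k in range(0, min(n, K) + 1):
                        wt = pd.DataFrame(
                            {"n_heritable": [n], "n_salt_specific": [k]}
                        )
                        out = fisher_enrichment(wt, K, N)
                        expected = exhaustive_one_tail_p(k, n, K, N)
                        assert out["fisher_p"].iloc[0] == pytest.approx(
                            expected, rel=1e-12, abs=1e-300
                        )

    def test_zero_successes_gives_p_one(self):
        wt = pd.DataFrame({"n_heritable": [10], "n_salt_specific": [0]})
        out = fisher_enrichment(wt, 50, 1000)
        assert out["fisher_p"].iloc[0] == pytest.approx(1.0)

    def test_empty_window_flagged(self):
        wt = pd.DataFrame({"n_heritable": [0], "n_salt_specific": [0]})
        out = fisher_enrichment(wt, 50, 1000)
        assert out["fisher_p"].iloc[0] == 1.0
        assert out["empty_window"].iloc[0]

    def test_all_successes_in_window_is_minimal_p(self):
        wt = pd.DataFrame({"n_heritable": [10], "n_salt_specific": [10]})
        out = fisher_enrichment(wt, 10, 100)
        assert out["fisher_p"].iloc[0] == pytest.approx(
            exhaustive_one_tail_p(10, 10, 10, 100), rel=1e-9
        )


class TestBootstrapAdjust:
    def _setup(self, n_genes=60, n_salt=10, seed=0):
        rng = np.random.default_rng(seed)
        mids = sorted(rng.integers(1, 10_000_000, n_genes).tolist())
        cat = _catalog(mids)
        genes = list(cat.table["gene_id"])
        w = make_windows(cat.lengths(), WindowSpec(1_500_000, 500_000))
        labels = pd.Series("general", index=genes)
        labels.iloc[:n_salt] = "salt_specific"
        wt = window_counts(w, cat, labels)
        wt["n_heritable"] = wt["n_general"] + wt["n_salt_specific"]
        wt = fisher_enrichment(wt, n_salt, n_genes)
        return wt, cat, genes, n_salt

    def test_adjusted_p_matches_hypergeometric_rank(self):
        """adjusted_p estimates P(null p <= observed p), which for a random
        draw of n_salt genes is an exact hypergeometric tail; a window whose
        observed p sits at the null median therefore adjusts to ~0.5."""
        from scipy.stats import hypergeom

        wt, cat, genes, n_salt = self._setup()
        B = 2000
        out = bootstrap_adjust(wt, cat, genes, n_salt, B=B, B_max=B, seed=1)
        for row in out.itertuples(index=False):
            theo = hypergeom.sf(row.n_salt_specific - 1, len(genes),
                                n_salt, row.n_heritable)
            se = np.sqrt(theo * (1 - theo) / B)
            assert abs(row.adjusted_p - (1 + B * theo) / (1 + B)) < 4 * se + 2 / B

    def test_never_exceeded_gives_adjusted_one(self):
        wt, cat, genes, n_salt = self._setup()
        wt["fisher_p"] = 1.0  # observed worse than every null draw
        out = bootstrap_adjust(wt, cat, genes, n_salt, B=99, B_max=99, seed=2)
        assert (out["adjusted_p"] == 1.0).all()

    def test_plus_one_correction_never_zero(self):
        wt, cat, genes, n_salt = self._setup()
        out = bootstrap_adjust(wt, cat, genes, n_salt, B=99, B_max=99, seed=3)
        assert (out["adjusted_p"] > 0).all()

    def test_escalation_anchors_extreme_windows(self):
        wt, cat, genes, n_salt = self._setup()
        wt.loc[wt["n_salt_specific"].idxmax(), "fisher_p"] = 1e-30
        out = bootstrap_adjust(wt, cat, genes, n_salt, B=200, B_max=2000, seed=4)
        hot = out.loc[wt["n_salt_specific"].idxmax()]
        assert hot["n_null_iterations"] == 2000  # escalated past B
        assert hot["adjusted_p"] == pytest.approx(1 / 2001)

    def test_n_salt_larger_than_pool_rejected(self):
        wt, cat, genes, _ = self._setup()
        with pytest.raises(ValueError):
            bootstrap_adjust(wt, cat, genes, len(genes) + 1, seed=1)

    def test_seed_stability_within_monte_carlo_error(self):
        wt, cat, genes, n_salt = self._setup()
        a = bootstrap_adjust(wt, cat, genes, n_salt, B=2000, B_max=2000, seed=5)
        b = bootstrap_adjust(wt, cat, genes, n_salt, B=2000, B_max=2000, seed=6)
        p = ((a["adjusted_p"] + b["adjusted_p"]) / 2).to_numpy()
        se = np.sqrt(np.maximum(p * (1 - p) * 2 / 2000, 1e-12))
        assert (np.abs(a["adjusted_p"] - b["adjusted_p"]) < 3 * se + 2 / 2000).all()


class TestMergeRegions:
    def _wt(self, rows):
        df = pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "adjusted_p"])
        return df

    def test_overlapping_windows_merge(self):
        wt = self._wt([("Chr1", 1, 1_500_000, 1e-5),
                       ("Chr1", 100_001, 1_600_000, 1e-5)])
        regions = merge_regions(wt, 100_000)
        assert len(regions) == 1
        assert (regions.iloc[0]["start_bp"], regions.iloc[0]["end_bp"]) == (1, 1_600_000)

    def test_distant_windows_stay_separate(self):
        wt = self._wt([("Chr1", 1, 1_500_000, 1e-5),
                       ("Chr1", 5_000_001, 6_500_000, 1e-5)])
        assert len(merge_regions(wt, 100_000)) == 2

    def test_no_significant_windows_empty(self):
        wt = self._wt([("Chr1", 1, 1_500_000, 0.5)])
        assert merge_regions(wt, 100_000).empty


class TestCompartmentCorrelation:
    def test_density_identical_to_track_is_perfect(self):
        rng = np.random.default_rng(0)
        mids, rows = [], []
        for b in range(20):
            n = int(rng.integers(0, 6))
            mids += [b * 500_000 + 100 + i for i in range(n)]
            rows.append(("Chr1", b * 500_000 + 1, (b + 1) * 500_000, float(n)))
        cat = _catalog(sorted(mids))
        track = GenomicTrack("t", pd.DataFrame(
            rows, columns=["chromosome", "start_bp", "end_bp", "value"]))
        labels = pd.Series("constitutive", index=cat.table["gene_id"])
        out = compartment_correlation(cat, labels, track, 500_000, "pearson")
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_rebinning_length_weighted_average(self):
        # track at 250 kb resolution averaged onto 500 kb bins
        rows = [("Chr1", 1, 250_000, 2.0), ("Chr1", 250_001, 500_000, 4.0)]
        track = GenomicTrack("t", pd.DataFrame(
            rows, columns=["chromosome", "start_bp", "end_bp", "value"]))
        from expherit.windows import _rebin_track
        vals = _rebin_track(track, "Chr1", 2, 500_000)
        assert vals[0] == pytest.approx(3.0)
        assert np.isnan(vals[1])

    def test_few_bins_flagged_unreliable(self):
        cat = _catalog([100, 200], length=1_000_000)
        track = GenomicTrack("t", pd.DataFrame(
            [("Chr1", 1, 500_000, 1.0), ("Chr1", 500_001, 1_000_000, -1.0)],
            columns=["chromosome", "start_bp", "end_bp", "value"]))
        labels = pd.Series("constitutive", index=cat.table["gene_id"])
        out = compartment_correlation(cat, labels, track, 500_000)
        assert not out["reliable"].iloc[0]

    def test_zero_noise_simulation_signs(self, small_dataset):
        """Noise-free eigenvector: constitutive rho = 1, repressed rho < 0."""
        eig, _ = simulate_tracks(small_dataset.catalog, small_dataset.truth,
                                 seed=1, noise_sd=0.0)
        labels = small_dataset.truth.set_index("gene_id")["class_control"]
        const = compartment_correlation(small_dataset.catalog, labels, eig,
                                        500_000, "pearson", "constitutive")
        repr_ = compartment_correlation(small_dataset.catalog, labels, eig,
                                        500_000, "pearson", "repressed")
        assert np.allclose(const["rho"], 1.0)
        assert (repr_["rho"] < 0).all()


class TestPlantedHotspot:
    def test_hotspot_recovered_and_background_clean(self):
        """The planted salt-specific window is found; background stays null."""
        spec = SimulationSpec(
            n_genotypes=30, n_markers=300, n_chromosomes=2,
            chromosome_length_bp=10_000_000, n_genes=400,
            hotspot_spec=(("Chr1", 4_000_001, 5_500_000, 17),), seed=33,
        )
        ds = simulate_dataset(spec)
        truth = ds.truth.set_index("gene_id")
        # heritability classes straight from the generative truth
        cls = pd.Series("not_heritable", index=truth.index)
        cls[(truth["h2_control"] > 0) & (truth["h2_salt"] > 0)] = "general"
        cls[truth["hotspot"]] = "salt_specific"
        heritable = cls[cls != "not_heritable"]
        wspec = WindowSpec(1_500_000, 100_000)
        wt = window_counts(make_windows(ds.catalog.lengths(), wspec),
                           ds.catalog, heritable)
        wt["n_heritable"] = wt.get("n_general", 0) + wt["n_salt_specific"]
        n_salt = int((heritable == "salt_specific").sum())
        wt = fisher_enrichment(wt, n_salt, len(heritable))
        wt = bootstrap_adjust(wt, ds.catalog, list(heritable.index), n_salt,
                              B=2000, B_max=10_000, seed=1)
        hot = wt[(wt["chromosome"] == "Chr1")
                 & (wt["start_bp"] <= 4_000_001) & (wt["end_bp"] >= 5_500_000 - 1)]
        in_hot = wt[(wt["chromosome"] == "Chr1")
                    & (wt["end_bp"] >= 4_000_001) & (wt["start_bp"] <= 5_500_000)]
        assert (in_hot["adjusted_p"] < 0.001).any()
        background = wt.drop(in_hot.index)
        assert (background["adjusted_p"] < 0.001).sum() <= max(
            1, math.ceil(0.001 * len(background))
        )
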