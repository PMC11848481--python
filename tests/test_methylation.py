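import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from dfatmap import (
    MethylationTrack,
    PatternParams,
    classify_patterns,
    cluster_patterns,
    composite_profile,
    gene_set_methylation,
    gene_tss_methylation,
    read_methylation_track,
    tss_profile_matrix,
)
from dfatmap.methylation import _label_centroid


def _track(rows, condition="CD"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "level"])
    return MethylationTrack(condition=condition, records=df)


def _annot(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


class TestReadTrack:
    def test_basic_and_sorting(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t500\t501\t0.9\nchr1\t100\t101\t0.5\nchr1\t200\t201\t0.7\n")
        t = read_methylation_track(p, "CD")
        assert len(t.records) == 3
        assert list(t.records["start"]) == [100, 200, 500]

    def test_percent_dialect(self, tmp_path):
        p = tmp_path / "pct.bedgraph"
        p.write_text("chr1\t10\t11\t85\nchr1\t20\t21\t12\n")
        with pytest.warns(UserWarning, match="percent"):
            t = read_methylation_track(p, "CD")
        assert t.records["level"].tolist() == [0.85, 0.12]

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t10\t11\t0.5\nchr1\toops\t21\t0.2\n")
        with pytest.raises(ValueError, match=":2"):
            read_methylation_track(p, "CD")

    def test_overlapping_records_rejected(self, tmp_path):
        p = tmp_path / "ov.bedgraph"
        p.write_text("chr1\t10\t15\t0.5\nchr1\t12\t20\t0.2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_methylation_track(p, "CD")

    def test_coverage_column_kept(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t10\t11\t0.5\t30\n")
        t = read_methylation_track(p, "CD")
        assert t.records["coverage"].tolist() == [30]


class TestProfileMatrix:
    def test_400_bins_for_2kb_at_10bp(self):
        t = _track([("chr1", 5000, 5001, 0.5)])
        a = _annot([("g1", "chr1", 5001, "+")])
        p = tss_profile_matrix(t, a, flank=2000, bin_size=10)
        assert p.n_bins == 400

    def test_constant_field(self):
        rows = [("chr1", s, s + 1, 0.5) for s in range(3000, 7000, 25)]
        t = _track(rows)
        a = _annot([("g1", "chr1", 5001, "+")])
        p = tss_profile_matrix(t, a, flank=2000, bin_size=10)
        covered = p.values.to_numpy()[0]
        assert np.nanmin(covered) == 0.5 and np.nanmax(covered) == 0.5

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        starts = np.sort(rng.choice(np.arange(2000, 9000), size=400, replace=False))
        levels = rng.uniform(0, 1, size=400)
        t = _track([("chr1", int(s), int(s) + 1, float(l))
                    for s, l in zip(starts, levels)])
        a = _annot([("g1", "chr1", 5501, "+"), ("g2", "chr1", 4001, "+")])
        flank, bin_size = 1000, 20
        p = tss_profile_matrix(t, a, flank=flank, bin_size=bin_size)
        for gi, tss in enumerate([5501, 4001]):
            tss0 = tss - 1
            for b in range(2 * flank // bin_size):
                lo = tss0 - flank + b * bin_size
                hi = lo + bin_size
                sel = (starts >= lo) & (starts < hi)
                expected = levels[sel].mean() if sel.any() else np.nan
                got = p.values.iloc[gi, b]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)

    def test_minus_strand_is_reversed_plus(self):
        rng = np.random.default_rng(3)
        starts = np.arange(3000, 7000, 37)
        levels = rng.uniform(0, 1, size=len(starts))
        t = _track([("chr1", int(s), int(s) + 1, float(l))
                    for s, l in zip(starts, levels)])
        a = _annot([("g+", "chr1", 5001, "+"), ("g-", "chr1", 5001, "-")])
        p = tss_profile_matrix(t, a, flank=2000, bin_size=10)
        plus = p.values.loc["g+"].to_numpy()
        minus = p.values.loc["g-"].to_numpy()
        np.testing.assert_array_equal(minus, plus[::-1])

    def test_strand_flip_mirror_symmetry(self):
        # mirroring coordinates and flipping strand leaves the row unchanged
        rng = np.random.default_rng(4)
        starts = np.sort(rng.choice(np.arange(3000, 7000), size=150, replace=False))
        levels = rng.uniform(0, 1, size=150)
        tss = 5001
        t_plus = _track([("chr1", int(s), int(s) + 1, float(l))
                         for s, l in zip(starts, levels)])
        a_plus = _annot([("g", "chr1", tss, "+")])
        row_plus = tss_profile_matrix(t_plus, a_plus, 2000, 10).values.loc["g"]

        c = 2 * (tss - 1)  # mirror around the 0-based TSS
        m_starts = c - starts - 1
        t_minus = _track(sorted(
            [("chr1", int(s), int(s) + 1, float(l))
             for s, l in zip(m_starts, levels)], key=lambda r: r[1]))
        a_minus = _annot([("g", "chr1", tss, "-")])
        row_minus = tss_profile_matrix(t_minus, a_minus, 2000, 10).values.loc["g"]
        np.testing.assert_allclose(row_minus.to_numpy(), row_plus.to_numpy())

    def test_absent_chromosome_gives_missing_row(self):
        t = _track([("chr1", 10, 11, 0.5)])
        a = _annot([("g1", "chr9", 5001, "+")])
        with pytest.warns(UserWarning, match="absent"):
            p = tss_profile_matrix(t, a, flank=1000, bin_size=10)
        assert p.values.isna().all().all()

    def test_indivisible_flank_rejected(self):
        t = _track([("chr1", 10, 11, 0.5)])
        a = _annot([("g1", "chr1", 5001, "+")])
        with pytest.raises(ValueError, match="divisible"):
            tss_profile_matrix(t, a, flank=2000, bin_size=13)


class TestCompositeProfile:
    def test_mean_of_two_genes(self):
        t = _track([("chr1", 4800, 4801, 0.2), ("chr1", 14800, 14801, 0.6)])
        a = _annot([("g1", "chr1", 5001, "+"), ("g2", "chr1", 15001, "+")])
        p = tss_profile_matrix(t, a, flank=1000, bin_size=10)
        comp = composite_profile(p)
        covered = comp.dropna(subset=["mean"])
        assert covered["mean"].tolist() == [pytest.approx(0.4)]
        assert covered["n_genes"].tolist() == [2]

    def test_missing_bin_uses_other_gene(self):
        t = _track([("chr1", 4800, 4801, 0.2), ("chr1", 14900, 14901, 0.6)])
        a = _annot([("g1", "chr1", 5001, "+"), ("g2", "chr1", 15001, "+")])
        comp = composite_profile(tss_profile_matrix(t, a, 1000, 10))
        covered = comp.dropna(subset=["mean"]).sort_index()
        assert covered["mean"].tolist() == [pytest.approx(0.2), pytest.approx(0.6)]
        assert covered["n_genes"].tolist() == [1, 1]

    def test_recovers_planted_dip_location(self):
        from dfatmap import MethSimConfig, simulate_methylomes

        cfg = MethSimConfig(n_genes=60, cpg_spacing=50, noise_sd=0.0,
                            coverage_mean=float("inf"), seed=5)
        tracks, annot, _ = simulate_methylomes(cfg)
        p = tss_profile_matrix(tracks[0], annot, flank=2000, bin_size=10)
        comp = composite_profile(p)
        # dip planted at the TSS: minimum bin within 1 bin of the center
        min_bin = comp["mean"].idxmin()
        center = p.n_bins // 2
        assert abs(min_bin - center) <= 1


class TestGeneTSSMethylation:
    def test_window_mean(self):
        t = _track([("chr1", 4500, 4501, 0.2), ("chr1", 5000, 5001, 0.4),
                    ("chr1", 5400, 5401, 0.9)])
        a = _annot([("g1", "chr1", 5001, "+")])
        s = gene_tss_methylation(t, a, flank=1000)
        assert s["g1"] == pytest.approx(0.5)

    def test_no_cpgs_missing_not_zero(self):
        t = _track([("chr1", 100, 101, 0.3)])
        a = _annot([("g1", "chr1", 50001, "+")])
        s = gene_tss_methylation(t, a, flank=1000)
        assert np.isnan(s["g1"])

    def test_matches_bruteforce_window_scan(self):
        rng = np.random.default_rng(9)
        starts = np.sort(rng.choice(np.arange(0, 20000), size=800, replace=False))
        levels = rng.uniform(0, 1, size=800)
        t = _track([("chr1", int(s), int(s) + 1, float(l))
                    for s, l in zip(starts, levels)])
        a = _annot([(f"g{i}", "chr1", int(tss), "+")
                    for i, tss in enumerate([3001, 9000, 15500])])
        s = gene_tss_methylation(t, a, flank=1000)
        for i, tss in enumerate([3001, 9000, 15500]):
            tss0 = tss - 1
            sel = (starts >= tss0 - 1000) & (starts < tss0 + 1000)
            assert s[f"g{i}"] == pytest.approx(levels[sel].mean())


class TestPatternClustering:
    def _summary(self, vectors, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        arr = np.asarray(vectors, dtype=float)
        arr = arr + rng.normal(0, noise, size=arr.shape)
        return pd.DataFrame(
            arr, columns=["CD", "HFD", "HFD-CD"],
            index=pd.Index([f"g{i}" for i in range(len(arr))], name="gene"),
        )

    def test_planted_shapes_recovered(self):
        protos = {0: [0.5, 0.8, 0.5], 1: [0.5, 0.2, 0.2], 2: [0.5, 0.5, 0.8]}
        truth = np.repeat([0, 1, 2], 30)
        s = self._summary([protos[t] for t in truth], noise=0.01, seed=1)
        clusters = cluster_patterns(s, PatternParams(k=3, seed=0))
        assert adjusted_rand_score(truth, clusters) == 1.0

    def test_identical_vectors_stable(self):
        s = self._summary([[0.5, 0.5, 0.5]] * 10)
        clusters = cluster_patterns(s, PatternParams(k=3, seed=0))
        assert len(clusters) == 10

    def test_more_clusters_never_increase_inertia(self):
        rng = np.random.default_rng(0)
        s = self._summary(rng.uniform(0.2, 0.8, size=(60, 3)))
        from sklearn.cluster import KMeans

        x = s.to_numpy() - s.to_numpy().mean(axis=1, keepdims=True)
        inertias = [
            KMeans(n_clusters=k, n_init=10, random_state=0).fit(x).inertia_
            for k in (3, 6)
        ]
        assert inertias[1] <= inertias[0] + 1e-9

    def test_missing_condition_genes_excluded(self):
        s = self._summary([[0.5, 0.8, 0.5]] * 10)
        s.iloc[0, 1] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            clusters = cluster_patterns(s, PatternParams(k=3, seed=0))
        assert "g0" not in clusters.index

    def test_fewer_genes_than_k_rejected(self):
        s = self._summary([[0.5, 0.8, 0.5]] * 3)
        with pytest.raises(ValueError, match="k="):
            cluster_patterns(s, PatternParams(k=5, seed=0))


class TestClassifyPatterns:
    @pytest.mark.parametrize(
        "centroid,expected",
        [
            ((0.8, 0.5, 0.78), "Pattern1"),
            ((0.8, 0.5, 0.52), "Pattern2"),
            ((0.5, 0.52, 0.8), "Pattern3"),
            ((0.5, 0.52, 0.55), "unclassified"),
            ((0.2, 0.5, 0.22), "Pattern1"),  # upward HFD shift, reversed
        ],
    )
    def test_centroid_rule(self, centroid, expected):
        assert _label_centroid(*centroid, PatternParams()) == expected

    def test_noise_free_recovery_exhaustive_over_directions(self):
        rows, truth = [], []
        effect = 0.2
        for base in (0.4, 0.6):
            for sign in (+1, -1):
                d = sign * effect
                for label, vec in [
                    ("Pattern1", [base, base + d, base]),
                    ("Pattern2", [base, base + d, base + d]),
                    ("Pattern3", [base, base, base + d]),
                ]:
                    rows.extend([vec] * 5)
                    truth.extend([label] * 5)
        rows.extend([[0.5, 0.5, 0.5]] * 10)
        truth.extend(["unclassified"] * 10)
        s = pd.DataFrame(
            rows, columns=["CD", "HFD", "HFD-CD"],
            index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene"),
        )
        params = PatternParams(k=13, seed=0)
        clusters = cluster_patterns(s, params)
        out = classify_patterns(s, clusters, params)
        assert (out["pattern"] == pd.Series(truth, index=s.index)).all()

    def test_global_shift_invariance(self):
        rng = np.random.default_rng(5)
        vals = np.column_stack(
            [np.full(40, 0.4), np.full(40, 0.6), np.full(40, 0.4)]
        ) + rng.normal(0, 0.01, size=(40, 3))
        idx = pd.Index([f"g{i}" for i in range(40)], name="gene")
        s1 = pd.DataFrame(vals, columns=["CD", "HFD", "HFD-CD"], index=idx)
        s2 = s1 + 0.15
        params = PatternParams(k=3, seed=0)
        p1 = classify_patterns(s1, cluster_patterns(s1, params), params)
        p2 = classify_patterns(s2, cluster_patterns(s2, params), params)
        assert (p1["pattern"] == p2["pattern"]).all()

    def test_labels_partition_clustered_genes(self, small_methylomes):
        from dfatmap import gene_methylation_summary

        tracks, annot, _ = small_methylomes
        s = gene_methylation_summary(tracks, annot)
        params = PatternParams(k=8, seed=0)
        clusters = cluster_patterns(s, params)
        out = classify_patterns(s, clusters, params)
        assert out["pattern"].isin(
            ["Pattern1", "Pattern2", "Pattern3", "unclassified"]
        ).all()
        assert out.index.equals(clusters.index)


class TestGeneSetMethylation:
    def _summary(self):
        return pd.DataFrame(
            {"CD": [0.3, 0.5, 0.7], "HFD": [0.4, 0.6, 0.8], "HFD-CD": [0.3, 0.5, 0.7]},
            index=pd.Index(["g0", "g1", "g2"], name="gene"),
        )

    def test_subset_values(self):
        vals, n = gene_set_methylation(self._summary(), ["g0", "g1"])
        assert n == 2
        assert vals["CD"].tolist() == [0.3, 0.5]

    def test_absent_genes_dropped_and_counted(self):
        vals, n = gene_set_methylation(self._summary(), ["g0", "missing"])
        assert n == 1
        assert vals.index.tolist() == ["g0"]

    def test_full_universe_identity(self):
        s = self._summary()
        vals, n = gene_set_methylation(s, list(s.index))
        pd.testing.assert_frame_equal(vals, s)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="no gene"):
            gene_set_methylation(self._summary(), ["nope"])
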