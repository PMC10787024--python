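import numpy as np
import pandas as pd
import pytest

from palmscan import genome_features as gf, synthetic_data as sim
from palmscan.io_core import ConfigurationError, FeatureRecord, GenomicWindow


def gene(gid, start, end, chrom="chr1", family="PR16"):
    return FeatureRecord(gid, chrom, start, end, "+", "gene", family)


class TestTandemArrays:
    def test_chain_by_hand(self):
        # gaps: 50k, 70k, 180k -> first three chain, fourth is a singleton
        feats = [
            gene("g1", 0, 2_000),
            gene("g2", 52_000, 54_000),
            gene("g3", 124_000, 126_000),
            gene("g4", 306_000, 308_000),
        ]
        arrays, summary = gf.detect_tandem_arrays(feats)
        assert len(arrays) == 1
        assert arrays[0].gene_ids == ("g1", "g2", "g3")
        assert (arrays[0].start, arrays[0].end) == (0, 126_000)
        assert summary["n_arrays"] == 1
        assert summary["fraction_in_arrays"] == pytest.approx(3 / 4)

    def test_single_gene_is_not_an_array(self):
        arrays, summary = gf.detect_tandem_arrays([gene("g1", 0, 2_000)])
        assert arrays == []
        assert summary["min_size"] == 0

    def test_genes_without_family_ignored(self):
        feats = [gene("g1", 0, 2_000), gene("g2", 10_000, 12_000, family=None)]
        arrays, summary = gf.detect_tandem_arrays(feats)
        assert arrays == []
        assert summary["n_family_genes"] == 1

    def test_planted_arrays_recovered(self):
        planted = tuple(
            sim.PlantedArray("chr1", "PR16", n, start)
            for n, start in [(5, 50_000), (3, 400_000), (2, 700_000)]
        )
        singles = tuple(
            ("chr1", "PR16", s) for s in (1_000_000, 1_200_000, 1_400_000, 1_600_000)
        )
        cfg = sim.AnnotationSimConfig(
            chrom_lengths={"chr1": 2_000_000},
            planted_arrays=planted,
            family_singletons=singles,
            seed=1,
        )
        ann = sim.simulate_gene_annotation(cfg)
        arrays, summary = gf.detect_tandem_arrays(ann.features)
        assert sorted(a.size for a in arrays) == [2, 3, 5]
        got = {tuple(a.gene_ids) for a in arrays}
        want = {tuple(ids) for _, _, ids in ann.truth_arrays}
        assert got == want
        assert summary["fraction_in_arrays"] == pytest.approx(10 / 14)

    def test_arrays_partition_their_genes(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(0, 5_000_000, 3_000), 60, replace=False))
        feats = [gene(f"g{k}", int(p), int(p) + 2_000) for k, p in enumerate(pos)]
        arrays, summary = gf.detect_tandem_arrays(feats)
        ids = [g for a in arrays for g in a.gene_ids]
        assert len(ids) == len(set(ids))  # no gene in two arrays
        assert all(a.size >= 2 for a in arrays)
        # order invariance
        arrays2, _ = gf.detect_tandem_arrays(list(reversed(feats)))
        assert arrays2 == arrays

    def test_overlapping_genes_chain(self):
        feats = [gene("g1", 0, 5_000), gene("g2", 3_000, 8_000)]
        arrays, _ = gf.detect_tandem_arrays(feats)
        assert arrays[0].gene_ids == ("g1", "g2")

    def test_per_family_separates_interleaved_families(self):
        feats = [
            gene("a1", 0, 2_000, family="F1"),
            gene("b1", 10_000, 12_000, family="F2"),
            gene("a2", 20_000, 22_000, family="F1"),
            gene("b2", 200_000, 202_000, family="F2"),
        ]
        pooled, _ = gf.detect_tandem_arrays(feats)
        assert pooled[0].gene_ids == ("a1", "b1", "a2")
        split, _ = gf.detect_tandem_arrays(feats, per_family=True)
        assert [a.gene_ids for a in split] == [("a1", "a2")]

    def test_bad_gap_rejected(self):
        with pytest.raises(ConfigurationError):
            gf.detect_tandem_arrays([], max_gap=0)


class TestLandscape:
    def windows(self, n, size=100_000):
        return [GenomicWindow("chr1", k * size, (k + 1) * size) for k in range(n)]

    def test_perfectly_coupled_tracks_have_r_one(self):
        w = self.windows(4)
        genome = {"chr1": "A" * 400_000}
        feats = []
        repeats = []
        for k, n in enumerate([1, 2, 3, 4]):
            for j in range(n):
                mid = k * 100_000 + 10_000 + j * 5_000
                feats.append(gene(f"g{k}_{j}", mid - 500, mid + 500, family=None))
            repeats.append(("chr1", k * 100_000, k * 100_000 + n * 10_000))
        t = gf.landscape_tracks(feats, repeats, genome, w)
        r = t.correlations.loc["gene_density", "repeat_fraction"]
        assert r == pytest.approx(1.0)

    def test_anticorrelated_extra_track(self):
        w = self.windows(4)
        genome = {"chr1": "A" * 400_000}
        feats = [
            gene(f"g{k}_{j}", k * 100_000 + j * 1_000, k * 100_000 + j * 1_000 + 500,
                 family=None)
            for k, n in enumerate([4, 3, 2, 1])
            for j in range(n)
        ]
        extra = {("chr1", k * 100_000): float(k) for k in range(4)}
        t = gf.landscape_tracks(feats, [], genome, w, extra_track=extra)
        assert t.correlations.loc["gene_density", "extra"] == pytest.approx(-1.0)

    def test_repeat_union_matches_per_bp_brute_force(self):
        rng = np.random.default_rng(3)
        L = 10_000
        intervals = []
        for _ in range(30):
            s = int(rng.integers(0, L - 1))
            e = int(rng.integers(s + 1, L + 1))
            intervals.append((s, e))
        for start, end in [(0, L), (2_000, 7_000), (9_000, 10_000)]:
            mask = np.zeros(L, dtype=bool)
            for s, e in intervals:
                mask[s:e] = True
            want = int(mask[start:end].sum())
            assert gf._union_coverage(intervals, start, end) == want

    def test_simulated_gene_repeat_anticorrelation(self):
        n_win = 30
        rng = np.random.default_rng(4)
        rep = np.linspace(0.1, 0.9, n_win)
        genes = np.round(20 * (1 - rep)).astype(int)
        cfg = sim.AnnotationSimConfig(
            chrom_lengths={"chr1": n_win * 100_000},
            gene_counts={"chr1": genes.tolist()},
            repeat_fraction={"chr1": rep.tolist()},
            seed=5,
        )
        ann = sim.simulate_gene_annotation(cfg)
        w = [
            GenomicWindow("chr1", k * 100_000, (k + 1) * 100_000)
            for k in range(n_win)
        ]
        t = gf.landscape_tracks(ann.features, ann.repeats, ann.genome, w)
        r = t.correlations.loc["gene_density", "repeat_fraction"]
        assert r == pytest.approx(-1.0, abs=0.05)

    def test_missing_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            gf.landscape_tracks([], [], {}, self.windows(1))


class TestChimeraDetection:
    def make_set(self, lgs, offsets=None, length=1_000_000):
        if offsets is None:
            offsets = [20_000 + 80_000 * k for k in range(len(lgs))]
        return gf.ContigMarkerSet("ctg", tuple(offsets), tuple(lgs), length)

    def test_uniform_contig_not_chimeric(self):
        (v,) = gf.detect_chimeras([self.make_set(["LG1"] * 10)])
        assert not v.is_chimeric
        assert v.split_offsets == ()

    def test_six_six_contig_split_at_gap_midpoint(self):
        offsets = [k * 80_000 for k in range(6)] + [480_000 + k * 80_000 for k in range(6)]
        ms = self.make_set(["LG1"] * 6 + ["LG2"] * 6, offsets)
        (v,) = gf.detect_chimeras([ms])
        assert v.is_chimeric
        assert v.lg_counts == {"LG1": 6, "LG2": 6}
        # split midway between last LG1 marker (400k) and first LG2 (480k)
        assert v.split_offsets == (440_000,)

    def test_minority_below_five_is_not_chimeric(self):
        (v,) = gf.detect_chimeras([self.make_set(["LG1"] * 10 + ["LG2"] * 3)])
        assert not v.is_chimeric

    def test_five_markers_each_is_chimeric(self):
        (v,) = gf.detect_chimeras([self.make_set(["LG1"] * 5 + ["LG2"] * 5)])
        assert v.is_chimeric

    def test_stray_third_group_ignored(self):
        lgs = ["LG1"] * 6 + ["LG3"] + ["LG2"] * 6
        (v,) = gf.detect_chimeras([self.make_set(lgs)])
        assert v.is_chimeric
        assert len(v.split_offsets) == 1

    def test_recovery_from_simulated_map_with_noise(self):
        plans = tuple(
            sim.ChimeraPlan(f"contig{k:03d}", (7, 7), ("LG1", "LG2"))
            for k in range(4)
        )
        cfg = sim.LinkageSimConfig(
            n_contigs=100, markers_per_contig=12, chimera_plans=plans,
            noise_rate=0.05, seed=6,
        )
        df, truth = sim.simulate_linkage_markers(cfg)
        sets = gf.marker_sets_from_frame(
            df, {c: cfg.contig_length for c in df["contig"].unique()}
        )
        verdicts = gf.detect_chimeras(sets)
        flagged = {v.contig for v in verdicts if v.is_chimeric}
        planted = {p.contig for p in plans}
        assert flagged == planted
        for v in verdicts:
            if v.contig in planted:
                (boundary,) = truth[v.contig]
                # a noise-flipped marker next to the boundary can displace the
                # split by up to roughly one marker spacing
                assert any(abs(s - boundary) <= 100_000 for s in v.split_offsets)


class TestSplitContigs:
    def test_non_chimeric_contig_passes_through(self):
        v = gf.ChimeraVerdict("c1", False, {"LG1": 10}, ())
        pieces, lift = gf.split_contigs([v], {"c1": "ACGTACGT"})
        assert pieces == {"c1": "ACGTACGT"}
        assert lift.iloc[0].tolist() == ["c1", "c1", 0, 8]

    def test_split_pieces_reassemble_source(self):
        seq = "A" * 440 + "C" * 560
        v = gf.ChimeraVerdict("c1", True, {}, (440,))
        pieces, lift = gf.split_contigs([v], {"c1": seq})
        assert pieces["c1.1"] == "A" * 440
        assert pieces["c1.2"] == "C" * 560
        assert pieces["c1.1"] + pieces["c1.2"] == seq
        assert lift["source_end"].tolist() == [440, 1000]

    def test_out_of_bounds_split_rejected(self):
        v = gf.ChimeraVerdict("c1", True, {}, (50,))
        with pytest.raises(ConfigurationError):
            gf.split_contigs([v], {"c1": "ACGT"})

    def test_multiple_splits(self):
        v = gf.ChimeraVerdict("c1", True, {}, (3, 7))
        pieces, _ = gf.split_contigs([v], {"c1": "AAACCCCTTT"})
        assert [pieces[f"c1.{k}"] for k in (1, 2, 3)] == ["AAA", "CCCC", "TTT"]
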