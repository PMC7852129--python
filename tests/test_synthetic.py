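"""Generator guarantees: determinism, planted features, read statistics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from misasm import synthetic as syn


def hamming_identity(a: str, b: str) -> float:
    """Direct alignment oracle for equal-length duplicate copies."""
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


class TestBuildTruthGenome:
    def test_length_conservation_no_features(self):
        spec = syn.GenomeSpec(chrom_lengths={"chr1": 5000}, seed=1)
        t = syn.build_truth_genome(spec)
        assert len(t.seqs["chr1"]) == 5000
        assert set(t.seqs["chr1"]) <= set("ACGT")

    def test_tandem_copies_are_near_identical(self):
        spec = syn.GenomeSpec(
            chrom_lengths={"chr1": 10_000},
            tandem_clusters=[syn.TandemCluster("td0", "chr1", 2000, 1000, 2)],
            seed=2,
        )
        t = syn.build_truth_genome(spec)
        c0 = t.seqs["chr1"][2000:3000]
        c1 = t.seqs["chr1"][3000:4000]
        assert hamming_identity(c0, c1) >= 95.0
        assert hamming_identity(c0, c1) < 100.0  # mutations actually applied

    def test_deterministic_per_seed(self):
        spec = syn.demo_spec(seed=5, n_chroms=1, chrom_length=60_000)
        a = syn.build_truth_genome(spec)
        b = syn.build_truth_genome(spec)
        assert a.seqs == b.seqs
        pd.testing.assert_frame_equal(a.duplicates, b.duplicates)

    def test_overlapping_writers_rejected(self):
        spec = syn.GenomeSpec(
            chrom_lengths={"chr1": 10_000},
            tandem_clusters=[
                syn.TandemCluster("td0", "chr1", 1000, 500, 2),
                syn.TandemCluster("td1", "chr1", 1500, 500, 2),
            ],
            seed=0,
        )
        with pytest.raises(syn.GenomeSpecError, match="td0.*td1"):
            syn.build_truth_genome(spec)

    def test_out_of_bounds_rejected(self):
        spec = syn.GenomeSpec(
            chrom_lengths={"chr1": 1000},
            gap_events=[("chr1", 500, 2000)],
        )
        with pytest.raises(syn.GenomeSpecError, match="bounds"):
            spec.validate()


class TestDeriveCollapsed:
    def test_local_collapse_gets_m2_and_rd_k(self):
        spec = syn.GenomeSpec(
            chrom_lengths={"chr1": 10_000},
            tandem_clusters=[syn.TandemCluster("td0", "chr1", 2000, 1000, 2)],
            collapse_events=["td0"],
            seed=2,
        )
        t = syn.build_truth_genome(spec)
        c = syn.derive_collapsed_assembly(t)
        assert len(c.seqs["chr1"]) == 9000  # one 1 kb copy removed
        seg = c.labels.segments
        m2 = seg[seg.category == "M2"]
        assert len(m2) == 1
        assert m2.expected_rd.iloc[0] == 2.0
        assert (m2.end - m2.start).iloc[0] == 1000

    def test_no_events_identity_case(self):
        spec = syn.GenomeSpec(chrom_lengths={"chr1": 8000}, seed=3)
        t = syn.build_truth_genome(spec)
        c = syn.derive_collapsed_assembly(t)
        assert c.seqs == t.seqs
        seg = c.labels.segments
        assert set(seg.category) == {"C1"}
        assert (seg.expected_rd == 1.0).all()

    def test_interchrom_collapse_gets_m3(self):
        spec = syn.GenomeSpec(
            chrom_lengths={"chr1": 10_000, "chr2": 10_000},
            interchrom_pairs=[syn.InterchromPair("ic0", "chr1", 2000, "chr2", 5000, 1500)],
            collapse_events=["ic0"],
            seed=4,
        )
        t = syn.build_truth_genome(spec)
        c = syn.derive_collapsed_assembly(t)
        seg = c.labels.segments
        m3 = seg[seg.category == "M3"]
        assert len(m3) == 1 and m3.chrom.iloc[0] == "chr1"
        assert m3.expected_rd.iloc[0] == 2.0
        assert len(c.seqs["chr2"]) == 8500

    def test_unknown_collapse_rejected(self):
        spec = syn.GenomeSpec(chrom_lengths={"chr1": 5000}, seed=0)
        t = syn.build_truth_genome(spec)
        with pytest.raises(syn.GenomeSpecError):
            syn.derive_collapsed_assembly(t, collapse_events=["nope"])

    def test_gap_becomes_n_run_rd0(self):
        spec = syn.GenomeSpec(
            chrom_lengths={"chr1": 5000}, gap_events=[("chr1", 1000, 2000)], seed=0
        )
        t = syn.build_truth_genome(spec)
        c = syn.derive_collapsed_assembly(t)
        assert c.seqs["chr1"][1000:2000] == "N" * 1000
        gap = c.labels.segments.query("category == 'gap'")
        assert gap.expected_rd.iloc[0] == 0.0


class TestSimulateReads:
    def test_poisson_mean_and_variance(self):
        spec = syn.GenomeSpec(chrom_lengths={"chr1": 1_000_000}, seed=8)
        t = syn.build_truth_genome(spec)
        seg = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1_000_000], "expected_rd": [1.0]}
        )
        p = syn.simulate_reads(t.seqs, seg, 46, 100, seed=8)
        counts = np.bincount(p["start"] // 100, minlength=10_000)
        # >= 10^4 bins: Poisson(46) oracle for mean and variance
        assert counts.mean() == pytest.approx(46, rel=0.02)
        assert counts.var() == pytest.approx(46, rel=0.10)

    def test_read_conservation(self, demo):
        non_n = sum(s.count("A") + s.count("C") + s.count("G") + s.count("T")
                    for s in demo.collapsed.seqs.values())
        # collapsed tracts carry extra expected RD; account for it
        seg = demo.collapsed.labels.segments
        expected_bases = sum(
            (r.end - r.start) * r.expected_rd for r in seg.itertuples()
        )
        expected = expected_bases / demo.spec.read_length * demo.spec.coverage / 100 * 100
        assert len(demo.placements) == pytest.approx(expected, rel=0.01)
        assert non_n > 0

    def test_zero_reads_in_gap(self, demo):
        seg = demo.collapsed.labels.segments
        for g in seg[seg.category == "gap"].itertuples():
            inside = demo.placements[
                (demo.placements.chrom == g.chrom)
                & (demo.placements.start >= g.start)
                & (demo.placements.start < g.end)
            ]
            assert len(inside) == 0

    def test_no_gc_bias_means_no_gc_correlation(self):
        spec = syn.GenomeSpec(chrom_lengths={"chr1": 500_000}, gc=0.4, seed=9)
        t = syn.build_truth_genome(spec)
        seg = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500_000], "expected_rd": [1.0]}
        )
        p = syn.simulate_reads(t.seqs, seg, 46, 100, gc_bias=0.0, seed=9)
        counts = np.bincount(p["start"] // 100, minlength=5000).astype(float)
        arr = np.frombuffer(t.seqs["chr1"].encode(), np.uint8)
        gc = np.isin(arr, np.frombuffer(b"GC", np.uint8)).reshape(5000, 100).mean(axis=1)
        obs = abs(sps.pearsonr(counts, gc)[0])
        # permutation oracle for the null scale of |r|
        rng = np.random.default_rng(0)
        null = [abs(sps.pearsonr(rng.permutation(counts), gc)[0]) for _ in range(200)]
        assert obs <= np.quantile(null, 0.99)

    def test_gc_bias_induces_correlation(self):
        spec = syn.GenomeSpec(chrom_lengths={"chr1": 300_000}, gc=0.4, seed=9)
        t = syn.build_truth_genome(spec)
        seg = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [300_000], "expected_rd": [1.0]}
        )
        p = syn.simulate_reads(t.seqs, seg, 46, 100, gc_bias=8.0, seed=9)
        counts = np.bincount(p["start"] // 100, minlength=3000).astype(float)
        arr = np.frombuffer(t.seqs["chr1"].encode(), np.uint8)
        gc = np.isin(arr, np.frombuffer(b"GC", np.uint8)).reshape(3000, 100).mean(axis=1)
        assert sps.pearsonr(counts, gc)[0] < -0.1

    def test_read_longer_than_chromosome_rejected(self):
        spec = syn.GenomeSpec(chrom_lengths={"chr1": 50}, seed=0)
        t = syn.build_truth_genome(spec)
        seg = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50], "expected_rd": [1.0]})
        with pytest.raises(ValueError, match="read length"):
            syn.simulate_reads(t.seqs, seg, 10, 100, seed=0)

    def test_deterministic_per_seed(self):
        spec = syn.GenomeSpec(chrom_lengths={"chr1": 20_000}, seed=1)
        t = syn.build_truth_genome(spec)
        seg = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [20_000], "expected_rd": [1.0]})
        a = syn.simulate_reads(t.seqs, seg, 10, 100, seed=42)
        b = syn.simulate_reads(t.seqs, seg, 10, 100, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_multimap_only_from_retained_duplicates(self, demo):
        seg = demo.collapsed.labels.segments
        dup = seg[seg.category.isin(["C2", "C3"])]
        mm = demo.placements[demo.placements.multimap == 1]
        for r in mm.itertuples():
            hit = dup[(dup.chrom == r.chrom) & (dup.start <= r.start) & (r.start < dup.end)]
            assert len(hit) == 1


class TestEmitCoords:
    def test_collapsed_cluster_yields_two_subject_blocks(self):
        spec = syn.GenomeSpec(
            chrom_lengths={"chr1": 10_000},
            tandem_clusters=[syn.TandemCluster("td0", "chr1", 2000, 1000, 2)],
            collapse_events=["td0"],
            seed=2,
        )
        c = syn.derive_collapsed_assembly(syn.build_truth_genome(spec))
        b = c.labels.blocks
        dup_blocks = b[(b.qstart == 2000) & (b.qend == 3000)]
        assert len(dup_blocks) == 2
        assert (dup_blocks.identity >= 95).all()

    def test_untouched_chromosome_single_full_block(self):
        spec = syn.GenomeSpec(chrom_lengths={"chr1": 5000}, seed=1)
        c = syn.derive_collapsed_assembly(syn.build_truth_genome(spec))
        b = c.labels.blocks
        assert len(b) == 1
        assert (b.qstart.iloc[0], b.qend.iloc[0], b.identity.iloc[0]) == (0, 5000, 100.0)

    def test_roundtrip_through_parse_coords(self, demo):
        from misasm.misassembly import parse_coords

        coords = syn.emit_alignment_coords(demo.collapsed)
        back = parse_coords(coords)
        orig = demo.collapsed.labels.blocks.reset_index(drop=True)
        for col in ["qchrom", "qstart", "qend", "schrom", "sstart", "send", "orient"]:
            assert list(back[col]) == list(orig[col])
        assert np.allclose(back.identity, orig.identity)
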