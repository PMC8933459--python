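"""Generator checks: planted structure must be recoverable from the data."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import nucleodomain as nd
from nucleodomain.simulate import _nb_draw, design_paired_layouts


class TestGenome:
    def test_degenerate_spacing_yields_one_fragment_per_chromosome(self, tmp_path):
        cfg = nd.SimConfig(chrom_lengths=[("c1", 200_000), ("c2", 150_000)],
                           gatc_spacing_mean=100_000_000, rdna_unit_length=5_000,
                           domain_layout=[], seed=1)
        nd.simulate_genome(cfg, tmp_path)
        fm = nd.build_gatc_fragments(str(tmp_path / "genome.fa"))
        assert fm.n_fragments == 2

    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        cfg = nd.SimConfig(chrom_lengths=[("c1", 300_000)], domain_layout=[],
                           rdna_unit_length=10_000, seed=5)
        nd.simulate_genome(cfg, tmp_path / "a")
        nd.simulate_genome(cfg, tmp_path / "b")
        assert (tmp_path / "a/genome.fa").read_bytes() == \
            (tmp_path / "b/genome.fa").read_bytes()

    def test_motif_count_matches_configured_spacing(self, small_study):
        # renewal process with mean gap 500 bp: count within 3 SD of L/500
        fm = small_study.fragments
        for chrom, size in small_study.truth.genome.sizes.items():
            n_motifs = fm.n_fragments_chrom(chrom) - 1
            expected = size / small_study.cfg.gatc_spacing_mean
            assert abs(n_motifs - expected) < 3 * np.sqrt(expected)

    def test_rdna_interval_terminates_last_chromosome(self, small_study):
        chrom, start, end = small_study.truth.rdna_interval
        assert chrom == "chr3"
        assert end == small_study.truth.genome.sizes["chr3"]
        assert end - start == small_study.cfg.rdna_unit_length

    def test_chromosome_shorter_than_rdna_unit_rejected(self):
        with pytest.raises(ValueError, match="shorter than"):
            nd.SimConfig(chrom_lengths=[("c1", 10_000)],
                         rdna_unit_length=50_000, domain_layout=[])

    def test_overlapping_layout_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            nd.SimConfig(domain_layout=[
                ("chr1", 0, 200_000, "NAD-only"),
                ("chr1", 100_000, 300_000, "LAD-only")])


class TestDamid:
    def test_null_enrichment_gives_zero_mean_ratio(self, small_study):
        from nucleodomain.damid import FragmentCounts
        cfg = replace(small_study.cfg, damid_enrichment=1.0,
                      damid_depth=2_000_000)
        truth = nd.SimTruth(small_study.truth.genome, cfg,
                            small_study.truth.rdna_interval)
        nols, dam = nd.simulate_damid(truth, small_study.fragments, seed=3)
        sc = nd.damid_ratio(FragmentCounts(small_study.fragments, nols),
                            FragmentCounts(small_study.fragments, dam))
        track = nd.bin_track(sc, cfg.bin_size)
        assert abs(np.mean(track.unmasked_values())) < 0.05

    def test_enrichment_recovered_as_log2_group_difference(self, small_study):
        from nucleodomain.damid import FragmentCounts
        cfg = replace(small_study.cfg, damid_depth=2_000_000)  # enrichment 4
        truth = nd.SimTruth(small_study.truth.genome, cfg,
                            small_study.truth.rdna_interval)
        nols, dam = nd.simulate_damid(truth, small_study.fragments, seed=4)
        sc = nd.damid_ratio(FragmentCounts(small_study.fragments, nols),
                            FragmentCounts(small_study.fragments, dam))
        track = nd.bin_track(sc, cfg.bin_size)
        diff = []
        for chrom in truth.genome.names:
            starts, ends = track.bin_bounds(chrom)
            mids = (starts + ends) // 2
            in_nad = truth.nad_truth.contains_points(
                np.full(len(mids), chrom, dtype=object), mids)
            um = ~track.mask[chrom]
            diff.append((track.values[chrom][um & in_nad],
                         track.values[chrom][um & ~in_nad]))
        inside = np.concatenate([d[0] for d in diff])
        outside = np.concatenate([d[1] for d in diff])
        assert inside.mean() - outside.mean() == pytest.approx(2.0, abs=0.1)

    def test_zero_dispersion_limit_is_poisson(self):
        rng = np.random.default_rng(0)
        mu = np.full(200_000, 10.0)
        x = _nb_draw(rng, mu, 0.0)
        assert x.var() / x.mean() == pytest.approx(1.0, abs=0.05)
        y = _nb_draw(rng, mu, 0.5)
        # var = mu + 0.5 mu^2 = 60 -> index of dispersion 6
        assert y.var() / y.mean() == pytest.approx(6.0, rel=0.1)

    def test_empty_fragment_map_rejected(self, small_study):
        class Empty:
            n_fragments = 0
        with pytest.raises(ValueError, match="empty fragment map"):
            nd.simulate_damid(small_study.truth, Empty())

    def test_determinism(self, small_study):
        a = nd.simulate_damid(small_study.truth, small_study.fragments, seed=9)
        b = nd.simulate_damid(small_study.truth, small_study.fragments, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestHicPairs:
    def test_distance_decay_slope_matches_alpha(self, small_study, tmp_path):
        cfg = replace(small_study.cfg, hic_rdna_boost=1.0,
                      hic_quintile1_boost=1.0, hic_compartment_boost=1.0,
                      hic_rdna_fraction=0.0, hic_decay_alpha=1.0,
                      hic_n_pairs=300_000)
        truth = nd.SimTruth(small_study.truth.genome, cfg,
                            small_study.truth.rdna_interval)
        pairs = nd.simulate_hic_pairs(truth, tmp_path / "p.txt", seed=2)
        cis = pairs[pairs.chrom1 == pairs.chrom2]
        s = np.abs(cis.pos2 - cis.pos1).to_numpy()
        edges = np.geomspace(10_000, 2_000_000, 15)
        hist, _ = np.histogram(s, bins=edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        density = hist / np.diff(edges)
        slope = np.polyfit(np.log(centers), np.log(density), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_rdna_boost_recovered_as_rate_ratio(self, small_study, tmp_path):
        cfg = replace(small_study.cfg, hic_rdna_boost=5.0,
                      hic_quintile1_boost=1.0, hic_rdna_fraction=0.5,
                      hic_n_pairs=100_000)
        truth = nd.SimTruth(small_study.truth.genome, cfg,
                            small_study.truth.rdna_interval)
        pairs = nd.simulate_hic_pairs(truth, tmp_path / "p.txt", seed=3)
        idx = nd.GenomeIndex(truth.genome, truth.rdna_interval)
        c1 = pairs.chrom1.to_numpy(dtype=object)
        c2 = pairs.chrom2.to_numpy(dtype=object)
        anchored = idx.in_rdna(c1, pairs.pos1.to_numpy()) \
            ^ idx.in_rdna(c2, pairs.pos2.to_numpy())
        other_chrom = np.where(idx.in_rdna(c1, pairs.pos1.to_numpy()), c2, c1)
        other_pos = np.where(idx.in_rdna(c1, pairs.pos1.to_numpy()),
                             pairs.pos2, pairs.pos1)
        in_nad = truth.nad_truth.contains_points(other_chrom[anchored],
                                                 other_pos[anchored])
        nad_bp = truth.nad_truth.total_bp
        non_bp = truth.genome.total_bp - nad_bp - cfg.rdna_unit_length
        rate_ratio = (in_nad.sum() / nad_bp) / ((~in_nad).sum() / non_bp)
        assert rate_ratio == pytest.approx(5.0, rel=0.2)

    def test_zero_pairs_rejected(self, small_study):
        cfg = replace(small_study.cfg, hic_n_pairs=0)
        truth = nd.SimTruth(small_study.truth.genome, cfg,
                            small_study.truth.rdna_interval)
        with pytest.raises(ValueError, match="hic_n_pairs"):
            nd.simulate_hic_pairs(truth, "/dev/null")


class TestChip:
    def test_state_mean_ratio_recovered(self, small_study, tmp_path):
        paths = nd.simulate_chip_tracks(small_study.truth, tmp_path,
                                        marks=["H3K9me2"], seed=6)
        track = nd.StepTrack.read_bedgraph(paths["H3K9me2"],
                                           small_study.truth.genome)
        means = {}
        for label in ("NAD/LAD", "LAD-only"):
            dset = small_study.truth.layer(label)
            df, _ = nd.domain_signal(track, dset)
            means[label] = df["Mean"].mean()
        # configured means: NAD/LAD 4.0, LAD-only 2.0
        assert means["NAD/LAD"] / means["LAD-only"] == pytest.approx(2.0, rel=0.1)

    def test_missing_label_mean_rejected(self, small_study, tmp_path):
        cfg = replace(small_study.cfg,
                      chip_state_means={"bad": {"NAD-only": 1.0}})
        truth = nd.SimTruth(small_study.truth.genome, cfg,
                            small_study.truth.rdna_interval)
        with pytest.raises(KeyError, match="missing mean"):
            nd.simulate_chip_tracks(truth, tmp_path)

    def test_zero_mean_mark_gives_zero_track(self, small_study, tmp_path):
        zero = {lab: 0.0 for lab in ("NAD-only", "NAD/LAD", "LAD-only", "none")}
        cfg = replace(small_study.cfg, chip_state_means={"null": zero})
        truth = nd.SimTruth(small_study.truth.genome, cfg,
                            small_study.truth.rdna_interval)
        paths = nd.simulate_chip_tracks(truth, tmp_path, seed=1)
        track = nd.StepTrack.read_bedgraph(paths["null"], truth.genome)
        assert track.total == 0.0


class TestExpression:
    def test_nad_genes_mostly_below_one_rpkm(self, small_study):
        genes, libsize = nd.simulate_expression(small_study.truth, 3000, seed=8)
        table = nd.compute_rpkm(genes, libsize)
        nad = table[table.TruthLabel.isin(["NAD-only", "NAD/LAD"])]
        assert len(nad) > 50
        assert (nad.RPKM < 1).mean() >= 0.70

    def test_determinism(self, small_study):
        a, _ = nd.simulate_expression(small_study.truth, 100, seed=2)
        b, _ = nd.simulate_expression(small_study.truth, 100, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_gene_count_rejected(self, small_study):
        with pytest.raises(ValueError):
            nd.simulate_expression(small_study.truth, 0)


def test_paired_layout_designed_fractions():
    """The default architecture encodes the headline overlap statistics."""
    l1, l2 = design_paired_layouts()
    g = nd.Genome({"chr1": 30_000_000, "chr2": 30_000_000, "chr3": 30_045_000})
    nad = nd.DomainSet.from_intervals(
        [iv for iv in l1 if iv[3] in ("NAD-only", "NAD/LAD")], g)
    lad = nd.DomainSet.from_intervals(
        [iv for iv in l1 if iv[3] in ("NAD/LAD", "LAD-only")], g)
    assert nd.overlap_fraction(nad, lad) == pytest.approx(52.83, abs=0.01)
    assert nd.overlap_fraction(lad, nad) == pytest.approx(40.0, abs=0.01)
    # 78% of cell-1-specific NAD-only bp is outside both compartments of cell 2
    nad_only1 = nd.DomainSet.from_intervals(
        [iv for iv in l1 if iv[3] == "NAD-only"], g)
    covered2 = nd.DomainSet.from_intervals(
        [iv for iv in l2 if iv[3] != "none"], g)
    outside = nad_only1.subtract(covered2).total_bp / nad_only1.total_bp
    assert outside == pytest.approx(0.78, abs=1e-9)
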