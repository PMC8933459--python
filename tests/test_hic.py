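"""rDNA contact extraction, KR balancing, replicate commonality and
positional distributions."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import nucleodomain as nd
from nucleodomain.genome import write_fasta
from nucleodomain.hic import (GenomeIndex, append_rdna, kr_balance,
                              extract_rdna_contacts, filter_blacklist,
                              common_contacts, quintile_distribution,
                              per_chromosome_summary, read_pairs,
                              read_juicer_dump, ContactTable)


@pytest.fixture
def index():
    genome = nd.Genome({"chr1": 100_000, "chr2": 100_000, "chr12": 120_000})
    return GenomeIndex(genome, ("chr12", 100_000, 120_000))


def _pairs(rows):
    return pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])


class TestAppendRdna:
    def test_unit_appended_and_coordinates_preserved(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"chr1": "ACGT" * 25, "chr12": "ACGT" * 10})
        write_fasta(tmp_path / "u.fa", {"rDNA": "GGCC" * 5})
        idx = append_rdna(tmp_path / "g.fa", tmp_path / "u.fa", "chr12",
                          tmp_path / "out.fa")
        assert idx.genome.sizes["chr12"] == 40 + 20
        assert idx.rdna_interval == ("chr12", 40, 60)
        assert idx.genome.sizes["chr1"] == 100  # untouched
        from pyfaidx import Fasta
        out = Fasta(str(tmp_path / "out.fa"))
        assert str(out["chr12"][:40]) == "ACGT" * 10

    def test_empty_unit_rejected(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"chr12": "ACGT" * 10})
        (tmp_path / "u.fa").write_text(">rDNA\n\n")
        with pytest.raises(Exception):
            append_rdna(tmp_path / "g.fa", tmp_path / "u.fa", "chr12",
                        tmp_path / "out.fa")

    def test_double_append_detected(self, tmp_path):
        write_fasta(tmp_path / "g.fa", {"chr12": "ACGT" * 10})
        write_fasta(tmp_path / "u.fa", {"rDNA": "GGCC" * 5})
        append_rdna(tmp_path / "g.fa", tmp_path / "u.fa", "chr12",
                    tmp_path / "once.fa")
        with pytest.raises(ValueError, match="already terminal"):
            append_rdna(tmp_path / "once.fa", tmp_path / "u.fa", "chr12",
                        tmp_path / "twice.fa")


class TestKrBalance:
    def test_two_by_two_system(self):
        # A = [[2,1],[1,2]]: by symmetry both scale factors are equal and
        # solve x^2 * 3 = 1
        res = kr_balance(np.array([[2.0, 1.0], [1.0, 2.0]]))
        assert res.scale[0] == pytest.approx(res.scale[1])
        assert res.scale[0] == pytest.approx(1 / np.sqrt(3), rel=1e-6)
        bal = res.balanced(np.array([[2.0, 1.0], [1.0, 2.0]]))
        assert bal.sum(axis=1) == pytest.approx([1.0, 1.0])

    def test_random_matrix_row_sum_cv(self):
        rng = np.random.default_rng(42)
        A = rng.random((200, 200))
        A = A + A.T
        res = kr_balance(A)
        rs = res.balanced(A).sum(axis=1)
        assert rs.std() / rs.mean() < 1e-6

    def test_permutation_invariance(self):
        rng = np.random.default_rng(43)
        A = rng.random((120, 120))
        A = A + A.T
        perm = rng.permutation(120)
        res = kr_balance(A)
        res_p = kr_balance(A[np.ix_(perm, perm)])
        ratio = res_p.scale / res.scale[perm]
        assert np.nanstd(ratio) / np.nanmean(ratio) < 1e-8

    def test_sparse_rows_masked(self):
        A = np.diag(np.ones(20))
        A[0, :] = A[:, 0] = 1.0  # row 0 dense, others ~2 nonzero < 10% of 20
        res = kr_balance(A, min_nonzero_frac=0.2)
        assert res.mask[1:].all() and not res.mask[0]

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            kr_balance(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_all_zero_all_masked(self):
        res = kr_balance(np.zeros((10, 10)))
        assert res.mask.all()


class TestExtraction:
    def test_exactly_one_end_rule(self, index):
        pairs = _pairs([
            ("chr1", 10, "chr2", 20),            # both outside
            ("chr12", 105_000, "chr12", 110_000),  # both inside
            ("chr12", 105_000, "chr1", 4_999),
            ("chr12", 105_000, "chr1", 5_000),
            ("chr1", 12_345, "chr12", 119_999),
        ])
        t = extract_rdna_contacts(pairs, index, bin_size=5_000)
        assert t.n_retained == 3
        assert t.n_both_outside == 1
        assert t.n_both_inside == 1
        got = t.bins.set_index("Start")["RawCount"]
        assert got[0] == 1 and got[5_000] == 1 and got[10_000] == 1

    def test_pair_conservation(self, index):
        rng = np.random.default_rng(0)
        pairs = _pairs([("chr1", int(a), "chr12", int(b))
                        for a, b in zip(rng.integers(0, 100_000, 500),
                                        rng.integers(0, 120_000, 500))])
        t = extract_rdna_contacts(pairs, index)
        assert t.n_retained + t.n_both_outside + t.n_both_inside == 500

    def test_malformed_lines_counted(self, index, tmp_path):
        path = tmp_path / "p.pairs"
        path.write_text("r1\tchr12\t105000\tchr1\t100\t+\t-\n"
                        "broken line\n"
                        "r2\tchr12\tnotanint\tchr1\t100\t+\t-\n")
        with pytest.warns(UserWarning, match="malformed"):
            t = extract_rdna_contacts(str(path), index)
        assert t.n_malformed == 2
        assert t.n_retained == 1

    def test_balancing_weights_applied(self, index):
        pairs = _pairs([("chr12", 105_000, "chr1", 100)] * 3)
        weights = {"chr1": np.full(20, 2.5)}
        t = extract_rdna_contacts(pairs, index, balancing=weights)
        assert t.bins["Score"].iloc[0] == pytest.approx(3 * 2.5)

    def test_juicer_dump_reader(self, index, tmp_path):
        path = tmp_path / "dump.txt"
        path.write_text("100000 5000 4\n50000 5000 2\n")
        t = read_juicer_dump(path, "chr12", "chr1", index)
        # only the row anchored in an rDNA bin is kept
        assert t.bins["RawCount"].tolist() == [4]
        # anchor-to-anchor rows of a cis dump are excluded
        cis = tmp_path / "cis.txt"
        cis.write_text("100000 110000 9\n100000 50000 3\n")
        t2 = read_juicer_dump(cis, "chr12", "chr12", index)
        assert t2.bins["RawCount"].tolist() == [3]


class TestBlacklist:
    def _table(self, index, starts):
        df = pd.DataFrame({"Chromosome": "chr1",
                           "Start": starts,
                           "End": [s + 5_000 for s in starts],
                           "RawCount": 1, "Score": 1.0})
        return ContactTable(df, 5_000, index.genome)

    def test_empty_blacklist_no_change(self, index):
        t = self._table(index, [0, 5_000])
        bl = nd.DomainSet.from_intervals([], index.genome)
        out, removed = filter_blacklist(t, bl)
        assert removed == 0 and out.n_unique == 2

    def test_whole_genome_blacklist_empties_table(self, index):
        t = self._table(index, [0, 5_000])
        bl = nd.DomainSet.from_intervals(
            [(c, 0, s) for c, s in index.genome.sizes.items()], index.genome)
        out, removed = filter_blacklist(t, bl)
        assert out.n_unique == 0 and removed == 2

    def test_single_bp_overlap_removes_bin(self, index):
        t = self._table(index, [0, 5_000, 10_000])
        bl = nd.DomainSet.from_intervals([("chr1", 4_000, 6_000)], index.genome)
        out, removed = filter_blacklist(t, bl)
        assert removed == 2
        assert out.bins["Start"].tolist() == [10_000]


class TestCommonContacts:
    def _table(self, index, records, rep=""):
        df = pd.DataFrame(records, columns=["Chromosome", "Start", "RawCount",
                                            "Score"])
        df["End"] = df["Start"] + 5_000
        df = df[["Chromosome", "Start", "End", "RawCount", "Score"]]
        return ContactTable(df, 5_000, index.genome, rep)

    def test_identical_tables_preserved(self, index):
        t = self._table(index, [("chr1", 0, 3, 1.5), ("chr2", 5_000, 2, 0.7)])
        out, _ = common_contacts([t, t])
        assert out.bins["Score"].tolist() == [1.5, 0.7]

    def test_disjoint_tables_empty(self, index):
        a = self._table(index, [("chr1", 0, 1, 1.0)])
        b = self._table(index, [("chr1", 5_000, 1, 1.0)])
        out, _ = common_contacts([a, b])
        assert out.n_unique == 0

    def test_three_replicates_mean_score(self, index):
        tables = [self._table(index, [("chr1", 0, 1, s)], f"r{s}")
                  for s in (2.0, 4.0, 6.0)]
        out, presence = common_contacts(tables)
        assert out.bins["Score"].iloc[0] == pytest.approx(4.0)
        assert presence.shape[0] == 1

    def test_inconsistent_binning_rejected(self, index):
        a = self._table(index, [("chr1", 0, 1, 1.0)])
        b = ContactTable(a.bins.copy(), 10_000, index.genome)
        with pytest.raises(ValueError, match="inconsistent"):
            common_contacts([a, b])


class TestDistributions:
    def test_all_contacts_in_first_fifth(self, index):
        df = pd.DataFrame({"Chromosome": "chr1",
                           "Start": [0, 5_000, 10_000],
                           "End": [5_000, 10_000, 15_000],
                           "RawCount": 1, "Score": 1.0})
        t = ContactTable(df, 5_000, index.genome)
        per_chrom, agg = quintile_distribution(t, index)
        assert per_chrom.loc["chr1"].tolist() == [1.0, 0, 0, 0, 0]

    def test_proportions_sum_to_one(self, study, hic_pairs):
        idx = GenomeIndex(study.truth.genome, study.truth.rdna_interval)
        t = extract_rdna_contacts(hic_pairs.pairs, idx)
        per_chrom, agg = quintile_distribution(t, idx)
        assert np.allclose(per_chrom.sum(axis=1), 1.0)
        assert 0 <= agg.min() and agg.max() <= 1

    def test_quintile1_boost_monotone(self, small_study, tmp_path):
        props = []
        for k in (1.0, 3.0, 8.0):
            cfg = replace(small_study.cfg, hic_quintile1_boost=k,
                          hic_rdna_boost=1.0, hic_rdna_fraction=1.0,
                          hic_n_pairs=4_000)
            truth = nd.SimTruth(small_study.truth.genome, cfg,
                                small_study.truth.rdna_interval)
            pairs = nd.simulate_hic_pairs(truth, tmp_path / f"p{k}.txt", seed=5)
            idx = GenomeIndex(truth.genome, truth.rdna_interval)
            t = extract_rdna_contacts(pairs, idx)
            _, agg = quintile_distribution(t, idx)
            props.append(agg[0])
        assert props == sorted(props)
        assert props[1] > 0.2

    def test_unique_contact_definition(self, index):
        pairs = _pairs([("chr12", 105_000, "chr1", 100)] * 2
                       + [("chr12", 105_000, "chr2", 100)])
        t = extract_rdna_contacts(pairs, index)
        summary = per_chromosome_summary(t)
        row1 = summary[summary["Chromosome"] == "chr1"].iloc[0]
        assert row1["n_unique"] == 1 and row1["total_raw"] == 2

    def test_rdna_chromosome_ranks_first_with_cis_nads(self, small_study, tmp_path):
        # concentrate planted NADs on the rDNA-bearing chromosome
        layout = [("chr3", 500_000, 2_500_000, "NAD-only")]
        cfg = replace(small_study.cfg, domain_layout=layout,
                      hic_rdna_boost=10.0, hic_quintile1_boost=1.0,
                      hic_rdna_fraction=0.5, hic_n_pairs=20_000)
        truth = nd.SimTruth(small_study.truth.genome, cfg,
                            small_study.truth.rdna_interval)
        pairs = nd.simulate_hic_pairs(truth, tmp_path / "p.txt", seed=6)
        idx = GenomeIndex(truth.genome, truth.rdna_interval)
        t = extract_rdna_contacts(pairs, idx)
        summary = per_chromosome_summary(t)
        assert summary.iloc[0]["Chromosome"] == "chr3"


def test_read_pairs_roundtrip(small_study, tmp_path):
    path = tmp_path / "x.pairs"
    pairs = nd.simulate_hic_pairs(small_study.truth, path, seed=1)
    loaded, malformed = read_pairs(path)
    assert malformed == 0
    assert len(loaded) == len(pairs)
    assert (loaded["pos1"].to_numpy() == pairs["pos1"].to_numpy()).all()
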