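"""SNP extraction and the MAF -> missingness -> LD filter chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vetkey import genotypes as geno

from conftest import make_matrix


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

class TestExtraction:
    def test_toy_ag_site(self):
        loci = {"L1": {
            "s1": ("AAAA", "AAAA"),   # AA at the variable site (pos 1 below)
            "s2": ("AGAA", "AAAA"),   # AG
            "s3": ("AGAA", "AGAA"),   # GG
            "s4": ("ANAA", "AAAA"),   # unresolved -> missing
        }}
        gm = geno.extract_biallelic_snps(loci)
        assert gm.n_snps == 1
        col = gm.values[:, 0]
        order = {s: i for i, s in enumerate(gm.sample_ids)}
        assert col[order["s1"]] == 0
        assert col[order["s2"]] == 1
        assert col[order["s3"]] == 2
        assert np.isnan(col[order["s4"]])
        assert gm.snp_meta["alt"].iloc[0] == "G"

    def test_monomorphic_locus_contributes_nothing(self):
        loci = {"L1": {"a": ("ACGT", "ACGT"), "b": ("ACGT", "ACGT")}}
        assert geno.extract_biallelic_snps(loci).n_snps == 0

    def test_triallelic_site_dropped(self):
        loci = {"L1": {"a": ("A", "A"), "b": ("C", "C"), "c": ("G", "G")}}
        assert geno.extract_biallelic_snps(loci).n_snps == 0

    def test_length_mismatch_skipped_with_log(self, caplog):
        loci = {"bad": {"a": ("ACG", "ACG"), "b": ("AC", "AC")},
                "good": {"a": ("AA", "AA"), "b": ("AT", "AT")}}
        with caplog.at_level("WARNING", logger="vetkey"):
            gm = geno.extract_biallelic_snps(loci)
        assert gm.n_snps == 1
        assert any("length-mismatched" in r.message for r in caplog.records)

    def test_snp_count_matches_site_scan_oracle(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        loci = {}
        for l in range(20):
            ref = rng.choice(bases, size=30)
            aln = {}
            for s in range(8):
                pair = []
                for _ in range(2):
                    seq = ref.copy()
                    muts = rng.random(30) < 0.08
                    seq[muts] = rng.choice(bases, size=int(muts.sum()))
                    pair.append("".join(seq))
                aln[f"s{s}"] = tuple(pair)
            loci[f"L{l}"] = aln
        gm = geno.extract_biallelic_snps(loci)

        # independent per-site scanner: a SNP is a site with exactly two
        # resolved bases observed across all allele copies
        expected = 0
        for aln in loci.values():
            length = len(next(iter(aln.values()))[0])
            for pos in range(length):
                obs = {a[pos] for pair in aln.values() for a in pair}
                if len(obs & set("ACGT")) == 2:
                    expected += 1
        assert gm.n_snps == expected


# ---------------------------------------------------------------------------
# MAF / missingness filters
# ---------------------------------------------------------------------------

class TestFrequencyFilters:
    def test_single_heterozygote_removed(self):
        values = np.zeros((200, 1))
        values[0, 0] = 1  # freq 1/400 = 0.0025 < 0.005
        gm, report = geno.filter_maf(make_matrix(values))
        assert gm.n_snps == 0
        assert report.removed["maf"] == 1

    def test_exact_boundary_retained(self):
        values = np.zeros((200, 1))
        values[0, 0] = 2  # freq 2/400 = 0.005 exactly; rule removes strictly below
        gm, _ = geno.filter_maf(make_matrix(values))
        assert gm.n_snps == 1

    def test_maf_matches_recount_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.binomial(2, rng.uniform(0.0, 0.2, 50), size=(40, 50)).astype(float)
        values[rng.random(values.shape) < 0.1] = np.nan
        gm = make_matrix(values)
        filtered, report = geno.filter_maf(gm, 0.05)
        keep = []
        for j in range(50):
            col = values[:, j]
            col = col[~np.isnan(col)]
            p = col.sum() / (2 * col.size)
            if not min(p, 1 - p) < 0.05:
                keep.append(j)
        assert filtered.n_snps == len(keep)
        report.check()

    def test_missing_twenty_percent_removed_inclusive(self):
        values = np.zeros((10, 2))
        values[:2, 0] = np.nan  # exactly 20% missing -> removed
        gm, report = geno.filter_missingness(make_matrix(values), 0.2)
        assert gm.n_snps == 1
        assert report.removed["missingness"] == 1

    def test_fully_observed_retained(self):
        gm, _ = geno.filter_missingness(make_matrix(np.ones((5, 3))))
        assert gm.n_snps == 3

    def test_missingness_matches_recount_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.binomial(2, 0.3, size=(25, 40)).astype(float)
        values[rng.random(values.shape) < 0.25] = np.nan
        filtered, _ = geno.filter_missingness(make_matrix(values), 0.2)
        expected = sum(np.isnan(values[:, j]).mean() < 0.2 for j in range(40))
        assert filtered.n_snps == expected


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

class TestLdPrune:
    def test_identical_columns_one_removed_seed_dependent(self):
        col = np.array([0., 1., 2., 0., 1., 2.])
        gm = make_matrix(np.column_stack([col, col]))
        out, report = geno.ld_prune(gm, seed=0)
        assert out.n_snps == 1
        assert report.removed["ld"] == 1
        # which SNP survives depends only on the seed
        survivors = {geno.ld_prune(gm, seed=s)[0].snp_meta["position"].iloc[0]
                     for s in range(20)}
        assert survivors == {0, 1}

    def test_exact_half_r2_retained(self):
        x = np.array([0., 0., 2., 2.])
        y = np.array([0., 1., 1., 2.])  # r^2 == 0.5 exactly; rule is strict >
        out, _ = geno.ld_prune(make_matrix(np.column_stack([x, y])))
        assert out.n_snps == 2

    def test_no_surviving_adjacent_pair_above_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.5, size=(60, 30)).astype(float)
        # inject correlated neighbours
        for j in range(0, 30, 3):
            if j + 1 < 30:
                base[:, j + 1] = base[:, j]
        out, _ = geno.ld_prune(make_matrix(base), seed=4)
        for j in range(out.n_snps - 1):
            r2 = geno._pairwise_r2(out.values[:, j], out.values[:, j + 1])
            assert r2 <= 0.5

    def test_idempotence_of_each_filter(self):
        rng = np.random.default_rng(5)
        values = rng.binomial(2, rng.uniform(0.05, 0.5, 60), size=(50, 60)).astype(float)
        values[rng.random(values.shape) < 0.15] = np.nan
        gm = make_matrix(values)
        for fn in (lambda g: geno.filter_maf(g, 0.05),
                   lambda g: geno.filter_missingness(g, 0.2),
                   lambda g: geno.ld_prune(g, seed=9)):
            once, _ = fn(gm)
            twice, report = fn(once)
            assert twice.n_snps == once.n_snps
            assert sum(report.removed.values()) == 0

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_bookkeeping_identity_holds(self, seed):
        rng = np.random.default_rng(seed)
        n, j = rng.integers(4, 20), rng.integers(1, 25)
        values = rng.binomial(2, 0.3, size=(n, j)).astype(float)
        values[rng.random(values.shape) < 0.3] = np.nan
        gm = make_matrix(values)
        _, report = geno.filter_chain(gm, seed=int(seed % 1000))
        report.check()
        assert sum(report.removed.values()) + report.retained == j


# ---------------------------------------------------------------------------
# IO round-trips
# ---------------------------------------------------------------------------

class TestIo:
    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        values = rng.binomial(2, 0.4, size=(6, 8)).astype(float)
        values[0, 0] = np.nan
        gm = make_matrix(values)
        path = tmp_path / "g.csv"
        geno.write_genotype_csv(gm, str(path))
        back = geno.read_genotype_csv(str(path))
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(gm.values))
        np.testing.assert_allclose(np.nan_to_num(back.values), np.nan_to_num(gm.values))
        assert back.sample_ids == gm.sample_ids

    def test_ped_map_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        values = rng.binomial(2, 0.4, size=(5, 7)).astype(float)
        values[2, 3] = np.nan
        gm = make_matrix(values)
        prefix = str(tmp_path / "panel")
        geno.write_ped_map(gm, prefix)
        back = geno.read_ped_map(prefix)
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(gm.values))
        np.testing.assert_allclose(np.nan_to_num(back.values), np.nan_to_num(gm.values))

    def test_rejects_bad_genotype_values(self):
        with pytest.raises(ValueError, match="0, 1, 2 or missing"):
            make_matrix([[0.0, 3.0]])
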