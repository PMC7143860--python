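import numpy as np
import pandas as pd
import pytest

from roh_inbred.genotype_io import (
    MISSING,
    FilterSpec,
    GenotypeDataError,
    GenotypeParseError,
    allele_frequencies,
    filter_snps,
    merge_datasets,
    minor_allele_frequencies,
    read_plink_text,
    read_vcf,
    write_plink_text,
    write_vcf,
)
from roh_inbred.synthetic_data import SimConfig, simulate_cohort

from conftest import make_dataset


def write_plink_pair(tmp_path, map_lines, ped_lines):
    map_path = tmp_path / "x.map"
    ped_path = tmp_path / "x.ped"
    map_path.write_text("".join(l + "\n" for l in map_lines))
    ped_path.write_text("".join(l + "\n" for l in ped_lines))
    return ped_path, map_path


class TestReadPlink:
    def test_single_homozygote_codes_zero(self, tmp_path):
        ped, mp = write_plink_pair(tmp_path, ["1 snp1 0 100"], ["f1 d1 0 0 0 -9 A A"])
        ds = read_plink_text(ped, mp)
        assert ds.samples == ["d1"]
        assert ds.calls.tolist() == [[0]]

    def test_zero_zero_is_missing(self, tmp_path):
        ped, mp = write_plink_pair(tmp_path, ["1 snp1 0 100"], ["f1 d1 0 0 0 -9 0 0"])
        assert read_plink_text(ped, mp).calls.tolist() == [[MISSING]]

    def test_hand_coded_fixture_cell_by_cell(self, tmp_path):
        # 3 samples x 4 SNPs; A/B coding is lexicographic per SNP
        ped, mp = write_plink_pair(
            tmp_path,
            ["1 s1 0 100", "1 s2 0 200", "2 s3 0 50", "2 s4 0 150"],
            [
                "f a 0 0 0 -9  A A  C T  G G  0 0",
                "f b 0 0 0 -9  A C  T T  G T  A A",
                "f c 0 0 0 -9  C C  C T  T T  A C",
            ],
        )
        ds = read_plink_text(ped, mp)
        # s1 alleles {A,C}: AA=0 AC=1 CC=2 ; s2 {C,T}: CT=1 TT=2
        # s3 {G,T}: GG=0 GT=1 TT=2 ; s4 {A,C}: missing, AA=0, AC=1
        expected = [[0, 1, 0, MISSING], [1, 2, 1, 0], [2, 1, 2, 1]]
        assert ds.calls.tolist() == expected
        assert list(ds.snps["allele_a"]) == ["A", "C", "G", "A"]
        assert list(ds.snps["allele_b"]) == ["C", "T", "T", "C"]

    def test_non_autosomal_rows_dropped(self, tmp_path):
        ped, mp = write_plink_pair(
            tmp_path, ["1 s1 0 100", "39 sX 0 200"], ["f d 0 0 0 -9 A A G G"]
        )
        ds = read_plink_text(ped, mp)
        assert ds.n_snps == 1 and ds.snps["snp_id"].iloc[0] == "s1"

    def test_malformed_row_names_line(self, tmp_path):
        ped, mp = write_plink_pair(tmp_path, ["1 s1 0 100"], ["f d 0 0 0 -9 A"])
        with pytest.raises(GenotypeParseError, match=":1"):
            read_plink_text(ped, mp)

    def test_three_alleles_names_snp(self, tmp_path):
        ped, mp = write_plink_pair(
            tmp_path, ["1 s1 0 100"],
            ["f a 0 0 0 -9 A A", "f b 0 0 0 -9 C C", "f c 0 0 0 -9 T T"],
        )
        with pytest.raises(GenotypeDataError, match="s1"):
            read_plink_text(ped, mp)


class TestRoundTrips:
    @pytest.fixture()
    def cohort(self):
        ds, _, _ = simulate_cohort(
            SimConfig(n_offspring=6, seed=5, chromosome_lengths_bp=(2_000_000, 1_000_000),
                      snp_density_per_mb=20)
        )
        return ds

    @staticmethod
    def genotype_labels(ds):
        # genotypes as unordered allele-character pairs, coding-independent
        a = ds.snps["allele_a"].to_numpy()
        b = ds.snps["allele_b"].to_numpy()
        label = {0: lambda j: a[j] + a[j], 1: lambda j: a[j] + b[j],
                 2: lambda j: b[j] + b[j], MISSING: lambda j: "00"}
        return [
            ["".join(sorted(label[int(ds.calls[i, j])](j))) for j in range(ds.n_snps)]
            for i in range(ds.n_samples)
        ]

    def test_plink_round_trip_preserves_genotypes_and_is_stable(self, cohort, tmp_path):
        # PED text stores allele characters, not codes: genotypes must
        # survive exactly, and a second write/read cycle must be the
        # identity on the code matrix
        write_plink_text(cohort, tmp_path / "c.ped", tmp_path / "c.map")
        back = read_plink_text(tmp_path / "c.ped", tmp_path / "c.map")
        assert back.samples == cohort.samples
        assert self.genotype_labels(back) == self.genotype_labels(cohort)
        pd.testing.assert_frame_equal(
            back.snps[["snp_id", "chromosome", "position_bp"]],
            cohort.snps[["snp_id", "chromosome", "position_bp"]],
        )
        write_plink_text(back, tmp_path / "d.ped", tmp_path / "d.map")
        again = read_plink_text(tmp_path / "d.ped", tmp_path / "d.map")
        np.testing.assert_array_equal(again.calls, back.calls)

    def test_vcf_round_trip_exact(self, cohort, tmp_path):
        write_vcf(cohort, tmp_path / "c.vcf")
        back = read_vcf(tmp_path / "c.vcf")
        assert back.samples == cohort.samples
        np.testing.assert_array_equal(back.calls, cohort.calls)


class TestReadVcf:
    HEADER = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1,length=1000000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
    )

    def test_gt_code_map(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            self.HEADER
            + "1\t100\tv1\tA\tC\t.\t.\t.\tGT\t0/1\n"
            + "1\t200\tv2\tA\tC\t.\t.\t.\tGT\t1/1\n"
            + "1\t300\tv3\tA\tC\t.\t.\t.\tGT\t./.\n"
        )
        ds = read_vcf(p)
        assert ds.calls.tolist() == [[1, 2, MISSING]]

    def test_multiallelic_skipped(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            self.HEADER
            + "1\t100\tv1\tA\tT,G\t.\t.\t.\tGT\t0/1\n"
            + "1\t200\tv2\tA\tC\t.\t.\t.\tGT\t0/0\n"
        )
        ds = read_vcf(p)
        assert ds.n_snps == 1 and ds.calls.tolist() == [[0]]

    def test_ref_alt_recoded_lexicographic(self, tmp_path):
        # REF=T ALT=A: allele_a is A, so hom-ref becomes code 2
        p = tmp_path / "a.vcf"
        p.write_text(self.HEADER + "1\t100\tv1\tT\tA\t.\t.\t.\tGT\t0/0\n")
        ds = read_vcf(p)
        assert ds.calls.tolist() == [[2]]
        assert ds.snps["allele_a"].iloc[0] == "A"


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "column, expected",
        [([0, 0, 0], 0.0), ([1, 1], 0.5), ([0, 1, 2, MISSING], 0.5)],
    )
    def test_hand_counts(self, column, expected):
        ds = make_dataset(np.array(column)[:, None])
        assert allele_frequencies(ds)[0] == pytest.approx(expected)

    def test_all_missing_flagged_nan(self):
        ds = make_dataset([[MISSING, 0], [MISSING, 2]])
        freqs = allele_frequencies(ds)
        assert np.isnan(freqs[0]) and freqs[1] == 0.5


class TestFilterSnps:
    def test_maf_boundary_is_exclusive_retain(self):
        # MAF exactly at the threshold is removed
        calls = np.zeros((50, 2), dtype=np.int8)
        calls[0, 0] = 1  # p_B = 1/100 -> MAF 0.01
        calls[:25, 1] = 2  # MAF 0.5
        ds = make_dataset(calls)
        kept = filter_snps(ds, FilterSpec(0.01, 0.99))
        assert list(kept.snps["snp_id"]) == ["snp1"]

    def test_clean_common_snp_retained(self):
        ds = make_dataset([[0, 0], [1, 1], [2, 2], [1, 1], [0, 2]])
        kept = filter_snps(ds, FilterSpec(0.01, 0.99))
        assert kept.n_snps == 2

    def test_ten_snp_fixture_matches_hand_filter(self):
        # 10 SNPs x 10 samples engineered MAF / call-rate mix
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(10, 10)).astype(np.int8)
        calls[:, 0] = 0           # monomorphic: MAF 0 -> out
        calls[0, 1] = MISSING     # call rate 0.9 -> out
        calls[:, 2] = [1] + [0] * 9   # MAF 0.05 -> in
        ds = make_dataset(calls)
        maf = minor_allele_frequencies(ds)
        cr = (ds.calls != MISSING).mean(axis=0)
        hand_keep = [j for j in range(10) if maf[j] > 0.01 and cr[j] >= 0.99]
        kept = filter_snps(ds, FilterSpec(0.01, 0.99))
        assert list(kept.snps["snp_id"]) == [f"snp{j}" for j in hand_keep]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.integers(0, 3, size=(20, 30)).astype(np.int8))
        spec = FilterSpec(0.05, 0.95)
        once = filter_snps(ds, spec)
        twice = filter_snps(once, spec)
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_all_removed_raises(self):
        ds = make_dataset(np.zeros((5, 3), dtype=np.int8))
        with pytest.raises(GenotypeDataError):
            filter_snps(ds, FilterSpec(0.01, 0.99))

    def test_post_filter_mafs_exceed_threshold(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.integers(0, 3, size=(30, 50)).astype(np.int8))
        kept = filter_snps(ds, FilterSpec(0.2, 0.5))
        assert (minor_allele_frequencies(kept) > 0.2).all()


class TestMerge:
    def test_trivial_union(self):
        a = make_dataset([[0]], samples=["a1"])
        b = make_dataset([[2]], samples=["b1"])
        m = merge_datasets(a, b)
        assert m.samples == ["a1", "b1"]
        assert m.calls.tolist() == [[0], [2]]

    def test_swapped_allele_labels_flip_codes(self):
        a = make_dataset([[0, 1]], samples=["a1"], allele_a="A", allele_b="G")
        b = make_dataset([[0, 1]], samples=["b1"], allele_a="A", allele_b="G")
        b.snps.loc[0, ["allele_a", "allele_b"]] = ["G", "A"]  # reversed at SNP 0
        m = merge_datasets(a, b)
        assert m.calls.tolist() == [[0, 1], [2, 1]]

    def test_disjoint_snp_sets_raise(self):
        a = make_dataset([[0]])
        b = make_dataset([[0]], samples=["t0"])
        b.snps.loc[0, "snp_id"] = "other"
        with pytest.raises(GenotypeDataError, match="common"):
            merge_datasets(a, b)

    def test_shared_sample_id_raises(self):
        a = make_dataset([[0]])
        with pytest.raises(GenotypeDataError, match="shared"):
            merge_datasets(a, make_dataset([[1]]))

    def test_irreconcilable_alleles_dropped(self):
        a = make_dataset([[0, 0]], samples=["a1"], allele_a="A", allele_b="G")
        b = make_dataset([[0, 0]], samples=["b1"], allele_a="A", allele_b="G")
        b.snps.loc[0, ["allele_a", "allele_b"]] = ["C", "T"]
        m = merge_datasets(a, b)
        assert m.n_snps == 1 and m.snps["snp_id"].iloc[0] == "snp1"

    def test_symmetric_up_to_ordering(self):
        rng = np.random.default_rng(3)
        a = make_dataset(rng.integers(0, 3, (3, 6)).astype(np.int8),
                         samples=["a0", "a1", "a2"])
        b = make_dataset(rng.integers(0, 3, (2, 6)).astype(np.int8),
                         samples=["b0", "b1"])
        ab, ba = merge_datasets(a, b), merge_datasets(b, a)
        ab_rows = {s: ab.calls[i].tolist() for i, s in enumerate(ab.samples)}
        ba_rows = {s: ba.calls[i].tolist() for i, s in enumerate(ba.samples)}
        assert ab_rows == ba_rows
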