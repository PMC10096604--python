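import numpy as np
import pandas as pd
import pytest

import apdkit as ak
from apdkit import MISSING
from apdkit.errors import NoDataError, ValidationError

from conftest import VCF_ALL_MULTI, VCF_BASIC, VCF_MIXED


class TestReadVCF:
    def test_basic_gt_to_dosage(self, vcf_file):
        G = ak.read_vcf(vcf_file(VCF_BASIC))
        assert list(G.sample_ids) == ["A", "B", "C"]
        assert list(G.locus_ids) == ["1:100", "1:200"]
        expected = np.array([[0, 2], [1, MISSING], [2, 0]])
        np.testing.assert_array_equal(G.dosage, expected)

    def test_multiallelic_dropped_phase_ignored_haploid_promoted(self, vcf_file):
        G = ak.read_vcf(vcf_file(VCF_MIXED))
        # multiallelic ALT "A,T" and the indel record are dropped
        assert list(G.locus_ids) == ["1:100", "rs7"]
        # phased het "1|0" collapses to dosage 1; haploid "1" promotes to 2
        np.testing.assert_array_equal(
            G.dosage, np.array([[0, 0], [1, 2], [2, MISSING]]))

    def test_all_multiallelic_is_empty_data_error(self, vcf_file):
        with pytest.raises(NoDataError):
            ak.read_vcf(vcf_file(VCF_ALL_MULTI))

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(OSError):
            ak.read_vcf(tmp_path / "missing.vcf")

    def test_vcf_round_trip(self, small_collection, tmp_path):
        G, _ = small_collection
        sub = G.take_loci(np.arange(50)).take_samples(np.arange(20))
        path = tmp_path / "rt.vcf"
        ak.write_vcf(sub, path)
        back = ak.read_vcf(path)
        np.testing.assert_array_equal(back.dosage, sub.dosage)
        assert list(back.sample_ids) == list(sub.sample_ids)


class TestReadMatrix:
    def _write(self, tmp_path, text, name="g.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_samples_by_loci(self, tmp_path):
        path = self._write(tmp_path, "sample_id,l1,l2,l3\na,0,1,2\nb,2,NA,0\n")
        G = ak.read_matrix(path)
        np.testing.assert_array_equal(
            G.dosage, np.array([[0, 1, 2], [2, MISSING, 0]]))

    def test_loci_by_samples_transposed(self, tmp_path):
        path = self._write(tmp_path,
                           "locus_id,a,b\nl1,0,2\nl2,1,NA\nl3,2,0\n")
        G = ak.read_matrix(path, orientation="loci_by_samples")
        assert list(G.sample_ids) == ["a", "b"]
        np.testing.assert_array_equal(
            G.dosage, np.array([[0, 1, 2], [2, MISSING, 0]]))

    def test_bad_cell_reports_coordinates(self, tmp_path):
        path = self._write(tmp_path, "sample_id,l1,l2\na,0,3\n")
        with pytest.raises(ValidationError, match="l2"):
            ak.read_matrix(path)

    def test_round_trip_exact(self, small_collection, tmp_path):
        G, _ = small_collection
        path = tmp_path / "rt.csv"
        ak.write_matrix(G, path)
        back = ak.read_matrix(path)
        np.testing.assert_array_equal(back.dosage, G.dosage)
        assert list(back.locus_ids) == list(G.locus_ids)


class TestGenotypeMatrix:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate sample"):
            ak.GenotypeMatrix(["a", "a"], ["l1"], np.zeros((2, 1), np.int8))

    def test_out_of_alphabet_dosage_rejected(self):
        with pytest.raises(ValidationError):
            ak.GenotypeMatrix(["a"], ["l1"], np.array([[3]], np.int8))


class TestLocusStats:
    def test_hand_counts(self):
        G = ak.GenotypeMatrix(
            list("abcd"), ["l1", "l2", "l3"],
            np.array([[0, 0, MISSING],
                      [1, 0, MISSING],
                      [2, 0, MISSING],
                      [MISSING, 0, MISSING]], np.int8))
        st = ak.locus_stats(G).set_index("locus_id")
        # [0,1,2,MISSING]: alt freq 3/6, maf 0.5, missing 1/4
        assert st.loc["l1", "alt_allele_freq"] == pytest.approx(0.5)
        assert st.loc["l1", "maf"] == pytest.approx(0.5)
        assert st.loc["l1", "missing_rate"] == pytest.approx(0.25)
        # monomorphic [0,0,0,0]
        assert st.loc["l2", "maf"] == 0.0
        # all-missing locus: undefined maf, missing rate 1
        assert np.isnan(st.loc["l3", "maf"])
        assert st.loc["l3", "missing_rate"] == 1.0

    def test_invariant_under_sample_permutation(self, random_matrix):
        G = random_matrix(20, 30, missing_rate=0.2, seed=5)
        perm = np.random.default_rng(1).permutation(G.n_samples)
        st1 = ak.locus_stats(G)
        st2 = ak.locus_stats(G.take_samples(perm))
        pd.testing.assert_frame_equal(st1, st2)


def _toy_with_mafs():
    """10 samples x 5 loci with mafs (0, 0.003..., 0.02..., 0.2, 0.5).

    Built from alternate-allele counts out of 20 alleles: 0, 1, 2, 4, 10 ->
    alt freqs 0, 0.05, 0.1, 0.2, 0.5.  To reach maf below 0.05 the first
    columns use larger matrices; instead freeze a 500-sample toy where counts
    0, 3, 20, 200, 500 of 1000 alleles give mafs exactly
    (0, 0.003, 0.02, 0.2, 0.5).
    """
    n = 500
    dosage = np.zeros((n, 5), np.int8)
    for j, alt in enumerate([0, 3, 20, 200, 500]):
        dosage[:, j] = 0
        full, rem = divmod(alt, 2)
        dosage[:full, j] = 2
        if rem:
            dosage[full, j] = 1
    return ak.GenotypeMatrix([f"s{i}" for i in range(n)],
                             [f"l{j}" for j in range(5)], dosage)


class TestFilterLoci:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(remove_monomorphic=True, min_maf=0.05), ["l3", "l4"]),
            (dict(remove_monomorphic=True), ["l1", "l2", "l3", "l4"]),
            (dict(remove_monomorphic=False, min_maf=0.01), ["l2", "l3", "l4"]),
            (dict(remove_monomorphic=False, max_missing=1.0),
             ["l0", "l1", "l2", "l3", "l4"]),
            (dict(remove_monomorphic=True, min_maf=0.002, max_missing=0.0),
             ["l1", "l2", "l3", "l4"]),
        ],
    )
    def test_hand_counted_toy(self, kwargs, expected):
        G = _toy_with_mafs()
        out = ak.filter_loci(G, **kwargs)
        assert list(out.locus_ids) == expected
        assert list(out.sample_ids) == list(G.sample_ids)

    def test_all_removed_is_error(self):
        with pytest.raises(NoDataError):
            ak.filter_loci(_toy_with_mafs(), min_maf=0.6)

    def test_idempotent(self, small_collection):
        G, _ = small_collection
        once, log = ak.filter_loci(G, min_maf=0.05, max_missing=0.5,
                                   return_log=True)
        twice = ak.filter_loci(once, min_maf=0.05, max_missing=0.5)
        np.testing.assert_array_equal(once.dosage, twice.dosage)
        assert log.n_retained == once.n_loci

    def test_log_counts_sum(self):
        G = _toy_with_mafs()
        out, log = ak.filter_loci(G, remove_monomorphic=True, min_maf=0.05,
                                  return_log=True)
        assert log.removed_monomorphic == 1
        assert log.removed_maf == 2
        assert log.n_retained == out.n_loci == 2


class TestWriteResults:
    def test_manifest_and_empty_table(self, tmp_path):
        tables = {
            "apd": pd.DataFrame({"sample_id": list("abc"), "apd": [0.1, 0.2, 0.3]}),
            "outliers": pd.DataFrame(columns=["sample_id", "apd"]),
        }
        manifest = ak.write_results(tables, tmp_path / "out")
        assert set(manifest["name"]) == {"apd", "outliers"}
        assert manifest.set_index("name").loc["apd", "n_rows"] == 3
        header = (tmp_path / "out" / "outliers.csv").read_text().splitlines()
        assert header == ["sample_id,apd"]

    def test_duplicate_names_rejected(self, tmp_path):
        df = pd.DataFrame({"x": [1]})
        with pytest.raises(ValidationError):
            ak.write_results([("t", df), ("t", df)], tmp_path)
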