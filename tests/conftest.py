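import numpy as np
import pytest

from apdkit import GenotypeMatrix, MISSING, default_config, simulate_collection

VCF_BASIC = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\t.\tG\tC\t.\t.\t.\tGT\t1/1\t./.\t0/0
"""

VCF_MIXED = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
1\t100\t.\tA\tT\t.\t.\t.\tGT\t0|0\t1|0\t1/1
1\t150\t.\tC\tA,T\t.\t.\t.\tGT\t0/0\t1/2\t0/1
1\t200\trs7\tG\tC\t.\t.\t.\tGT\t0\t1\t./.
1\t250\t.\tGA\tG\t.\t.\t.\tGT\t0/0\t0/0\t1/1
"""

VCF_ALL_MULTI = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
1\t100\t.\tA\tT,C\t.\t.\t.\tGT\t0/0\t1/2
"""


@pytest.fixture
def vcf_file(tmp_path):
    def write(text, name="test.vcf"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return write


@pytest.fixture
def random_matrix():
    """Factory for random genotype matrices with optional missingness."""
    def make(n_samples, n_loci, missing_rate=0.0, seed=0):
        rng = np.random.default_rng(seed)
        dosage = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int8)
        if missing_rate > 0:
            dosage[rng.random(dosage.shape) < missing_rate] = MISSING
        return GenotypeMatrix(
            [f"S{i:04d}" for i in range(n_samples)],
            [f"L{j:05d}" for j in range(n_loci)],
            dosage,
        )
    return make


@pytest.fixture(scope="session")
def small_collection():
    """A small structured synthetic collection shared across tests."""
    cfg = default_config(n_samples=80, n_loci=600, n_duplicate_pairs=2,
                         n_outliers=2, seed=123)
    return simulate_collection(cfg)
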