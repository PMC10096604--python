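"""Simple-matching dissimilarities and the per-sample APD statistic.

For two samples the genotypic similarity S is the simple matching coefficient
(Sokal & Michener): the fraction of loci, among those called in both samples,
at which the two dosage states are identical (0-0, 1-1 or 2-2; the heterozygote
is its own state).  The pairwise dissimilarity is d = 1 - S.  A sample's APD is
the mean of its n - 1 pairwise dissimilarities against the rest of the
collection; a high APD marks a genetically distinct accession, a low APD a
redundant one.

Missing data are handled by pairwise-complete comparison only — no imputation.
A pair with zero co-called loci is undefined (NaN) and is excluded from the
averages but reported in the diagnostics.

The pairwise matrix is accumulated in locus blocks so peak memory scales with
the block size; because per-block match counts are exact integers, the result
is bit-identical for every block size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SizeError, ValidationError
from .genotype_io import MISSING, GenotypeMatrix

DEFAULT_BLOCK_SIZE = 10_000


@dataclass
class PairDissimilarity:
    """One pairwise comparison: d = 1 - matches / n_compared."""

    d: float
    n_compared: int
    sample_i: str | None = None
    sample_j: str | None = None

    @property
    def defined(self) -> bool:
        return self.n_compared > 0


@dataclass
class APDResult:
    """Per-sample APD and diagnostics over a collection of n samples."""

    sample_ids: np.ndarray
    apd: np.ndarray           # mean of the sample's defined pairwise d
    apd_sd: np.ndarray        # sample SD (ddof=1) of those pairwise d
    n_pairs_used: np.ndarray  # defined pairs entering the mean
    min_pair_loci: np.ndarray  # smallest n_compared over the sample's defined pairs
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "apd": self.apd,
            "apd_sd": self.apd_sd,
            "n_pairs_used": self.n_pairs_used,
            "min_pair_loci": self.min_pair_loci,
        })


@dataclass
class APDDistribution:
    """Mean (M) and standard deviation (SD) of the APD values of a collection."""

    M: float
    SD: float


def pair_dissimilarity(gi, gj, method: str = "state") -> PairDissimilarity:
    """Dissimilarity between two dosage vectors over co-called loci.

    ``method="state"`` (default) scores a locus as matching iff the dosage
    codes are identical.  ``method="allele"`` is the allele-sharing variant:
    per-locus distance |gi - gj| / 2, offered for comparison only.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape or gi.ndim != 1:
        raise ValidationError("dosage vectors must be 1-D and equal length")
    both = (gi != MISSING) & (gj != MISSING)
    n = int(both.sum())
    if n == 0:
        return PairDissimilarity(d=float("nan"), n_compared=0)
    if method == "state":
        d = 1.0 - float((gi[both] == gj[both]).sum()) / n
    elif method == "allele":
        d = float(np.abs(gi[both] - gj[both]).sum()) / (2.0 * n)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return PairDissimilarity(d=d, n_compared=n)


def pairwise_dissimilarity(
    G: GenotypeMatrix,
    block_size: int = DEFAULT_BLOCK_SIZE,
    method: str = "state",
):
    """All-pairs dissimilarity matrix and co-called-locus counts.

    Returns ``(D, n_compared)`` where ``D`` is a symmetric float64 matrix with
    zero diagonal and NaN for undefined pairs, and ``n_compared`` counts the
    loci called in both members of each pair.

    The computation runs over locus blocks of ``block_size`` columns.  Match
    counts per block are integers represented exactly in float32 (valid up to
    2^24 loci), so the accumulated counts — and hence ``D`` — do not depend on
    the block size.
    """
    if method not in ("state", "allele"):
        raise ValidationError(f"unknown method {method!r}")
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    n, L = G.n_samples, G.n_loci
    num = np.zeros((n, n), dtype=np.int64)   # matches or summed allele distance
    ncomp = np.zeros((n, n), dtype=np.int64)
    for start in range(0, L, block_size):
        block = G.dosage[:, start:start + block_size]
        called = (block != MISSING).astype(np.float32)
        ncomp += (called @ called.T).astype(np.int64)
        ind = [(block == s).astype(np.float32) for s in (0, 1, 2)]
        if method == "state":
            acc = ind[0] @ ind[0].T
            acc += ind[1] @ ind[1].T
            acc += ind[2] @ ind[2].T
        else:  # summed |gi - gj| over co-called loci
            c01 = ind[0] @ ind[1].T
            c12 = ind[1] @ ind[2].T
            c02 = ind[0] @ ind[2].T
            acc = c01 + c01.T + c12 + c12.T + 2.0 * (c02 + c02.T)
        num += acc.astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "state":
            D = 1.0 - num / ncomp
        else:
            D = (num / 2.0) / ncomp
    D[ncomp == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    return D, ncomp


def apd_from_distances(
    D: np.ndarray,
    ncomp: np.ndarray,
    sample_ids: np.ndarray,
) -> APDResult:
    """Per-sample APD from a precomputed pairwise matrix.

    Undefined pairs (NaN off-diagonal) are excluded from the per-sample mean
    and SD; a sample whose pairs are all undefined gets NaN APD.
    """
    n = D.shape[0]
    if n < 3:
        raise SizeError(f"APD needs at least 3 samples, got {n}")
    off = ~np.eye(n, dtype=bool)
    defined = off & ~np.isnan(D)
    n_used = defined.sum(axis=1)
    Dz = np.where(defined, D, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        apd = np.where(n_used > 0, Dz.sum(axis=1) / n_used, np.nan)
        # sample SD over each sample's defined pairwise d (ddof = 1)
        ss = (np.where(defined, (D - apd[:, None]) ** 2, 0.0)).sum(axis=1)
        apd_sd = np.where(n_used > 1, np.sqrt(ss / np.maximum(n_used - 1, 1)),
                          np.nan)
    big = np.iinfo(np.int64).max
    nc = np.where(defined, ncomp, big)
    min_pair = np.where(n_used > 0, nc.min(axis=1), 0)
    return APDResult(
        sample_ids=np.asarray(sample_ids, dtype=object),
        apd=apd, apd_sd=apd_sd,
        n_pairs_used=n_used.astype(np.int64),
        min_pair_loci=min_pair.astype(np.int64),
        n=n,
    )


def apd_all(
    G: GenotypeMatrix,
    block_size: int = DEFAULT_BLOCK_SIZE,
    method: str = "state",
) -> APDResult:
    """APD and its SD for every sample of the collection (n >= 3)."""
    if G.n_samples < 3:
        raise SizeError(f"APD needs at least 3 samples, got {G.n_samples}")
    D, ncomp = pairwise_dissimilarity(G, block_size=block_size, method=method)
    return apd_from_distances(D, ncomp, G.sample_ids)


def apd_distribution(r: APDResult) -> APDDistribution:
    """Collection-level mean M and sample SD of the APD values.

    When every pair is defined, M equals the grand mean of all C(n, 2)
    pairwise dissimilarities (each d_ij appears in exactly two per-sample
    averages).  NaN APDs (samples with no defined pair) are excluded.
    """
    vals = np.asarray(r.apd, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise SizeError("no defined APD values")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return APDDistribution(M=float(vals.mean()), SD=sd)
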