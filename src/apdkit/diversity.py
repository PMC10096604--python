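"""Group characterization: distance-based AMOVA and Weir-Goudet group Fst.

AMOVA (one level, groups as populations) partitions squared pairwise distances
into among-group and within-group components.  With squared distances
``dd_ij = d_ij**2``:

    SSD_total  = (1/n)   * sum_{i<j} dd_ij
    SSD_within = sum_g (1/n_g) * sum_{i<j in g} dd_ij
    SSD_among  = SSD_total - SSD_within
    MS_among   = SSD_among / (g - 1),   MS_within = SSD_within / (n - g)
    sigma2_within = MS_within
    sigma2_among  = (MS_among - MS_within) / n0,
    n0 = (n - sum_g n_g**2 / n) / (g - 1)

The among-group percentage is 100 * sigma2_among / (sigma2_among +
sigma2_within); a negative sigma2_among is reported as computed (flagged), as
happens under no structure.

Group-specific Fst follows the Weir-Goudet allele-matching (beta)
formulation.  For group i, Mw_i is the average over loci of the proportion of
matching allele pairs drawn from two *distinct* individuals of the group
(excluding within-individual pairs removes the inbreeding/selfing effect);
Mb is the average over group pairs of between-group allele matching; then

    beta_i = (Mw_i - Mb) / (1 - Mb)

beta_i may be negative — the group then holds more rare alleles (more
diversity) than the collection average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categorize import GroupAssignment
from .errors import SizeError, ValidationError
from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class AMOVATable:
    """One-level AMOVA variance decomposition for a grouping."""

    df_among: int
    df_within: int
    ssd_among: float
    ssd_within: float
    ssd_total: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    negative_sigma2: bool = False
    p_value: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "source": ["among_groups", "within_groups", "total"],
            "df": [self.df_among, self.df_within, self.df_among + self.df_within],
            "SSD": [self.ssd_among, self.ssd_within, self.ssd_total],
            "MS": [self.ssd_among / self.df_among,
                   self.ssd_within / self.df_within, np.nan],
            "variance_component": [self.sigma2_among, self.sigma2_within, np.nan],
            "pct": [self.pct_among, 100.0 - self.pct_among, 100.0],
        })


@dataclass
class FstEstimates:
    """Per-group Weir-Goudet beta and their unweighted mean."""

    groups: np.ndarray
    n_per_group: np.ndarray
    beta: np.ndarray
    overall_beta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.groups, "n": self.n_per_group,
                             "beta": self.beta})


def _as_labels(groups, n: int) -> np.ndarray:
    if isinstance(groups, GroupAssignment):
        labels = np.asarray(groups.group)
    else:
        labels = np.asarray(groups)
    if labels.shape != (n,):
        raise ValidationError(
            f"group labels have shape {labels.shape}, expected ({n},)")
    return labels


def amova(
    D: np.ndarray,
    groups,
    clamp_negative: bool = False,
) -> AMOVATable:
    """One-level AMOVA on a symmetric pairwise distance matrix.

    ``groups`` is a label vector aligned to ``D`` (or a
    :class:`~apdkit.categorize.GroupAssignment`).  Groups of size zero are
    ignored; at least two non-empty groups must remain.  With
    ``clamp_negative=True`` a negative among-group component is reported as 0.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValidationError("D must be a square matrix")
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValidationError("D must be symmetric")
    if np.isnan(D).any():
        raise ValidationError("D contains undefined (NaN) distances")
    labels = _as_labels(groups, n)
    uniq, counts = np.unique(labels, return_counts=True)
    uniq = uniq[counts > 0]
    g = len(uniq)
    if g < 2:
        raise SizeError("AMOVA needs at least 2 non-empty groups")
    if n - g < 1:
        raise SizeError("AMOVA needs n > number of groups")
    DD = D ** 2
    ssd_total = DD[np.triu_indices(n, k=1)].sum() / n
    ssd_within = 0.0
    sizes = []
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        sizes.append(len(idx))
        sub = DD[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    sizes = np.array(sizes, dtype=float)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = g - 1, n - g
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within
    n0 = (n - (sizes ** 2).sum() / n) / df_among
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0
    negative = sigma2_among < 0
    if clamp_negative and negative:
        sigma2_among = 0.0
    denom = sigma2_among + sigma2_within
    pct = 100.0 * sigma2_among / denom if denom != 0 else np.nan
    return AMOVATable(
        df_among=df_among, df_within=df_within,
        ssd_among=float(ssd_among), ssd_within=float(ssd_within),
        ssd_total=float(ssd_total),
        sigma2_among=float(sigma2_among), sigma2_within=float(sigma2_within),
        pct_among=float(pct), negative_sigma2=bool(negative),
    )


def amova_permutation_test(
    D: np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AMOVATable:
    """AMOVA with a label-permutation p-value for the among-group component.

    The p-value is the fraction of permuted label vectors (plus the observed
    one) whose among-group percentage is at least the observed value.
    """
    result = amova(D, groups)
    labels = _as_labels(groups, D.shape[0])
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if amova(D, perm).pct_among >= result.pct_among:
            hits += 1
    result.p_value = hits / (n_permutations + 1)
    return result


def wg_fst(G: GenotypeMatrix, groups) -> FstEstimates:
    """Weir-Goudet group-specific Fst (beta) from allele matching.

    Needs at least two groups with two or more samples each (smaller groups
    are dropped with a warning).  Loci where a group has fewer than two called
    samples are skipped for that group's within term; loci with no calls in a
    group are skipped for that group's between terms.  A group with no usable
    locus gets NaN beta.
    """
    labels = _as_labels(groups, G.n_samples)
    uniq, counts = np.unique(labels, return_counts=True)
    keep = counts >= 2
    if (~keep).any():
        warnings.warn(
            f"dropping groups with < 2 samples: {list(uniq[~keep])}")
    uniq, counts = uniq[keep], counts[keep]
    K = len(uniq)
    if K < 2:
        raise SizeError("wg_fst needs at least 2 groups with >= 2 samples")
    L = G.n_loci
    Mw = np.full(K, np.nan)
    pbar = np.full((K, L), np.nan)   # mean individual allele frequency
    ncall = np.zeros((K, L))
    for gi, lab in enumerate(uniq):
        Xg = G.dosage[labels == lab].astype(float)
        called = Xg != MISSING
        p_ind = np.where(called, Xg / 2.0, 0.0)
        m = called.sum(axis=0).astype(float)          # called samples per locus
        s = p_ind.sum(axis=0)
        q = (p_ind ** 2).sum(axis=0)
        ncall[gi] = m
        with np.errstate(divide="ignore", invalid="ignore"):
            pbar[gi] = np.where(m > 0, s / m, np.nan)
            # allele matching across pairs of distinct individuals
            num = (s * s - q) + ((m - s) ** 2 - (m - 2 * s + q))
            mw_l = np.where(m >= 2, num / (m * np.maximum(m - 1, 1)), np.nan)
        if np.isfinite(mw_l).any():
            Mw[gi] = np.nanmean(mw_l)
    mb_pairs = []
    for i in range(K):
        for j in range(i + 1, K):
            both = (ncall[i] > 0) & (ncall[j] > 0)
            if both.any():
                mij = (pbar[i, both] * pbar[j, both]
                       + (1 - pbar[i, both]) * (1 - pbar[j, both]))
                mb_pairs.append(mij.mean())
    if not mb_pairs:
        raise SizeError("no locus with calls in two or more groups")
    Mb = float(np.mean(mb_pairs))
    if Mb >= 1.0:
        raise ValidationError("between-group matching is 1: no variation")
    beta = (Mw - Mb) / (1.0 - Mb)
    if np.isnan(beta).any():
        warnings.warn("groups with no usable locus have undefined (NaN) beta")
    return FstEstimates(
        groups=uniq, n_per_group=counts.astype(np.int64), beta=beta,
        overall_beta=float(np.nanmean(beta)),
    )
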