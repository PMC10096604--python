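"""Synthetic germplasm collections with planted ground truth.

The generator emulates the statistical structure of genebank SNP panels for
mostly-inbred selfing crops: a Balding-Nichols subpopulation model over an
L-shaped ancestral allele-frequency spectrum, per-sample selfing (a sample is
fully homozygous with probability ``selfing_f``), L-shaped per-locus missing
rates, planted near-duplicate accession pairs (redeposited seed lots of the
same inbred line, differing by a small per-locus flip rate), and planted
outlier accessions from a divergent source population (misclassified or
introgressed material).

Outlier divergence: a Balding-Nichols perturbation of the *same* ancestral
frequencies is mean-preserving, so it cannot raise the expected pairwise
distance to the rest of the collection no matter how large theta is.  The
outlier source therefore mixes an independent ancestral frequency vector into
the collection's one with weight ``outlier_theta``: 0 makes the outlier source
just another subpopulation, 1 an unrelated species.

Everything is reproducible bit-for-bit from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotype_io import MISSING, GenotypeMatrix

_ROW_BLOCK = 256  # genotype generation block; bounds peak memory, not results


@dataclass
class SimulationConfig:
    """Parameters of one synthetic collection (defaults: a 300-accession,
    5000-SNP selfing-crop panel with 3 subpopulations, 5 planted duplicate
    pairs and 3 planted outliers)."""

    n_samples: int = 300
    n_loci: int = 5000
    n_subpops: int = 3
    theta: float = 0.05
    selfing_f: float = 0.95
    maf_spectrum: tuple[float, float] = (0.3, 0.3)
    n_duplicate_pairs: int = 5
    duplicate_mutation_rate: float = 0.001
    n_outliers: int = 3
    outlier_theta: float = 0.5
    missing_spectrum: tuple[float, float] = (0.3, 5.0)
    max_missing_cap: float = 0.95
    seed: int = 42

    def validate(self) -> None:
        if min(self.n_samples, self.n_loci, self.n_subpops) < 1:
            raise ValidationError("n_samples, n_loci, n_subpops must be >= 1")
        if self.n_duplicate_pairs < 0 or self.n_outliers < 0:
            raise ValidationError("counts must be non-negative")
        if 2 * self.n_duplicate_pairs + self.n_outliers > self.n_samples:
            raise ValidationError(
                "2 * n_duplicate_pairs + n_outliers exceeds n_samples")
        for name in ("theta", "outlier_theta"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        for name in ("selfing_f", "duplicate_mutation_rate", "max_missing_cap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("maf_spectrum", "missing_spectrum"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValidationError(f"{name} shapes must be positive")


@dataclass
class SimulationTruth:
    """Planted structure: duplicate pairs, outliers, subpopulation labels."""

    duplicate_pairs: list[tuple[str, str]]
    outlier_ids: list[str]
    subpop_of: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        partner = {}
        for a, b in self.duplicate_pairs:
            partner[a] = b
            partner[b] = a
        dup_members = set(partner)
        rows = []
        for sid, pop in self.subpop_of.items():
            role = ("outlier" if sid in self.outlier_ids
                    else "duplicate" if sid in dup_members else "normal")
            rows.append({"sample_id": sid, "role": role,
                         "partner_id": partner.get(sid, ""), "subpop": pop})
        return pd.DataFrame(rows, columns=["sample_id", "role", "partner_id",
                                           "subpop"])


def _bn_freq(rng: np.random.Generator, p_anc: np.ndarray, theta: float,
             size=None) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies around ancestral p_anc."""
    if theta == 0:
        return np.broadcast_to(p_anc, size or p_anc.shape).copy()
    a = p_anc * (1 - theta) / theta
    b = (1 - p_anc) * (1 - theta) / theta
    # guard against zero shapes when p_anc hits 0 or 1 exactly
    p = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12), size=size)
    return p


def _genotypes(rng: np.random.Generator, freqs: np.ndarray,
               selfed: np.ndarray) -> np.ndarray:
    """Dosage rows for per-row allele frequencies; selfed rows are homozygous."""
    n, L = freqs.shape
    X = np.empty((n, L), dtype=np.int8)
    for start in range(0, n, _ROW_BLOCK):
        sl = slice(start, min(start + _ROW_BLOCK, n))
        f = freqs[sl]
        hom = 2 * (rng.random(f.shape) < f).astype(np.int8)
        het = rng.binomial(2, f).astype(np.int8)
        X[sl] = np.where(selfed[sl, None], hom, het)
    return X


def simulate_collection(cfg: SimulationConfig):
    """Generate a collection and its planted truth.

    Returns ``(GenotypeMatrix, SimulationTruth)``.  Sample order is shuffled
    so planted samples carry no positional signal.  Duplicate donors are drawn
    from the selfed (homozygous) base samples when any exist; each copy flips
    every locus independently to one of the two other states with probability
    ``duplicate_mutation_rate``.  Missingness is locus-driven: per-locus rate
    min(Beta(missing_spectrum), cap), applied Bernoulli per cell.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L, K = cfg.n_loci, cfg.n_subpops
    n_base = cfg.n_samples - cfg.n_duplicate_pairs - cfg.n_outliers

    p_anc = rng.beta(*cfg.maf_spectrum, size=L)
    P = _bn_freq(rng, p_anc, cfg.theta, size=(K, L))

    subpop = rng.integers(0, K, size=n_base)
    selfed = rng.random(n_base) < cfg.selfing_f
    X_base = _genotypes(rng, P[subpop], selfed)

    # near-duplicates: copies of homozygous donors with rare state flips
    donor_pool = np.flatnonzero(selfed) if selfed.any() else np.arange(n_base)
    donors = rng.choice(donor_pool, size=cfg.n_duplicate_pairs, replace=False) \
        if cfg.n_duplicate_pairs else np.empty(0, dtype=int)
    copies = []
    for d in donors:
        c = X_base[d].copy()
        flip = np.flatnonzero(rng.random(L) < cfg.duplicate_mutation_rate)
        if flip.size:
            # move to one of the two other states, uniformly
            c[flip] = (c[flip] + rng.integers(1, 3, size=flip.size)) % 3
        copies.append(c)

    # outliers: divergent source population (independent-spectrum mixture)
    outliers = []
    if cfg.n_outliers:
        q = rng.beta(*cfg.maf_spectrum, size=L)
        p_mix = (1 - cfg.outlier_theta) * p_anc + cfg.outlier_theta * q
        p_out = _bn_freq(rng, p_mix, cfg.theta)
        out_selfed = rng.random(cfg.n_outliers) < cfg.selfing_f
        outliers = list(_genotypes(rng, np.tile(p_out, (cfg.n_outliers, 1)),
                                   out_selfed))

    X = np.vstack([X_base] + copies + outliers) if (copies or outliers) else X_base

    # locus-driven L-shaped missingness
    m_rate = np.minimum(rng.beta(*cfg.missing_spectrum, size=L),
                        cfg.max_missing_cap)
    miss = rng.random(X.shape) < m_rate[None, :]
    X = np.where(miss, np.int8(MISSING), X)

    width = max(4, len(str(cfg.n_samples)))
    ids = np.array([f"S{i + 1:0{width}d}" for i in range(cfg.n_samples)],
                   dtype=object)
    perm = rng.permutation(cfg.n_samples)  # shuffle positions, keep ids stable
    X = X[perm]
    pos_of = np.empty(cfg.n_samples, dtype=int)
    pos_of[perm] = np.arange(cfg.n_samples)

    def sid(orig_row: int) -> str:
        return ids[pos_of[orig_row]]

    subpop_of = {}
    for i in range(n_base):
        subpop_of[sid(i)] = f"pop{subpop[i] + 1}"
    pairs = []
    for j, d in enumerate(donors):
        copy_row = n_base + j
        subpop_of[sid(copy_row)] = f"pop{subpop[d] + 1}"
        pairs.append((sid(int(d)), sid(copy_row)))
    outlier_ids = []
    for j in range(cfg.n_outliers):
        row = n_base + cfg.n_duplicate_pairs + j
        subpop_of[sid(row)] = "outlier_pop"
        outlier_ids.append(sid(row))

    G = GenotypeMatrix(ids,
                       np.array([f"L{j + 1:06d}" for j in range(L)], dtype=object),
                       X, ploidy_note=f"synthetic (seed={cfg.seed})")
    truth = SimulationTruth(duplicate_pairs=pairs, outlier_ids=outlier_ids,
                            subpop_of=subpop_of)
    return G, truth


def expected_structure(cfg: SimulationConfig) -> dict:
    """Closed-form expectations under the generative model, used as oracles.

    * ``expected_fst``: the Balding-Nichols theta.
    * ``expected_heterozygosity``: mean per-locus heterozygote fraction,
      (1 - selfing_f) * 2 * E[p(1-p)] with E over the subpopulation frequency
      distribution (Beta ancestral moments shrunk by (1 - theta)).
    * ``expected_duplicate_dissimilarity``: a flipped locus always mismatches
      its donor state, so the pair dissimilarity equals the flip rate (the
      "correction" from two independent flips colliding on the same state is
      O(rate^2) and negligible).
    """
    cfg.validate()
    a, b = cfg.maf_spectrum
    e_p1p = (a * b) / ((a + b) * (a + b + 1))       # E[p(1-p)] under Beta(a,b)
    e_p1p_sub = e_p1p * (1 - cfg.theta)             # Balding-Nichols shrinkage
    return {
        "expected_fst": cfg.theta,
        "expected_heterozygosity": (1 - cfg.selfing_f) * 2 * e_p1p_sub,
        "expected_duplicate_dissimilarity": cfg.duplicate_mutation_rate,
        "expected_within_subpop_dissimilarity_homozygous": 2 * e_p1p_sub,
    }


def default_config(**overrides) -> SimulationConfig:
    """The documented default study collection, with optional overrides."""
    return replace(SimulationConfig(), **overrides)
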