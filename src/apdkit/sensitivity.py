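"""Sensitivity of APD estimation to sample size, SNP number, MAF and missing data.

Each scenario perturbs the collection along one axis (random sample subset,
random SNP subset, removal of low-MAF loci, removal of high-missing-rate
loci), recomputes APD, and correlates the new estimates with the full-data
APD of the same samples.  A high correlation means the perturbed data would
give an APD-based sample ranking consistent with the original one; the
practical question is how few SNPs (or samples) still support a stable
ranking.

Pearson r is the primary statistic; Spearman rank correlation is reported
alongside because ranking consistency is the quantity of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .apd_core import APDResult, apd_all
from .errors import SizeError, ValidationError
from .genotype_io import GenotypeMatrix, locus_stats

AXES = ("sample_subsample", "snp_subsample", "maf_removal", "missing_removal")


@dataclass
class Scenario:
    """One perturbation: an axis, its parameter, a replicate index and a seed."""

    axis: str
    parameter: float
    replicate: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValidationError(f"unknown axis {self.axis!r}; expected one of {AXES}")
        if self.axis in ("maf_removal", "missing_removal"):
            if not 0.0 <= self.parameter <= 1.0:
                raise ValidationError(
                    f"{self.axis} threshold must be in [0, 1], got {self.parameter}")
        elif self.parameter < 1 or self.parameter != int(self.parameter):
            raise ValidationError(
                f"{self.axis} count must be a positive integer, got {self.parameter}")


@dataclass
class ScenarioResult:
    """Correlation between reference and scenario APD over shared samples."""

    pearson_r: float
    spearman_r: float
    n_shared: int
    scenario: Scenario | None = None


def make_scenario_data(
    G: GenotypeMatrix,
    s: Scenario,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Build the perturbed genotype matrix for one scenario.

    Subsampling axes draw uniformly without replacement using ``rng`` (or a
    generator seeded from ``s.seed``); the filtering axes are deterministic:
    ``maf_removal`` drops loci with MAF < threshold, ``missing_removal`` drops
    loci with missing rate >= threshold.
    """
    if rng is None:
        rng = np.random.default_rng(s.seed)
    if s.axis == "sample_subsample":
        k = int(s.parameter)
        if k > G.n_samples:
            raise SizeError(f"requested {k} samples, only {G.n_samples} available")
        idx = np.sort(rng.choice(G.n_samples, size=k, replace=False))
        return G.take_samples(idx)
    if s.axis == "snp_subsample":
        k = int(s.parameter)
        if k > G.n_loci:
            raise SizeError(f"requested {k} loci, only {G.n_loci} available")
        idx = np.sort(rng.choice(G.n_loci, size=k, replace=False))
        return G.take_loci(idx)
    stats = locus_stats(G)
    if s.axis == "maf_removal":
        keep = ~(stats["maf"].to_numpy() < s.parameter)
    else:  # missing_removal
        keep = ~(stats["missing_rate"].to_numpy() >= s.parameter)
    if not keep.any():
        raise SizeError(f"{s.axis} at {s.parameter} removes every locus")
    return G.take_loci(np.flatnonzero(keep))


def apd_correlation(ref: APDResult, alt: APDResult) -> ScenarioResult:
    """Pearson and Spearman correlation of two APD vectors over shared samples."""
    ref_s = pd.Series(ref.apd, index=pd.Index(ref.sample_ids))
    alt_s = pd.Series(alt.apd, index=pd.Index(alt.sample_ids))
    shared = ref_s.index.intersection(alt_s.index)
    x = ref_s.loc[shared].to_numpy(dtype=float)
    y = alt_s.loc[shared].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise SizeError(f"need >= 3 shared samples with defined APD, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # constant vector: correlation undefined, flagged as NaN
        return ScenarioResult(np.nan, np.nan, int(x.size))
    pearson = float(sps.pearsonr(x, y).statistic)
    spearman = float(sps.spearmanr(x, y).statistic)
    return ScenarioResult(pearson, spearman, int(x.size))


def scenario_seed(master_seed: int, axis: str, parameter: float,
                  replicate: int) -> int:
    """Deterministic per-scenario seed derived from the master seed."""
    ss = np.random.SeedSequence(
        [int(master_seed), AXES.index(axis),
         int(round(float(parameter) * 1_000_000)), int(replicate)])
    return int(ss.generate_state(1)[0])


def build_plan(
    axes: dict[str, list[float]],
    replicates: int = 5,
    master_seed: int = 0,
) -> list[Scenario]:
    """Expand ``{axis: [parameters]}`` into seeded scenario replicates."""
    if not axes:
        raise ValidationError("empty sensitivity plan")
    plan = []
    for axis, params in axes.items():
        if not params:
            raise ValidationError(f"axis {axis!r} has no parameters")
        for p in params:
            for rep in range(replicates):
                plan.append(Scenario(axis, p, replicate=rep,
                                     seed=scenario_seed(master_seed, axis, p, rep)))
    return plan


def run_sensitivity(
    G: GenotypeMatrix,
    plan: list[Scenario],
    ref: APDResult | None = None,
    block_size: int = 10_000,
) -> pd.DataFrame:
    """Execute a scenario plan against the full-data APD reference.

    The reference APD is computed once from ``G`` (or supplied).  For
    ``sample_subsample`` scenarios the reference values are the full-data APDs
    restricted to the retained samples.  A failed scenario is recorded with
    NaN correlations rather than aborting the run.  Results are sorted by
    axis, parameter, replicate.
    """
    if not plan:
        raise ValidationError("empty sensitivity plan")
    if ref is None:
        ref = apd_all(G, block_size=block_size)
    rows = []
    for s in plan:
        row = {"axis": s.axis, "parameter": s.parameter,
               "replicate": s.replicate, "seed": s.seed,
               "n_shared": 0, "pearson_r": np.nan, "spearman_r": np.nan}
        try:
            sub = make_scenario_data(G, s)
            alt = apd_all(sub, block_size=block_size)
            res = apd_correlation(ref, alt)
            row.update(n_shared=res.n_shared, pearson_r=res.pearson_r,
                       spearman_r=res.spearman_r)
        except (SizeError, ValidationError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["axis", "parameter", "replicate"],
                          kind="mergesort").reset_index(drop=True)
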