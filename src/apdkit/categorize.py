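"""Distribution-based categorization of APD estimates.

Three management views of the same per-sample APD vector:

* six genetic groups cut at M+3SD, M+2SD, M+SD, M, M-SD (group 1 holds the
  most distinct samples; group 6 is the catch-all below M-SD, with the M-2SD
  edge reported as an additional threshold);
* a one-sided genetic outlier set, APD > M + k*SD (k = 5 by default) —
  candidates for species misclassification or introgressed material;
* distinct / redundant sets of the k samples with the largest / smallest APD.

Boundary ties resolve upward (toward the more distinct group) and rank ties
break on sample id, so every assignment is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .apd_core import APDDistribution, APDResult
from .errors import SizeError, ValidationError


@dataclass
class GroupAssignment:
    """Per-sample group 1..6 plus outlier / distinct / redundant flags."""

    sample_ids: np.ndarray
    group: np.ndarray
    is_outlier: np.ndarray | None = None
    in_distinct: np.ndarray | None = None
    in_redundant: np.ndarray | None = None
    thresholds: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return self.group

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "group": self.group})
        for name in ("is_outlier", "in_distinct", "in_redundant"):
            val = getattr(self, name)
            if val is not None:
                df[name] = val
        return df


@dataclass
class OutlierResult:
    """Samples with APD above M + k_sd * SD, most extreme first."""

    sample_ids: np.ndarray
    apd: np.ndarray
    threshold: float
    k_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "apd": self.apd,
                             "threshold": self.threshold})


def assign_groups(r: APDResult, dist: APDDistribution) -> GroupAssignment:
    """Assign every sample to one of six APD-distribution groups.

    Bin edges sit at M+3SD, M+2SD, M+SD, M and M-SD; group k (k = 2..5) spans
    one SD width, group 1 is everything at or above M+3SD and group 6
    everything below M-SD.  With SD = 0 the distribution is degenerate and
    every sample lands in group 4 (with a warning).
    """
    apd = np.asarray(r.apd, dtype=float)
    if apd.size == 0:
        raise SizeError("empty APD result")
    M, SD = dist.M, dist.SD
    thresholds = {f"M{s:+d}SD": M + s * SD for s in (3, 2, 1, 0, -1, -2)}
    if SD <= 0:
        warnings.warn("APD distribution has SD = 0; all samples in group 4")
        group = np.full(apd.size, 4, dtype=np.int64)
    else:
        edges = np.array([M - SD, M, M + SD, M + 2 * SD, M + 3 * SD])
        # ties go upward: apd == edge joins the more distinct (lower-number) group
        group = 6 - np.searchsorted(edges, np.nan_to_num(apd, nan=M), side="right")
        group = np.clip(group, 1, 6).astype(np.int64)
        if np.isnan(apd).any():
            warnings.warn("samples with undefined APD placed in group 4")
    return GroupAssignment(sample_ids=np.asarray(r.sample_ids, dtype=object),
                           group=group, thresholds=thresholds)


def find_outliers(
    r: APDResult,
    dist: APDDistribution,
    k_sd: float = 5.0,
) -> OutlierResult:
    """Samples with APD strictly above M + k_sd * SD, sorted by APD descending."""
    if k_sd < 0:
        raise ValidationError("k_sd must be >= 0")
    apd = np.asarray(r.apd, dtype=float)
    threshold = dist.M + k_sd * dist.SD
    idx = np.flatnonzero(apd > threshold)
    order = idx[np.lexsort((np.asarray(r.sample_ids, dtype=object)[idx],
                            -apd[idx]))]
    return OutlierResult(
        sample_ids=np.asarray(r.sample_ids, dtype=object)[order],
        apd=apd[order], threshold=float(threshold), k_sd=float(k_sd),
    )


def select_extremes(
    r: APDResult,
    k: int = 100,
    which: str = "distinct",
    passport: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """The k samples with the largest (distinct) or smallest (redundant) APD.

    Ties break on sample id (lexicographic) so the selection is deterministic.
    A passport table (first column or ``sample_id`` column holding ids) is
    left-joined onto the result when supplied.
    """
    if which not in ("distinct", "redundant"):
        raise ValidationError(f"which must be 'distinct' or 'redundant', got {which!r}")
    if not 1 <= k <= r.n:
        raise SizeError(f"k = {k} out of range for n = {r.n}")
    df = pd.DataFrame({"sample_id": np.asarray(r.sample_ids, dtype=object),
                       "apd": np.asarray(r.apd, dtype=float)})
    ascending = which == "redundant"
    df = df.sort_values(["apd", "sample_id"], ascending=[ascending, True],
                        kind="mergesort").head(k).reset_index(drop=True)
    if passport is not None:
        pp = passport.copy()
        if "sample_id" not in pp.columns:
            pp = pp.rename(columns={pp.columns[0]: "sample_id"})
        df = df.merge(pp, on="sample_id", how="left")
    return df


def full_assignment(
    r: APDResult,
    dist: APDDistribution,
    k_sd: float = 5.0,
    extremes_k: int = 100,
    passport: pd.DataFrame | None = None,
) -> GroupAssignment:
    """Groups, outlier flag and distinct/redundant flags in one assignment."""
    ga = assign_groups(r, dist)
    out = find_outliers(r, dist, k_sd=k_sd)
    distinct = select_extremes(r, k=extremes_k, which="distinct", passport=passport)
    redundant = select_extremes(r, k=extremes_k, which="redundant", passport=passport)
    ids = pd.Index(ga.sample_ids)
    ga.is_outlier = ids.isin(out.sample_ids)
    ga.in_distinct = ids.isin(distinct["sample_id"])
    ga.in_redundant = ids.isin(redundant["sample_id"])
    ga.thresholds[f"M+{k_sd:g}SD"] = out.threshold
    return ga
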