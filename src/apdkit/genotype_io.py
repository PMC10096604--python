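"""Reading, validating, summarizing, filtering and writing SNP genotype data.

The central container is :class:`GenotypeMatrix`: a samples x loci matrix of
alternate-allele dosages for biallelic SNPs.  Dosage codes are ``0`` (homozygous
reference), ``1`` (heterozygous), ``2`` (homozygous alternate) and
:data:`MISSING` (``-1``) for uncalled genotypes.  Diploid dosage is assumed for
every downstream computation; haploid calls are promoted to the matching
homozygous state at ingestion.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import NoDataError, ValidationError

MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """Samples x loci alternate-allele dosage matrix with a missing mask.

    Parameters
    ----------
    sample_ids : ndarray of str
        Unique sample (accession) identifiers, one per row.
    locus_ids : ndarray of str
        Unique locus identifiers, one per column.
    dosage : ndarray of int8, shape (n_samples, n_loci)
        Codes in ``{0, 1, 2, MISSING}``.
    ploidy_note : str
        Free-text provenance tag; all computation assumes diploid dosage.
    """

    sample_ids: np.ndarray
    locus_ids: np.ndarray
    dosage: np.ndarray
    ploidy_note: str = "diploid dosage assumed"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValidationError("dosage must be a 2-D samples x loci array")
        if self.dosage.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid dosage code {self.dosage[i, j]!r} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        self.dosage = self.dosage.astype(np.int8, copy=False)
        for name, ids in (("sample", self.sample_ids), ("locus", self.locus_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Series(ids).loc[lambda s: s.duplicated()].iloc[0]
                raise ValidationError(f"duplicate {name} id {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return self.dosage == MISSING

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row-subset (or reorder) by positional index."""
        return GenotypeMatrix(
            self.sample_ids[index], self.locus_ids, self.dosage[index],
            self.ploidy_note,
        )

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """Column-subset (or reorder) by positional index."""
        return GenotypeMatrix(
            self.sample_ids, self.locus_ids[index], self.dosage[:, index],
            self.ploidy_note,
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples x loci DataFrame with MISSING as pandas NA."""
        df = pd.DataFrame(
            self.dosage, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.locus_ids, dtype="Int8",
        )
        return df.mask(df == MISSING)


@dataclass
class FilterLog:
    """Per-rule removal counts from :func:`filter_loci`."""

    n_input: int
    removed_monomorphic: int = 0
    removed_maf: int = 0
    removed_missing: int = 0

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.removed_monomorphic
                - self.removed_maf - self.removed_missing)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF (plain or gzip) into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained.  GT fields map to alternate-allele
    dosage (phase ignored); any genotype containing a missing allele becomes
    :data:`MISSING`; haploid calls are promoted (``0`` -> 0, ``1`` -> 2).
    Locus ids come from the ID field when present, else ``CHROM:POS`` (with an
    ``:k`` ordinal appended on collision).
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if not os.path.exists(path):
        raise OSError(f"cannot read VCF: no such file {path!r}")
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exception on malformed input
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"duplicate sample names in VCF {path!r}")

    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    seen: dict[str, int] = {}
    n_records = 0
    for v in vcf:
        n_records += 1
        if len(v.ALT) != 1:
            continue  # biallelic only
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # SNPs only, no indels
        dos = np.empty(len(samples), dtype=np.int8)
        for i, call in enumerate(v.genotypes):
            alleles = call[:-1]  # trailing element is the phase flag
            if any(a < 0 for a in alleles):
                dos[i] = MISSING
            elif len(alleles) == 1:  # haploid: promote to homozygous state
                dos[i] = 2 * alleles[0]
            else:
                dos[i] = sum(alleles)
        lid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if lid in seen:
            seen[lid] += 1
            lid = f"{lid}:{seen[lid]}"
        seen.setdefault(lid, 0)
        locus_ids.append(lid)
        rows.append(dos)
    if not rows:
        raise NoDataError(
            f"no biallelic SNP records retained from {path!r} "
            f"({n_records} records read)"
        )
    dosage = np.stack(rows, axis=1)  # samples x loci
    return GenotypeMatrix(np.array(samples, dtype=object),
                          np.array(locus_ids, dtype=object), dosage,
                          ploidy_note=f"read from VCF {os.path.basename(path)}")


def read_matrix(
    path: str | os.PathLike,
    orientation: str = "samples_by_loci",
    missing_token: str = "NA",
    delimiter: str | None = None,
) -> GenotypeMatrix:
    """Read a delimited dosage matrix with an ID header row and column.

    ``orientation`` is ``"samples_by_loci"`` or ``"loci_by_samples"``; the
    latter is transposed on ingestion.  Cells must be ``0``, ``1``, ``2`` or
    ``missing_token``.  Delimiter defaults to tab for ``.tsv``/``.txt`` and
    comma otherwise.
    """
    if orientation not in ("samples_by_loci", "loci_by_samples"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = os.fspath(path)
    if delimiter is None:
        delimiter = "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","
    # keep_default_na=False so tokens like "NA" survive as literal text
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     keep_default_na=False)
    if orientation == "loci_by_samples":
        df = df.T
    values = df.to_numpy()
    dosage = np.full(values.shape, MISSING, dtype=np.int8)
    alphabet = {"0": 0, "1": 1, "2": 2}
    for token, code in alphabet.items():
        dosage[values == token] = code
    ok = np.isin(values, list(alphabet)) | (values == missing_token)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValidationError(
            f"invalid cell {values[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} (expected 0/1/2/{missing_token})"
        )
    return GenotypeMatrix(df.index.to_numpy(dtype=object),
                          df.columns.to_numpy(dtype=object), dosage)


def write_matrix(
    G: GenotypeMatrix,
    path: str | os.PathLike,
    orientation: str = "samples_by_loci",
    missing_token: str = "NA",
    delimiter: str = ",",
) -> None:
    """Write the dosage matrix in the dialect :func:`read_matrix` accepts."""
    df = pd.DataFrame(G.dosage.astype(object), index=G.sample_ids,
                      columns=G.locus_ids)
    df = df.mask(df == MISSING, missing_token)
    if orientation == "loci_by_samples":
        df = df.T
        df.index.name = "locus_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter)


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Emit a minimal VCF (GT only) for round-trip testing and interchange.

    Locus ids of the form ``CHROM:POS`` are split back into coordinates;
    anything else is placed on a synthetic contig at consecutive positions
    with the id preserved in the ID column.  REF/ALT are arbitrary (A/T):
    dosage data carries no allele identity.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in G.sample_ids) + "\n")
        for j, lid in enumerate(G.locus_ids):
            parts = str(lid).split(":")
            if len(parts) == 2 and parts[1].isdigit():
                chrom, pos, vid = parts[0], parts[1], "."
            else:
                chrom, pos, vid = "1", str(j + 1), str(lid)
            gts = "\t".join(_VCF_GT[int(d)] for d in G.dosage[:, j])
            fh.write(f"{chrom}\t{pos}\t{vid}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def locus_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus allele frequency, MAF, missing rate and call count.

    Returns a DataFrame with columns ``locus_id``, ``alt_allele_freq``,
    ``maf``, ``missing_rate``, ``n_called``.  Loci with no calls get NaN
    frequencies and missing_rate 1.
    """
    if G.n_loci == 0 or G.n_samples == 0:
        raise NoDataError("empty genotype matrix")
    called = G.dosage != MISSING
    n_called = called.sum(axis=0)
    alt_sum = np.where(called, G.dosage, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame({
        "locus_id": G.locus_ids,
        "alt_allele_freq": freq,
        "maf": maf,
        "missing_rate": 1.0 - n_called / G.n_samples,
        "n_called": n_called,
    })


def filter_loci(
    G: GenotypeMatrix,
    remove_monomorphic: bool = True,
    min_maf: float | None = None,
    max_missing: float | None = None,
    return_log: bool = False,
):
    """Drop loci by polymorphism, MAF and missing-rate rules.

    Retained loci satisfy ``maf > 0`` (if ``remove_monomorphic``),
    ``maf >= min_maf`` and ``missing_rate <= max_missing``.  The sample set is
    unchanged.  With ``return_log=True`` also returns a :class:`FilterLog`
    attributing each removed locus to the first rule it failed
    (monomorphic, then MAF, then missing rate).
    """
    for name, thr in (("min_maf", min_maf), ("max_missing", max_missing)):
        if thr is not None and not 0.0 <= thr <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {thr}")
    stats = locus_stats(G)
    maf = stats["maf"].to_numpy()
    miss = stats["missing_rate"].to_numpy()
    log = FilterLog(n_input=G.n_loci)
    alive = np.ones(G.n_loci, dtype=bool)
    if remove_monomorphic:
        # all-missing loci carry no variation either: treat NaN maf as monomorphic
        hit = alive & ~(maf > 0)
        log.removed_monomorphic = int(hit.sum())
        alive &= ~hit
    if min_maf is not None:
        hit = alive & ~(maf >= min_maf)
        log.removed_maf = int(hit.sum())
        alive &= ~hit
    if max_missing is not None:
        hit = alive & ~(miss <= max_missing)
        log.removed_missing = int(hit.sum())
        alive &= ~hit
    if not alive.any():
        raise NoDataError(
            "all loci removed by filters "
            f"(monomorphic: {log.removed_monomorphic}, maf: {log.removed_maf}, "
            f"missing: {log.removed_missing})"
        )
    out = G.take_loci(np.flatnonzero(alive))
    return (out, log) if return_log else out


def write_results(
    tables: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
    out_dir: str | os.PathLike,
    float_format: str = "%.10g",
) -> pd.DataFrame:
    """Write named result tables as ``<name>.csv`` under ``out_dir``.

    Returns the manifest (name, path, n_rows) and writes it as
    ``manifest.txt``.  Duplicate table names are a validation error.
    """
    items = list(tables.items()) if isinstance(tables, Mapping) else list(tables)
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate table names in write_results")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} not writable: {exc}") from exc
    records = []
    for name, df in items:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format=float_format)
        records.append({"name": name, "path": str(path), "n_rows": len(df)})
    manifest = pd.DataFrame(records, columns=["name", "path", "n_rows"])
    with open(out_dir / "manifest.txt", "w") as fh:
        for rec in records:
            fh.write(f"{rec['name']}\t{rec['path']}\t{rec['n_rows']}\n")
    return manifest


def file_checksum(path: str | os.PathLike) -> str:
    """SHA-256 of a file, for run-log provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
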