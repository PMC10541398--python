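"""Genotype data model, VCF I/O, and genotype-level site filters.

The central container is :class:`GenotypeMatrix`: samples x biallelic SNP
sites with calls encoded as alternate-allele dosage (0 = hom-ref, 1 = het,
2 = hom-alt) and a distinct ``MISSING`` sentinel (-1).  Dosage never stands
in for a missing call and vice versa.

Site filters mirror the genotype-level options of RAD-seq genotyping
pipelines: a minimum per-site call rate (``-R``), a single-SNP-per-locus
restriction, and a minor-allele-frequency floor.  The order of application
is presence -> single-SNP -> MAF and is recorded in the attrition report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing call.  Distinct from every valid dosage.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})
_NUCLEOTIDES = frozenset("ACGT")


class GenotypeError(ValueError):
    """Fatal problem with genotype input (unreadable file, empty matrix, ...)."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    ``replicate_of`` names another sample of which this one is a technical
    re-measurement (same plant, independent library); ``region_label`` is a
    free-text geographic label (e.g. district).
    """

    sample_id: str
    region_label: str | None = None
    replicate_of: str | None = None


@dataclass(frozen=True)
class SiteMeta:
    """One biallelic SNP: locus identifier, 1-based position, ref/alt alleles."""

    locus_id: str
    position: int
    ref_allele: str = "A"
    alt_allele: str = "C"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int]:
        return (self.locus_id, self.position)


@dataclass(frozen=True)
class FilterConfig:
    """Genotype-level site filters.

    Parameters
    ----------
    min_presence_fraction
        Minimum fraction of samples with a non-missing call at a site
        (the ``-R`` option of RAD genotyping pipelines).
    min_maf
        Minimum minor-allele frequency, computed over non-missing diploid
        calls; a site exactly at the floor is retained.
    single_snp_per_locus
        Keep only the lowest-position SNP of each locus.
    """

    min_presence_fraction: float = 0.5
    min_maf: float = 0.05
    single_snp_per_locus: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_presence_fraction <= 1.0:
            raise ValueError("min_presence_fraction must lie in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of biallelic SNP dosages.

    ``calls[i, j]`` is the alternate-allele dosage of sample ``i`` at site
    ``j`` — one of ``{0, 1, 2, MISSING}``.
    """

    samples: list[SampleMeta]
    sites: list[SiteMeta]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample IDs are not unique")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("site keys (locus_id, position) are not unique")
        known = set(ids)
        for s in self.samples:
            if s.replicate_of is not None and s.replicate_of not in known:
                raise ValueError(
                    f"{s.sample_id}: replicate_of={s.replicate_of!r} is not a sample"
                )
        self._index = {sid: i for i, sid in enumerate(ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def sample_calls(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        sites = [s for s, k in zip(self.sites, keep) if k]
        return GenotypeMatrix(self.samples, sites, self.calls[:, keep])

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        kept = set(sample_ids)
        samples = []
        for i in idx:
            s = self.samples[i]
            if s.replicate_of is not None and s.replicate_of not in kept:
                s = replace(s, replicate_of=None)
            samples.append(s)
        return GenotypeMatrix(samples, list(self.sites), self.calls[idx])

    def alt_allele_frequencies(self) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing calls (NaN if none)."""
        valid = self.calls != MISSING
        dose = np.where(valid, self.calls, 0).astype(float)
        n_alleles = 2.0 * valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, dose.sum(axis=0) / n_alleles, np.nan)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and [s.key for s in self.sites] == [s.key for s in other.sites]
            and np.array_equal(self.calls, other.calls)
        )


# -- VCF I/O ---------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF file into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNP records (indels, symbolic alleles) are
    skipped with a logged count.  ``./.`` (or ``.|.``) genotypes map to
    ``MISSING``; phased and unphased separators are treated identically.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise GenotypeError(f"cannot read VCF: no such file {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise GenotypeError(f"cannot read VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    sites: list[SiteMeta] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        if rec.REF not in _NUCLEOTIDES or alts[0] not in _NUCLEOTIDES:
            n_skipped += 1
            continue
        sites.append(SiteMeta(rec.CHROM, rec.POS, rec.REF, alts[0]))
        columns.append(remap[rec.gt_types])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not sites:
        raise GenotypeError(f"no biallelic SNPs retained from {path}")
    calls = np.stack(columns, axis=1)
    samples = [SampleMeta(sid) for sid in sample_ids]
    return GenotypeMatrix(samples, sites, calls)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal VCF 4.2 text file.

    The emitted file round-trips through :func:`read_vcf` with identical
    calls.  Missing calls are written as ``./.``.
    """
    path = Path(path)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    loci = list(dict.fromkeys(s.locus_id for s in matrix.sites))
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=clonalpop\n")
            for locus in loci:
                fh.write(f"##contig=<ID={locus}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(matrix.sample_ids)
                + "\n"
            )
            for j, site in enumerate(matrix.sites):
                gts = "\t".join(gt_strings[int(g)] for g in matrix.calls[:, j])
                fh.write(
                    f"{site.locus_id}\t{site.position}\t.\t{site.ref_allele}\t"
                    f"{site.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
                )
    except OSError as exc:
        raise GenotypeError(f"cannot write VCF {path}: {exc}") from exc


# -- sample metadata CSV ---------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata from a CSV with columns sample_id,region_label,replicate_of."""
    df = pd.read_csv(path, dtype=str).fillna("")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            SampleMeta(
                sample_id=row.sample_id,
                region_label=getattr(row, "region_label", "") or None,
                replicate_of=getattr(row, "replicate_of", "") or None,
            )
        )
    return metas


def attach_sample_metadata(matrix: GenotypeMatrix, metas: list[SampleMeta]) -> GenotypeMatrix:
    """Return a copy of *matrix* with metadata merged in by sample_id."""
    by_id = {m.sample_id: m for m in metas}
    samples = [by_id.get(s.sample_id, s) for s in matrix.samples]
    return GenotypeMatrix(samples, list(matrix.sites), matrix.calls.copy())


# -- filters ---------------------------------------------------------------

@dataclass(frozen=True)
class FilterReport:
    """Per-filter attrition counts from one :func:`apply_filters` run."""

    n_input: int
    removed_presence: int
    removed_single_snp: int
    removed_maf: int

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.removed_presence
            - self.removed_single_snp
            - self.removed_maf
        )


def apply_filters(
    matrix: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the site filters in the order presence -> single-SNP -> MAF.

    Filtering selects sites; it never alters the surviving calls.  Raises
    :class:`GenotypeError` if no site survives, reporting per-filter
    attrition.
    """
    calls = matrix.calls
    n_input = matrix.n_sites
    valid = calls != MISSING

    presence = valid.sum(axis=0) / matrix.n_samples
    keep = presence >= cfg.min_presence_fraction
    removed_presence = int(n_input - keep.sum())

    removed_single = 0
    if cfg.single_snp_per_locus:
        best: dict[str, int] = {}
        for j, site in enumerate(matrix.sites):
            if not keep[j]:
                continue
            prev = best.get(site.locus_id)
            if prev is None or site.position < matrix.sites[prev].position:
                best[site.locus_id] = j
        chosen = set(best.values())
        for j in range(n_input):
            if keep[j] and j not in chosen:
                keep[j] = False
                removed_single += 1

    dose = np.where(valid, calls, 0).astype(float)
    n_alleles = 2.0 * valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_alleles > 0, dose.sum(axis=0) / n_alleles, np.nan)
    maf = np.fmin(p_alt, 1.0 - p_alt)
    removed_maf = 0
    for j in range(n_input):
        if keep[j] and not (maf[j] >= cfg.min_maf):  # NaN fails too
            keep[j] = False
            removed_maf += 1

    report = FilterReport(n_input, removed_presence, removed_single, removed_maf)
    if not keep.any():
        raise GenotypeError(
            "all sites removed by filters "
            f"(presence: {removed_presence}, single-SNP: {removed_single}, "
            f"MAF: {removed_maf} of {n_input})"
        )
    logger.info(
        "apply_filters: %d -> %d sites (presence -%d, single-SNP -%d, MAF -%d)",
        n_input, report.n_retained, removed_presence, removed_single, removed_maf,
    )
    return matrix.subset_sites(keep), report


def heterozygosity_ratio(matrix: GenotypeMatrix, sample_id: str) -> float:
    """Fraction of a sample's non-missing calls that are heterozygous.

    A low ratio (below ~0.2) flags individuals with a marked shift toward
    homozygosity, e.g. from inbreeding after hybridization.
    """
    row = matrix.sample_calls(sample_id)
    n_valid = int((row != MISSING).sum())
    if n_valid == 0:
        raise GenotypeError(f"sample {sample_id!r} has no non-missing calls")
    return float((row == 1).sum() / n_valid)


def heterozygosity_screen(
    matrix: GenotypeMatrix, threshold: float = 0.2
) -> pd.DataFrame:
    """Het ratio per sample with a ``low_het`` flag for ratios below *threshold*."""
    rows = []
    for sid in matrix.sample_ids:
        r = heterozygosity_ratio(matrix, sid)
        rows.append({"sample_id": sid, "het_ratio": r, "low_het": r < threshold})
    return pd.DataFrame(rows)
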