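"""Cohort containers, genotype I/O, and descriptive genetics statistics.

A :class:`Cohort` holds a sample-by-variant matrix of minor-allele dosages
(0/1/2, ``nan`` for missing), a binary phenotype (1 = high-aggressive
disease, 0 = low-aggressive), and the three adjustment covariates used
throughout the pipeline: age in years, a binary study-site indicator
(1 = Louisiana, 0 = North Carolina), and a genetic-ancestry proportion
in [0, 1].

Genotypes can be read from a delimited sample-by-variant table (dosage or
allele-pair cells) or from a minimal biallelic VCF.  Minor alleles are
always defined *within* the analysed stratum: :func:`determine_minor_alleles`
re-orients dosages so that every variant counts its less common allele,
which matters because minor/major assignments can flip between ancestry
groups (e.g. rs4652, or a 19-bp del/ins treated as ordinary alleles).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "Cohort",
    "ClinicalRecord",
    "GenotypeDistribution",
    "TableDialect",
    "GenotypeFormatError",
    "DataError",
    "ClassificationError",
    "read_genotype_table",
    "read_variant_table",
    "read_vcf_biallelic",
    "determine_minor_alleles",
    "compute_maf",
    "ld_r2",
    "genotype_distribution",
    "compare_distributions",
    "classify_aggressiveness",
]


class GenotypeFormatError(ValueError):
    """The input file does not have the structure the reader requires."""


class DataError(ValueError):
    """The file parsed but its contents violate a data contract."""


class ClassificationError(ValueError):
    """A clinical record is incomplete or out of range."""


@dataclass
class Variant:
    """A biallelic polymorphism with a cohort-specific minor allele.

    ``minor_allele`` must be one of the two allele labels; ``maf`` is the
    minor-allele frequency in the cohort the variant was oriented against
    (<= 0.5 after :func:`determine_minor_alleles`).  Indels are represented
    with ordinary allele labels such as ``"del"``/``"ins"``.
    """

    variant_id: str
    chromosome: str = ""
    position: int | None = None
    gene: str = ""
    allele_a: str | None = None
    allele_b: str | None = None
    minor_allele: str | None = None
    maf: float | None = None
    monomorphic: bool = False

    def __post_init__(self) -> None:
        if self.minor_allele is not None and self.allele_a is not None:
            if self.minor_allele not in (self.allele_a, self.allele_b):
                raise ValueError(
                    f"{self.variant_id}: minor allele {self.minor_allele!r} is "
                    f"not one of {self.allele_a!r}/{self.allele_b!r}"
                )
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.variant_id}: maf {self.maf} outside [0, 0.5]")

    @property
    def major_allele(self) -> str | None:
        if self.minor_allele is None or self.allele_a is None:
            return None
        return self.allele_b if self.minor_allele == self.allele_a else self.allele_a

    def genotype_labels(self) -> tuple[str, str, str]:
        """Genotype strings for dosage 0/1/2, major allele written first."""
        maj, mnr = self.major_allele, self.minor_allele
        if maj is None or mnr is None:
            return ("0", "1", "2")
        sep = "/" if max(len(maj), len(mnr)) > 1 else ""
        return (sep.join([maj, maj]), sep.join([maj, mnr]), sep.join([mnr, mnr]))


@dataclass
class Cohort:
    """One race stratum: dosage matrix, binary phenotype, covariates."""

    samples: list[str]
    variants: list[Variant]
    genotypes: np.ndarray  # (n_samples, n_variants) float, nan = missing
    phenotype: np.ndarray  # float 0/1, nan = missing
    age: np.ndarray
    site: np.ndarray
    ancestry: np.ndarray
    stratum_label: str = ""

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.variants):
            raise DataError("genotype matrix shape inconsistent with sample/variant lists")
        for arr_name in ("phenotype", "age", "site", "ancestry"):
            if len(getattr(self, arr_name)) != n:
                raise DataError(f"{arr_name} length != number of samples")
        ph = self.phenotype[np.isfinite(self.phenotype)]
        if ph.size and not np.all(np.isin(ph, (0.0, 1.0))):
            raise DataError("phenotype must be binary 0/1 among non-missing values")
        anc = self.ancestry[np.isfinite(self.ancestry)]
        if anc.size and (anc.min() < 0 or anc.max() > 1):
            raise DataError("ancestry proportions must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in cohort") from None

    def variant(self, variant_id: str) -> Variant:
        return self.variants[self.index(variant_id)]

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.genotypes[:, self.index(variant_id)]

    def covariates(self) -> np.ndarray:
        """(n, 3) array of [age, site, ancestry]."""
        return np.column_stack([self.age, self.site, self.ancestry]).astype(float)

    covariate_names = ("age", "site", "ancestry")


@dataclass
class ClinicalRecord:
    """Diagnostic work-up values used to grade tumour aggressiveness."""

    gleason: int
    psa: float
    stage: str  # clinical T-stage, "T1".."T4"


@dataclass
class GenotypeDistribution:
    """Counts of the three genotype classes plus missing calls."""

    hom_major: int
    het: int
    hom_minor: int
    missing: int = 0

    def __post_init__(self) -> None:
        if min(self.hom_major, self.het, self.hom_minor, self.missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_genotyped(self) -> int:
        return self.hom_major + self.het + self.hom_minor

    def as_array(self) -> np.ndarray:
        return np.array([self.hom_major, self.het, self.hom_minor], dtype=float)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@dataclass
class TableDialect:
    """Column names and conventions for the delimited genotype table."""

    sep: str = "\t"
    sample_id: str | None = "sample"
    phenotype: str | None = "phenotype"
    age: str = "age"
    site: str = "site"
    ancestry: str = "ancestry"
    missing_tokens: tuple[str, ...] = ("", ".", "NA", "NaN", "nan")


def _parse_genotype_cell(cell: str, variant: Variant, dialect: TableDialect) -> float:
    cell = cell.strip()
    if cell in dialect.missing_tokens:
        return math.nan
    sep = "/" if "/" in cell else ("|" if "|" in cell else None)
    if sep is not None:
        if variant.minor_allele is None:
            raise GenotypeFormatError(
                f"{variant.variant_id}: allele-pair genotype {cell!r} requires a "
                "declared minor allele (provide variant metadata)"
            )
        alleles = [a.strip() for a in cell.split(sep)]
        known = {variant.allele_a, variant.allele_b} - {None}
        if len(alleles) != 2 or (known and not all(a in known for a in alleles)):
            log.warning("%s: unparseable genotype %r treated as missing",
                        variant.variant_id, cell)
            return math.nan
        return float(sum(a == variant.minor_allele for a in alleles))
    try:
        value = float(cell)
    except ValueError:
        log.warning("%s: unparseable genotype %r treated as missing",
                    variant.variant_id, cell)
        return math.nan
    if value not in (0.0, 1.0, 2.0):
        log.warning("%s: dosage %r outside {0,1,2} treated as missing",
                    variant.variant_id, cell)
        return math.nan
    return value


def read_variant_table(path, sep: str = "\t") -> list[Variant]:
    """Read a variant-metadata sidecar (variant_id, chromosome, position,
    gene, allele_a, allele_b, minor_allele)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "variant_id" not in df.columns:
        raise GenotypeFormatError("variant table needs a 'variant_id' column")
    out = []
    for _, row in df.iterrows():
        pos = row.get("position", "")
        out.append(Variant(
            variant_id=row["variant_id"],
            chromosome=row.get("chromosome", ""),
            position=int(pos) if str(pos).strip() else None,
            gene=row.get("gene", ""),
            allele_a=row.get("allele_a") or None,
            allele_b=row.get("allele_b") or None,
            minor_allele=row.get("minor_allele") or None,
        ))
    return out


def read_genotype_table(path, variants: list[Variant] | None = None,
                        dialect: TableDialect | None = None,
                        stratum_label: str = "") -> Cohort:
    """Read a delimited sample-by-variant table into a :class:`Cohort`.

    Genotype cells may be dosages in {0, 1, 2} or allele pairs such as
    ``A/G`` (counted against each variant's declared minor allele).
    Unparseable cells become missing; a non-binary phenotype is an error.
    """
    dialect = dialect or TableDialect()
    if not dialect.phenotype:
        raise DataError("dialect must name the phenotype column")
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)

    mandatory = [dialect.phenotype, dialect.age, dialect.site, dialect.ancestry]
    absent = [c for c in mandatory if c not in df.columns]
    if absent:
        raise GenotypeFormatError(f"mandatory column(s) missing: {absent}")

    reserved = set(mandatory) | ({dialect.sample_id} if dialect.sample_id else set())
    if variants is None:
        geno_cols = [c for c in df.columns if c not in reserved]
        variants = [Variant(variant_id=c) for c in geno_cols]
    else:
        geno_cols = [v.variant_id for v in variants]
        absent = [c for c in geno_cols if c not in df.columns]
        if absent:
            raise GenotypeFormatError(f"genotype column(s) missing: {absent}")

    def numeric(col: str) -> np.ndarray:
        raw = df[col].astype(str).str.strip()
        raw = raw.where(~raw.isin(dialect.missing_tokens), other="")
        return pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)

    phenotype = numeric(dialect.phenotype)
    bad = phenotype[np.isfinite(phenotype)]
    if bad.size and not np.all(np.isin(bad, (0.0, 1.0))):
        raise DataError(
            f"phenotype column {dialect.phenotype!r} contains non-binary values")

    geno = np.empty((len(df), len(variants)), dtype=float)
    for j, var in enumerate(variants):
        col = df[var.variant_id].astype(str)
        geno[:, j] = [_parse_genotype_cell(c, var, dialect) for c in col]

    if dialect.sample_id and dialect.sample_id in df.columns:
        samples = df[dialect.sample_id].astype(str).tolist()
    else:
        samples = [f"S{i:05d}" for i in range(len(df))]

    return Cohort(samples=samples, variants=variants, genotypes=geno,
                  phenotype=phenotype, age=numeric(dialect.age),
                  site=numeric(dialect.site), ancestry=numeric(dialect.ancestry),
                  stratum_label=stratum_label)


def read_vcf_biallelic(path, sample_subset: list[str] | None = None):
    """Read biallelic records from a VCF into (dosage matrix, variants, samples).

    Dosage is the ALT-allele count (re-orient to the cohort minor allele
    afterwards with :func:`determine_minor_alleles`).  Multi-allelic records
    are skipped with a warning; any half-missing genotype (``./1``) is
    treated as fully missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=sample_subset, gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeFormatError("VCF has no sample columns / GT data")

    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            log.warning("skipping non-biallelic record %s:%s (%s)",
                        rec.CHROM, rec.POS, ",".join(rec.ALT) or "no ALT")
            continue
        gts = rec.genotypes
        if gts is None:
            raise GenotypeFormatError("record lacks GT field")
        dos = np.empty(len(samples), dtype=float)
        for i, gt in enumerate(gts):
            a = gt[:-1]  # last element is the phased flag
            dos[i] = math.nan if min(a) < 0 else float(sum(x == 1 for x in a))
        rows.append(dos)
        variants.append(Variant(
            variant_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
            chromosome=str(rec.CHROM), position=int(rec.POS),
            allele_a=rec.REF, allele_b=rec.ALT[0], minor_allele=rec.ALT[0],
        ))
    matrix = (np.column_stack(rows) if rows
              else np.empty((len(samples), 0), dtype=float))
    return matrix, variants, samples


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def compute_maf(dosages: np.ndarray) -> float:
    """Frequency of the allele the dosages count: sum(g) / (2 * n_nonmissing)."""
    d = np.asarray(dosages, dtype=float)
    obs = d[np.isfinite(d)]
    if obs.size == 0:
        raise DataError("no non-missing genotypes")
    return float(obs.sum() / (2.0 * obs.size))


def determine_minor_alleles(cohort: Cohort) -> list[Variant]:
    """Assign each variant's minor allele from THIS cohort's frequencies.

    Where the currently counted allele has frequency > 0.5 the dosages are
    flipped (g -> 2 - g) and the minor-allele label is swapped.  An exact
    tie at 0.5 is broken toward the lexicographically smaller allele label.
    Monomorphic variants are flagged (downstream models must exclude them).
    Idempotent; mutates the cohort in place and returns its variant list.
    """
    for j, var in enumerate(cohort.variants):
        g = cohort.genotypes[:, j]
        freq = compute_maf(g)
        flip = freq > 0.5
        if freq == 0.5 and var.allele_a is not None and var.minor_allele is not None:
            flip = var.major_allele < var.minor_allele
        if flip:
            cohort.genotypes[:, j] = np.where(np.isfinite(g), 2.0 - g, np.nan)
            if var.minor_allele is not None:
                var.minor_allele = var.major_allele
            freq = compute_maf(cohort.genotypes[:, j])
        var.maf = freq
        var.monomorphic = freq == 0.0
        if var.monomorphic:
            log.warning("%s is monomorphic in stratum %r",
                        var.variant_id, cohort.stratum_label)
    return cohort.variants


def ld_r2(dosages_1: np.ndarray, dosages_2: np.ndarray) -> float:
    """Composite (dosage-based) LD: squared Pearson correlation.

    Missing genotypes are dropped pairwise.  Returns ``nan`` (flagged) when
    fewer than two complete pairs remain or either vector is constant.
    """
    d1 = np.asarray(dosages_1, dtype=float)
    d2 = np.asarray(dosages_2, dtype=float)
    mask = np.isfinite(d1) & np.isfinite(d2)
    x, y = d1[mask], d2[mask]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("LD r² undefined (n=%d complete pairs)", x.size)
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def genotype_distribution(dosages: np.ndarray) -> GenotypeDistribution:
    d = np.asarray(dosages, dtype=float)
    obs = d[np.isfinite(d)]
    return GenotypeDistribution(
        hom_major=int(np.sum(obs == 0)),
        het=int(np.sum(obs == 1)),
        hom_minor=int(np.sum(obs == 2)),
        missing=int(np.sum(~np.isfinite(d))),
    )


def compare_distributions(d1: GenotypeDistribution,
                          d2: GenotypeDistribution) -> tuple[float, float]:
    """Pearson chi-square comparing two genotype distributions.

    Categories empty in both groups are collapsed out before testing.
    Returns (statistic, p).
    """
    table = np.vstack([d1.as_array(), d2.as_array()])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or np.any(table.sum(axis=1) == 0):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Clinical classification
# ---------------------------------------------------------------------------

def _stage_number(stage: str) -> int:
    s = str(stage).strip().upper()
    if s.startswith("T"):
        s = s[1:]
    if not s or s[0] not in "1234":
        raise ClassificationError(f"unrecognised clinical stage {stage!r}")
    return int(s[0])


def classify_aggressiveness(record: ClinicalRecord) -> str:
    """Grade a case as 'high', 'intermediate' or 'low' aggressive.

    High: Gleason >= 8, or PSA > 20 ng/mL, or Gleason >= 7 with stage T3-T4.
    Low: Gleason < 7 and stage T1-T2 and PSA < 10 ng/mL.
    Everything else is intermediate.
    """
    if record is None or record.gleason is None or record.psa is None \
            or record.stage is None:
        raise ClassificationError("gleason, psa and stage are all required")
    if not 2 <= record.gleason <= 10:
        raise ClassificationError(f"Gleason score {record.gleason} outside [2, 10]")
    if record.psa < 0:
        raise ClassificationError("PSA must be non-negative")
    t = _stage_number(record.stage)
    if record.gleason >= 8 or record.psa > 20 or (record.gleason >= 7 and t >= 3):
        return "high"
    if record.gleason < 7 and t <= 2 and record.psa < 10:
        return "low"
    return "intermediate"
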