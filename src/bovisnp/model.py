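"""Domain types shared by every stage of the pipeline.

The experimental unit is a young bull sampled at one of three ages (6, 9,
12 months) in one of three cattle breeds (Polish Red, Polish
Holstein-Friesian, Hereford), two biological replicates per breed x age
cell: a complete panel is 18 samples.  Variant evidence is carried per
sample; breed-level SNP databases key records by (chromosome, position,
alternate allele) and keep every supporting record, so all downstream
filters can reason about read depth and the SNP ratio (fraction of
covering reads that support the alternate allele).

All genomic coordinates are 1-based inclusive internally, matching the
convention of locus identifiers such as ``BTA19_24970466``; BED input and
output are converted at the boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional


class ValidationError(ValueError):
    """An input object or file violates a structural invariant."""


class Breed(str, enum.Enum):
    POLISH_RED = "PolishRed"
    POLISH_HF = "PolishHF"
    HEREFORD = "Hereford"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


AGES = (6, 9, 12)
REPLICATES = (1, 2)

#: Genotype codes used in validation tables. R = reference allele,
#: A = alternate allele; "--" marks a failed/missing call.
GENOTYPES = ("RR", "RA", "AA")
MISSING_GENOTYPE = "--"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'BTA'/'Chr'/'chr' prefix so that 'BTA19', 'chr19'
    and '19' key identically.  The original label is kept for display."""
    c = str(chrom)
    for prefix in ("BTA", "Chr", "chr", "CHR"):
        if c.startswith(prefix) and len(c) > len(prefix):
            return c[len(prefix):]
    return c


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequenced animal within the panel."""

    sample_id: str
    breed: Breed
    age_months: int
    replicate: int

    def __post_init__(self) -> None:
        if self.age_months not in AGES:
            raise ValidationError(
                f"age_months must be one of {AGES}, got {self.age_months}")
        if self.replicate not in REPLICATES:
            raise ValidationError(
                f"replicate must be 1 or 2, got {self.replicate}")

    @property
    def cell(self) -> tuple[Breed, int]:
        return (self.breed, self.age_months)


def full_panel() -> list[SampleMeta]:
    """The 3 breeds x 3 ages x 2 replicates = 18 sample design."""
    panel = []
    for breed in Breed:
        for age in AGES:
            for rep in REPLICATES:
                panel.append(SampleMeta(
                    sample_id=f"{breed.value}_{age}m_r{rep}",
                    breed=breed, age_months=age, replicate=rep))
    return panel


def validate_panel(panel: Iterable[SampleMeta]) -> None:
    """(breed, age, replicate) must be unique within a panel."""
    seen: set[tuple] = set()
    for s in panel:
        key = (s.breed, s.age_months, s.replicate)
        if key in seen:
            raise ValidationError(f"duplicate panel cell/replicate: {key}")
        seen.add(key)


class VariantClass(str, enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """SNP iff both alleles are a single base and the alt does not use the
    +/- pileup indel encoding."""
    if alt and alt[0] in "+-":
        return VariantClass.INDEL
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNP
    return VariantClass.INDEL


@dataclass(frozen=True)
class VariantRecord:
    """One called variant allele in one sample.

    ``snp_ratio`` is a derived quantity, never stored: the fraction of
    reads covering the position that support the alternate allele.  A
    ratio of exactly 100% (all covering reads carry the alternate) is
    tested on the integers ``alt_depth == total_depth`` to avoid floating
    error.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_allele: str
    total_depth: int
    alt_depth: int
    sample: SampleMeta
    variant_class: VariantClass = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not self.alt_allele:
            raise ValidationError("alt_allele must be non-empty")
        if not (0 < self.alt_depth <= self.total_depth):
            raise ValidationError(
                f"need 0 < alt_depth <= total_depth, got "
                f"alt={self.alt_depth} total={self.total_depth} "
                f"at {self.chrom}:{self.pos}")
        if self.variant_class is None:
            object.__setattr__(
                self, "variant_class",
                classify_alleles(self.ref_base, self.alt_allele))

    @property
    def snp_ratio(self) -> float:
        return self.alt_depth / self.total_depth

    @property
    def is_full_ratio(self) -> bool:
        """True iff every covering read supports the alternate."""
        return self.alt_depth == self.total_depth

    @property
    def key(self) -> tuple[str, int, str]:
        return (normalize_chrom(self.chrom), self.pos, self.alt_allele)

    @property
    def position(self) -> tuple[str, int]:
        return (normalize_chrom(self.chrom), self.pos)


SnpKey = tuple[str, int, str]


@dataclass
class SnpDb:
    """Keyed collection of SNP records for a breed (or pooled panel).

    Records are keyed by (normalised chromosome, position, alternate
    allele); each key holds every supporting :class:`VariantRecord` so
    per-sample evidence survives combination.  ``provenance`` is the
    ordered list of (operation, parameters) applied to reach this state.
    """

    breed: Optional[str] = None
    records: dict[SnpKey, list[VariantRecord]] = field(default_factory=dict)
    provenance: list[tuple[str, dict]] = field(default_factory=list)

    def add(self, rec: VariantRecord) -> None:
        self.records.setdefault(rec.key, []).append(rec)

    def keys(self):
        return self.records.keys()

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: SnpKey) -> bool:
        return key in self.records

    def __iter__(self) -> Iterator[SnpKey]:
        return iter(self.records)

    def key_set(self) -> set[SnpKey]:
        return set(self.records)

    def all_records(self) -> Iterator[VariantRecord]:
        for recs in self.records.values():
            yield from recs

    def positions(self) -> dict[tuple[str, int], set[str]]:
        """Map (chrom, pos) -> set of distinct alternate alleles."""
        out: dict[tuple[str, int], set[str]] = {}
        for (chrom, pos, alt) in self.records:
            out.setdefault((chrom, pos), set()).add(alt)
        return out

    def stamp(self, op: str, **params) -> None:
        self.provenance.append((op, dict(params)))

    def subset(self, keys: Iterable[SnpKey], breed: Optional[str] = None) -> "SnpDb":
        sub = SnpDb(breed=breed if breed is not None else self.breed,
                    provenance=list(self.provenance))
        for k in keys:
            sub.records[k] = list(self.records[k])
        return sub


FLAGSTAT_FIELDS = (
    "total", "mapped", "paired_in_sequencing", "read1", "read2",
    "properly_paired", "itself_and_mate_mapped", "singletons",
    "mate_diff_chr", "mate_diff_chr_mapq5",
)


@dataclass(frozen=True)
class FlagstatProfile:
    """The ten read-accounting counters of a paired-end alignment summary."""

    label: str
    total: int
    mapped: int
    paired_in_sequencing: int
    read1: int
    read2: int
    properly_paired: int
    itself_and_mate_mapped: int
    singletons: int
    mate_diff_chr: int
    mate_diff_chr_mapq5: int

    def __post_init__(self) -> None:
        for name in FLAGSTAT_FIELDS:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.read1 + self.read2 != self.paired_in_sequencing:
            raise ValidationError(
                f"read1 + read2 != paired_in_sequencing "
                f"({self.read1} + {self.read2} != {self.paired_in_sequencing})")
        if not (self.properly_paired <= self.mapped <= self.total):
            raise ValidationError(
                "need properly_paired <= mapped <= total, got "
                f"{self.properly_paired}, {self.mapped}, {self.total}")
        if self.singletons > self.mapped:
            raise ValidationError("singletons cannot exceed mapped")

    def counters(self) -> tuple[int, ...]:
        return tuple(getattr(self, f) for f in FLAGSTAT_FIELDS)


@dataclass(frozen=True)
class GeneLocus:
    """One QTL/candidate-gene interval, 1-based inclusive."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"locus {self.symbol}: start {self.start} > end {self.end}")

    @property
    def chrom_norm(self) -> str:
        return normalize_chrom(self.chrom)

    def contains(self, chrom: str, pos: int) -> bool:
        return (normalize_chrom(chrom) == self.chrom_norm
                and self.start <= pos <= self.end)


@dataclass
class GenotypeTable:
    """Per-animal biallelic genotype calls at one validation marker.

    calls: list of (animal_id, breed, genotype) with genotype in
    {RR, RA, AA, '--'} (R = reference allele, A = alternate allele).
    """

    marker_id: str
    allele_ref: str
    allele_alt: str
    calls: list[tuple[str, Breed, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, _, g in self.calls:
            if g not in GENOTYPES and g != MISSING_GENOTYPE:
                raise ValidationError(f"unknown genotype code {g!r}")

    def breeds(self) -> list[Breed]:
        seen = []
        for _, b, _ in self.calls:
            if b not in seen:
                seen.append(b)
        return seen

    def genotype_counts(self, breed: Breed) -> dict[str, int]:
        counts = {g: 0 for g in GENOTYPES}
        for _, b, g in self.calls:
            if b == breed and g != MISSING_GENOTYPE:
                counts[g] += 1
        return counts

    def n_typed(self, breed: Breed) -> int:
        return sum(self.genotype_counts(breed).values())
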