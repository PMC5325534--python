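"""Readers and writers for the formats the pipeline touches.

Variant calls come in either a VCF v4.x subset (CHROM, POS, REF, ALT with
depth in DP and alternate-supporting reads in DV or AD) parsed through
pysam, or a six-column TSV dialect ``chrom pos ref alt total_depth
alt_depth``.  Mapping summaries are ``samtools flagstat`` text or a
10-counter TSV.  Candidate-gene loci are BED4 (0-based half-open) or TSV
(1-based inclusive); coordinates are converted to the internal 1-based
inclusive convention at the boundary.  Genotype tables can be exported in
Genepop 4 input format for cross-checking against the original software.

The SNP ratio is always computed from the depth integers at read time,
never read from a column.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence, Union

import pysam

from .model import (
    MISSING_GENOTYPE,
    Breed,
    FlagstatProfile,
    FLAGSTAT_FIELDS,
    GeneLocus,
    GenotypeTable,
    SampleMeta,
    SnpDb,
    ValidationError,
    VariantRecord,
    normalize_chrom,
)

VARIANT_TSV_HEADER = ("chrom", "pos", "ref", "alt", "total_depth", "alt_depth")

# Chromosome labels considered canonical for the bovine assembly; anything
# else is retained but flagged, since a typo upstream would silently drop
# every locus intersection.
_KNOWN_CHROMS = {str(i) for i in range(1, 30)} | {"X", "Y", "MT", "M"}


# ---------------------------------------------------------------------------
# variant calls
# ---------------------------------------------------------------------------

def read_variant_calls(path, dialect: str, sample: SampleMeta) -> list[VariantRecord]:
    """Read per-sample variant calls from ``path``.

    dialect 'tsv': six columns (header optional) ``chrom pos ref alt
    total_depth alt_depth``.  dialect 'vcf': a VCF with depth in INFO/DP
    (or FORMAT/DP) and alternate support in INFO/DV or FORMAT/AD;
    multi-allelic lines are split into one record per alternate allele.

    Records whose alternate depth exceeds the total depth are rejected
    with a warning naming the offending line, never clamped.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_variant_tsv(path, sample)
    if dialect == "vcf":
        return _read_variant_vcf(path, sample)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _make_record(chrom, pos, ref, alt, total, altd, sample, where):
    if altd > total:
        warnings.warn(
            f"{where}: alt_depth {altd} > total_depth {total} at "
            f"{chrom}:{pos}; record rejected")
        return None
    try:
        return VariantRecord(chrom=chrom, pos=pos, ref_base=ref,
                             alt_allele=alt, total_depth=total,
                             alt_depth=altd, sample=sample)
    except ValidationError as exc:
        raise ValidationError(f"{where}: {exc}") from exc


def _read_variant_tsv(path: Path, sample: SampleMeta) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "chrom":
                continue
            if len(fields) != 6:
                raise ValidationError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}")
            chrom, pos_s, ref, alt, total_s, alt_s = fields
            try:
                pos, total, altd = int(pos_s), int(total_s), int(alt_s)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer field ({exc})") from exc
            rec = _make_record(chrom, pos, ref, alt, total, altd,
                               sample, f"{path}:{lineno}")
            if rec is not None:
                records.append(rec)
    return records


def _read_variant_vcf(path: Path, sample: SampleMeta) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            where = f"{path}:{rec.chrom}:{rec.pos}"
            total = rec.info.get("DP")
            if total is None and rec.samples:
                total = next(iter(rec.samples.values())).get("DP")
            if total is None:
                raise ValidationError(f"{where}: no DP depth field")
            alts = rec.alts or ()
            ad = None
            if rec.samples:
                ad = next(iter(rec.samples.values())).get("AD")
            dv = rec.info.get("DV")
            for i, alt in enumerate(alts):
                if ad is not None:
                    altd = ad[i + 1]
                elif dv is not None:
                    if len(alts) > 1:
                        raise ValidationError(
                            f"{where}: DV cannot apportion a multi-allelic "
                            "line; AD required")
                    altd = dv
                else:
                    raise ValidationError(
                        f"{where}: no DV/AD alternate-depth field")
                out = _make_record(rec.chrom, rec.pos, rec.ref, alt,
                                   int(total), int(altd), sample, where)
                if out is not None:
                    records.append(out)
    return records


def write_variant_calls(records: Sequence[VariantRecord], path,
                        dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(VARIANT_TSV_HEADER) + "\n")
            for r in records:
                fh.write(f"{r.chrom}\t{r.pos}\t{r.ref_base}\t{r.alt_allele}"
                         f"\t{r.total_depth}\t{r.alt_depth}\n")
    elif dialect == "vcf":
        _write_variant_vcf(records, path)
    else:
        raise ValueError(f"unknown variant dialect {dialect!r}")


def _write_variant_vcf(records: Sequence[VariantRecord], path: Path) -> None:
    contigs: list[str] = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                 'Description="Total read depth">\n')
        fh.write('##INFO=<ID=DV,Number=1,Type=Integer,'
                 'Description="Reads supporting the alternate allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref_base}\t{r.alt_allele}"
                     f"\t.\t.\tDP={r.total_depth};DV={r.alt_depth}\n")


# ---------------------------------------------------------------------------
# flagstat
# ---------------------------------------------------------------------------

_FLAGSTAT_PHRASES = [
    ("with mate mapped to a different chr (mapq>=5)", "mate_diff_chr_mapq5"),
    ("with mate mapped to a different chr", "mate_diff_chr"),
    ("with itself and mate mapped", "itself_and_mate_mapped"),
    ("properly paired", "properly_paired"),
    ("paired in sequencing", "paired_in_sequencing"),
    ("singletons", "singletons"),
    ("in total", "total"),
    ("read1", "read1"),
    ("read2", "read2"),
    ("mapped", "mapped"),
]

FLAGSTAT_TSV_HEADER = ("label",) + FLAGSTAT_FIELDS


def read_flagstat(path, label: str | None = None) -> FlagstatProfile:
    """Parse a ``samtools flagstat`` text file or a one-row 10-counter TSV."""
    path = Path(path)
    text = path.read_text()
    first = text.splitlines()[0] if text.strip() else ""
    if first.lower().startswith("label\t") or first.lower().startswith("age\t"):
        profiles = read_flagstat_tsv(path)
        if len(profiles) != 1:
            raise ValidationError(
                f"{path}: expected a single profile row, got {len(profiles)}")
        return profiles[0]
    values: dict[str, int] = {}
    for line in text.splitlines():
        low = line.lower()
        parts = line.split()
        if not parts or not parts[0].isdigit():
            continue
        count = int(parts[0])
        for phrase, fieldname in _FLAGSTAT_PHRASES:
            if phrase in low and fieldname not in values:
                # newer samtools prints "primary mapped" too; take the
                # plain "mapped" line only
                if fieldname == "mapped" and ("mate mapped" in low
                                              or "primary" in low):
                    continue
                values[fieldname] = count
                break
    missing = [f for f in FLAGSTAT_FIELDS if f not in values]
    if missing:
        raise ValidationError(f"{path}: missing flagstat counter(s): "
                              + ", ".join(missing))
    return FlagstatProfile(label=label or path.stem, **values)


def read_flagstat_tsv(path) -> list[FlagstatProfile]:
    path = Path(path)
    profiles = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 11:
            raise ValidationError(
                f"{path}: expected 11 columns (label + 10 counters), "
                f"got {len(header)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise ValidationError(
                    f"{path}:{lineno}: expected 11 columns, got {len(fields)}")
            try:
                counters = [int(x) for x in fields[1:]]
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer counter ({exc})") from exc
            try:
                profiles.append(FlagstatProfile(
                    fields[0], **dict(zip(FLAGSTAT_FIELDS, counters))))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return profiles


def write_flagstat_tsv(profiles: Sequence[FlagstatProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FLAGSTAT_TSV_HEADER) + "\n")
        for p in profiles:
            fh.write(p.label + "\t"
                     + "\t".join(str(c) for c in p.counters()) + "\n")


# ---------------------------------------------------------------------------
# gene loci
# ---------------------------------------------------------------------------

def read_gene_loci(path, dialect: str) -> list[GeneLocus]:
    """Read QTL/candidate-gene intervals.

    dialect 'bed': BED4, 0-based half-open, converted to 1-based
    inclusive.  dialect 'tsv': ``symbol chrom start end`` already 1-based
    inclusive (header optional).  The dialect is declared, never guessed.
    Duplicate symbols are rejected; an unrecognised chromosome label
    triggers a warning but the locus is retained.
    """
    path = Path(path)
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 4:
                    raise ValidationError(
                        f"{path}:{lineno}: BED4 needs 4 columns")
                chrom, start_s, end_s, symbol = fields[:4]
                start, end = int(start_s) + 1, int(end_s)
            elif dialect == "tsv":
                if lineno == 1 and fields[0].lower() == "symbol":
                    continue
                if len(fields) < 4:
                    raise ValidationError(
                        f"{path}:{lineno}: TSV needs symbol chrom start end")
                symbol, chrom, start_s, end_s = fields[:4]
                start, end = int(start_s), int(end_s)
            else:
                raise ValueError(f"unknown locus dialect {dialect!r}")
            if symbol in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate locus symbol {symbol!r}")
            seen.add(symbol)
            if normalize_chrom(chrom) not in _KNOWN_CHROMS:
                warnings.warn(f"{path}:{lineno}: unrecognised chromosome "
                              f"label {chrom!r}; locus retained")
            try:
                loci.append(GeneLocus(symbol=symbol, chrom=chrom,
                                      start=start, end=end))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return loci


def write_gene_loci(loci: Sequence[GeneLocus], path, dialect: str) -> None:
    with open(path, "w") as fh:
        if dialect == "bed":
            for l in loci:
                fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\t{l.symbol}\n")
        elif dialect == "tsv":
            fh.write("symbol\tchrom\tstart\tend\n")
            for l in loci:
                fh.write(f"{l.symbol}\t{l.chrom}\t{l.start}\t{l.end}\n")
        else:
            raise ValueError(f"unknown locus dialect {dialect!r}")


# ---------------------------------------------------------------------------
# SnpDb TSV
# ---------------------------------------------------------------------------

SNPDB_TSV_HEADER = ("chrom", "pos", "ref", "alt", "total_depth", "alt_depth",
                    "sample_id", "breed", "age_months", "replicate")


def write_snpdb_tsv(db: SnpDb, path) -> None:
    """Evidence-level TSV with provenance header lines (# prefixed)."""
    with open(path, "w") as fh:
        fh.write(f"#breed={db.breed or ''}\n")
        for op, params in db.provenance:
            fh.write(f"#provenance={op} {json.dumps(params, sort_keys=True)}\n")
        fh.write("\t".join(SNPDB_TSV_HEADER) + "\n")
        for key in sorted(db.records):
            for r in db.records[key]:
                s = r.sample
                fh.write(f"{r.chrom}\t{r.pos}\t{r.ref_base}\t{r.alt_allele}"
                         f"\t{r.total_depth}\t{r.alt_depth}\t{s.sample_id}"
                         f"\t{s.breed.value}\t{s.age_months}\t{s.replicate}\n")


def read_snpdb_tsv(path) -> SnpDb:
    path = Path(path)
    db = SnpDb()
    samples: dict[str, SampleMeta] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#breed="):
                db.breed = line.split("=", 1)[1] or None
                continue
            if line.startswith("#provenance="):
                body = line.split("=", 1)[1]
                op, _, params = body.partition(" ")
                db.provenance.append((op, json.loads(params or "{}")))
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":
                continue
            if len(fields) != 10:
                raise ValidationError(
                    f"{path}:{lineno}: expected 10 columns, got {len(fields)}")
            sid = fields[6]
            if sid not in samples:
                samples[sid] = SampleMeta(
                    sample_id=sid, breed=Breed(fields[7]),
                    age_months=int(fields[8]), replicate=int(fields[9]))
            db.add(VariantRecord(
                chrom=fields[0], pos=int(fields[1]), ref_base=fields[2],
                alt_allele=fields[3], total_depth=int(fields[4]),
                alt_depth=int(fields[5]), sample=samples[sid]))
    return db


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

#: Two-digit Genepop allele codes: reference allele = 01, alternate = 02.
_GENEPOP_CODES = {"RR": "0101", "RA": "0102", "AA": "0202",
                  MISSING_GENOTYPE: "0000"}


def write_genepop(tables: Sequence[GenotypeTable], path,
                  title: str = "bovisnp validation markers") -> None:
    """Genepop 4 input: title line, one locus name per line, then one
    'Pop' block per breed with two-digit allele codes (0000 = missing)."""
    if not tables:
        raise ValueError("no genotype tables to export")
    breeds: list[Breed] = []
    animals: dict[Breed, list[str]] = {}
    for t in tables:
        for animal, breed, _ in t.calls:
            if breed not in breeds:
                breeds.append(breed)
                animals[breed] = []
            if animal not in animals[breed]:
                animals[breed].append(animal)
    lookup = {t.marker_id: {(a, b): g for a, b, g in t.calls}
              for t in tables}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for t in tables:
            fh.write(t.marker_id + "\n")
        for breed in breeds:
            fh.write("Pop\n")
            for animal in animals[breed]:
                codes = [
                    _GENEPOP_CODES[lookup[t.marker_id].get(
                        (animal, breed), MISSING_GENOTYPE)]
                    for t in tables]
                fh.write(f"{animal} ,  " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# genotype CSV
# ---------------------------------------------------------------------------

def read_genotype_csv(path) -> list[GenotypeTable]:
    """CSV columns: animal_id, breed, marker, genotype (RR/RA/AA/--),
    plus optional allele_ref/allele_alt columns."""
    import csv

    path = Path(path)
    tables: dict[str, GenotypeTable] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                marker = row["marker"]
                if marker not in tables:
                    tables[marker] = GenotypeTable(
                        marker_id=marker,
                        allele_ref=row.get("allele_ref", "R") or "R",
                        allele_alt=row.get("allele_alt", "A") or "A")
                tables[marker].calls.append(
                    (row["animal_id"], Breed(row["breed"]), row["genotype"]))
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    for t in tables.values():
        GenotypeTable.__post_init__(t)
    return list(tables.values())


def write_genotype_csv(tables: Sequence[GenotypeTable], path) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id,breed,marker,genotype,allele_ref,allele_alt\n")
        for t in tables:
            for animal, breed, g in t.calls:
                fh.write(f"{animal},{breed.value},{t.marker_id},{g},"
                         f"{t.allele_ref},{t.allele_alt}\n")


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def write_outputs(obj: Union[SnpDb, GenotypeTable, Sequence[GenotypeTable], dict],
                  path, format: str) -> None:
    """Write ``obj`` in ``format``; unsupported (object, format) pairs fail
    before any file is created."""
    if isinstance(obj, SnpDb):
        if format == "tsv":
            return write_snpdb_tsv(obj, path)
        if format == "vcf":
            recs = [r for k in sorted(obj.records) for r in obj.records[k]]
            return write_variant_calls(recs, path, dialect="vcf")
        if format == "json":
            summary = {"breed": obj.breed, "n_records": len(obj),
                       "provenance": [[op, p] for op, p in obj.provenance]}
            return Path(path).write_text(json.dumps(summary, indent=2) + "\n")
    elif isinstance(obj, GenotypeTable):
        if format == "genepop":
            return write_genepop([obj], path)
        if format == "tsv":
            return write_genotype_csv([obj], path)
    elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], GenotypeTable):
        if format == "genepop":
            return write_genepop(list(obj), path)
        if format == "tsv":
            return write_genotype_csv(list(obj), path)
    elif isinstance(obj, dict):
        if format == "json":
            return Path(path).write_text(json.dumps(obj, indent=2,
                                                    sort_keys=True) + "\n")
    raise ValueError(
        f"unsupported (object, format) pair: ({type(obj).__name__}, {format})")
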