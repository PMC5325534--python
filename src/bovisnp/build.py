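"""Construction of breed-specific SNP databases and raw-count accounting.

Per-sample call lists are combined into one database per breed, keyed by
(chromosome, position, alternate allele) with per-sample evidence kept.
Positions at which the combined breed data carry more than one distinct
alternate allele are treated as error records and removed wholesale.
A raw-count summary mirrors the per-sample indel/SNP/total accounting of
the study design: per-sample counts, per-breed subtotals, grand totals,
breed percentage shares (one decimal, half-up) and the floor-divided
average per animal.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    Breed,
    SampleMeta,
    SnpDb,
    ValidationError,
    VariantClass,
    VariantRecord,
)


def build_breed_snpdb(records: Iterable[VariantRecord],
                      breed: Breed) -> SnpDb:
    """Combine one breed's per-sample SNP calls into a keyed database.

    Indel-class records are excluded here (they are accounted for by
    :func:`summarize_counts`); a record from a different breed is an
    error, not a silent skip.
    """
    db = SnpDb(breed=breed.value)
    n = 0
    for rec in records:
        if rec.sample.breed != breed:
            raise ValidationError(
                f"record from breed {rec.sample.breed.value} passed to "
                f"{breed.value} database")
        if rec.variant_class is VariantClass.SNP:
            db.add(rec)
            n += 1
    db.stamp("build_breed_snpdb", breed=breed.value, n_records=n)
    return db


def remove_error_records(db: SnpDb) -> tuple[SnpDb, int]:
    """Drop every position carrying more than one distinct alternate
    allele; returns the cleaned database and the number of removed keys.

    Idempotent: a second application removes nothing.
    """
    multi = {pos for pos, alts in db.positions().items() if len(alts) > 1}
    keep = [k for k in db.records if (k[0], k[1]) not in multi]
    removed = len(db) - len(keep)
    out = db.subset(keep)
    out.stamp("remove_error_records", removed=removed)
    return out, removed


def classify_sample_counts(records: Iterable[VariantRecord]) -> dict[str, int]:
    """Indel / SNP / combined counts for one sample's raw calls."""
    n_indel = n_snp = 0
    for r in records:
        if r.variant_class is VariantClass.INDEL:
            n_indel += 1
        else:
            n_snp += 1
    return {"only_indels": n_indel, "only_snps": n_snp,
            "snps_and_indels": n_indel + n_snp}


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_counts(per_sample: Mapping[SampleMeta, Sequence[VariantRecord]]
                     ) -> dict:
    """Raw-database accounting across a panel.

    Returns per-sample rows, per-breed subtotals, grand totals, breed
    percentage shares of the combined total (one decimal, half-up) and
    the average per animal (grand total floor-divided by sample count).
    """
    if not per_sample:
        raise ValidationError("summarize_counts needs at least one sample")
    rows = []
    for sample, records in per_sample.items():
        counts = classify_sample_counts(records)
        rows.append({"sample_id": sample.sample_id,
                     "breed": sample.breed.value,
                     "age_months": sample.age_months,
                     "replicate": sample.replicate, **counts})
    df = pd.DataFrame(rows)
    count_cols = ["only_indels", "only_snps", "snps_and_indels"]
    subtotals = df.groupby("breed")[count_cols].sum()
    grand = df[count_cols].sum()
    grand_total = int(grand["snps_and_indels"])
    shares = {
        breed: round_half_up(100 * sub / grand_total, 1) if grand_total else 0.0
        for breed, sub in subtotals["snps_and_indels"].items()
    }
    return {
        "per_sample": df,
        "breed_subtotals": subtotals,
        "grand_totals": {c: int(grand[c]) for c in count_cols},
        "breed_shares_pct": shares,
        "average_per_bull": grand_total // len(per_sample),
    }


def summarize_counts_from_table(table: pd.DataFrame) -> dict:
    """Same accounting starting from an already-counted table with columns
    breed, only_indels, only_snps, snps_and_indels (one row per sample),
    for use when only printed per-sample counts are available."""
    count_cols = ["only_indels", "only_snps", "snps_and_indels"]
    subtotals = table.groupby("breed")[count_cols].sum()
    grand = table[count_cols].sum()
    grand_total = int(grand["snps_and_indels"])
    shares = {
        breed: round_half_up(100 * sub / grand_total, 1) if grand_total else 0.0
        for breed, sub in subtotals["snps_and_indels"].items()
    }
    return {
        "breed_subtotals": subtotals,
        "grand_totals": {c: int(grand[c]) for c in count_cols},
        "breed_shares_pct": shares,
        "average_per_bull": grand_total // len(table),
    }
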