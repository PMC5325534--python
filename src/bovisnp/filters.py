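"""Stringent SNP filters: depth, exact SNP ratio, replicate concordance,
and detection of variants in unassembled (ref = 'N') regions.

The depth threshold applies to the reads supporting the alternate allele
(not the total depth); a "100% SNP ratio" means every covering read
carries the alternate, tested on integers as ``alt_depth ==
total_depth``.  A database key survives a filter if ANY of its evidence
records passes (``evidence_mode='any'``); requiring every record to pass
is available as ``evidence_mode='all'``.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Optional, Union

from .model import (
    Breed,
    SnpDb,
    ValidationError,
    VariantRecord,
)

Ratio = Union[float, Fraction, None]


def _ratio_fraction(ratio: Ratio) -> Optional[Fraction]:
    if ratio is None:
        return None
    frac = Fraction(ratio) if isinstance(ratio, Fraction) else Fraction(ratio).limit_denominator(10**6)
    if not 0 <= frac <= 1:
        raise ValidationError(f"ratio must lie in [0, 1], got {ratio}")
    return frac


def record_passes(rec: VariantRecord, min_depth: int,
                  ratio: Optional[Fraction]) -> bool:
    if rec.alt_depth < min_depth:
        return False
    if ratio is not None and Fraction(rec.alt_depth, rec.total_depth) != ratio:
        return False
    return True


def filter_records(db: SnpDb, min_depth: int = 0,
                   exact_ratio: Ratio = None,
                   evidence_mode: str = "any") -> SnpDb:
    """Keep keys whose evidence passes the (depth, exact-ratio) criteria.

    ``exact_ratio=None`` disables the ratio constraint; otherwise the SNP
    ratio must equal it exactly (compared as a rational, so 1.0 means all
    covering reads support the alternate).  Idempotent and monotone:
    output keys are a subset of input keys, and tightening ``min_depth``
    never adds keys.
    """
    if min_depth < 0:
        raise ValidationError(f"min_depth must be >= 0, got {min_depth}")
    ratio = _ratio_fraction(exact_ratio)
    if evidence_mode not in ("any", "all"):
        raise ValueError(f"evidence_mode must be 'any' or 'all', got {evidence_mode!r}")
    chooser = any if evidence_mode == "any" else all
    keep = [k for k, recs in db.records.items()
            if chooser(record_passes(r, min_depth, ratio) for r in recs)]
    out = db.subset(keep)
    out.stamp("filter_records", min_depth=min_depth,
              exact_ratio=None if ratio is None else [ratio.numerator,
                                                      ratio.denominator],
              evidence_mode=evidence_mode)
    return out


def replicate_concordant_set(records: Iterable[VariantRecord],
                             breed: Breed,
                             min_depth: int = 5) -> SnpDb:
    """Keys supported in BOTH biological replicates of at least one age
    cell of ``breed``, each with alternate depth >= ``min_depth``.

    Every (breed, age) cell present must contain exactly the two
    replicates of the design.
    """
    by_cell: dict[int, dict[int, dict]] = {}
    for rec in records:
        if rec.sample.breed != breed:
            continue
        reps = by_cell.setdefault(rec.sample.age_months, {})
        reps.setdefault(rec.sample.replicate, {}).setdefault(
            rec.key, []).append(rec)
    out = SnpDb(breed=breed.value)
    for age, reps in sorted(by_cell.items()):
        if set(reps) != {1, 2}:
            raise ValidationError(
                f"{breed.value} {age}m: need exactly replicates {{1, 2}}, "
                f"got {sorted(reps)}")
        for key in reps[1].keys() & reps[2].keys():
            ok = all(
                any(r.alt_depth >= min_depth for r in reps[rep][key])
                for rep in (1, 2))
            if ok:
                for rep in (1, 2):
                    for r in reps[rep][key]:
                        out.add(r)
    out.stamp("replicate_concordant_set", breed=breed.value,
              min_depth=min_depth)
    return out


def detect_de_novo(records: Iterable[VariantRecord],
                   min_depth: int = 10,
                   exact_ratio: Ratio = 1.0) -> SnpDb:
    """Confidently supported variants whose reference base is 'N'
    (unassembled reference sequence), i.e. candidate novel sites.

    Disjoint by construction from any database built over known-reference
    records.
    """
    ratio = _ratio_fraction(exact_ratio)
    out = SnpDb(breed="de_novo")
    for rec in records:
        if rec.ref_base == "N" and record_passes(rec, min_depth, ratio):
            out.add(rec)
    out.stamp("detect_de_novo", min_depth=min_depth,
              exact_ratio=None if ratio is None else [ratio.numerator,
                                                      ratio.denominator])
    return out
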