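"""Intersection of SNP databases with QTL/candidate-gene intervals and
classification of loci as monomorphic or highly polymorphic.

A SNP hits a locus when its position falls inside the locus interval
(1-based inclusive on both ends, same chromosome); overlapping loci each
count the SNP.  A locus with hits is *monomorphic* when its evidence
shows a fixed alternate: every hit position carries a single alternate
allele breed-wide and every supporting record has a 100% SNP ratio (no
heterozygous evidence) — the signature of genotype fixation.  The
alternative reading, exactly one hit position, is available as
``mono_def='single-hit'``.  Polymorphic loci are ranked by distinct hit
positions (descending, ties by symbol) and the top-k are flagged highly
polymorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .model import GeneLocus, SnpDb, ValidationError


@dataclass(frozen=True)
class LocusHitSummary:
    symbol: str
    breed: Optional[str]
    hit_positions: frozenset          # of (chrom, pos)
    status: str = "no_hit"            # no_hit | monomorphic | polymorphic
    rank: Optional[int] = None        # rank among polymorphic loci
    highly_polymorphic: bool = False

    @property
    def hit_count(self) -> int:
        return len(self.hit_positions)


def locus_hits(db: SnpDb, loci: Sequence[GeneLocus]) -> list[LocusHitSummary]:
    """Count distinct SNP positions inside each locus interval.

    Every locus gets a summary, hit or not.  Backed by an interval tree
    per chromosome; inclusive bounds on both ends.
    """
    if not loci:
        raise ValidationError("locus_hits needs a non-empty locus list")
    trees: dict[str, IntervalTree] = {}
    for i, locus in enumerate(loci):
        # +1: IntervalTree is half-open, our loci are inclusive
        trees.setdefault(locus.chrom_norm, IntervalTree()).addi(
            locus.start, locus.end + 1, i)
    hits: dict[int, set] = {i: set() for i in range(len(loci))}
    for (chrom, pos, _alt) in db.records:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(pos):
            hits[iv.data].add((chrom, pos))
    return [
        LocusHitSummary(symbol=locus.symbol, breed=db.breed,
                        hit_positions=frozenset(hits[i]),
                        status="no_hit" if not hits[i] else "polymorphic")
        for i, locus in enumerate(loci)
    ]


def classify_locus_polymorphism(summaries: Sequence[LocusHitSummary],
                                db: SnpDb, top_k: int = 10,
                                mono_def: str = "fixed"
                                ) -> list[LocusHitSummary]:
    """Assign monomorphic/polymorphic status, rank polymorphic loci and
    flag the top-k as highly polymorphic."""
    if top_k < 1:
        raise ValidationError(f"top_k must be >= 1, got {top_k}")
    if mono_def not in ("fixed", "single-hit"):
        raise ValueError(f"mono_def must be 'fixed' or 'single-hit', got {mono_def!r}")
    by_position = db.positions()
    records = db.records

    def is_monomorphic(s: LocusHitSummary) -> bool:
        if s.hit_count == 0:
            return False
        if mono_def == "single-hit":
            return s.hit_count == 1
        for pos in s.hit_positions:
            alts = by_position.get(pos, set())
            if len(alts) != 1:
                return False
            (alt,) = alts
            if not all(r.is_full_ratio for r in records[(*pos, alt)]):
                return False
        return True

    classified = []
    for s in summaries:
        if s.hit_count == 0:
            classified.append(replace(s, status="no_hit", rank=None,
                                      highly_polymorphic=False))
        elif is_monomorphic(s):
            classified.append(replace(s, status="monomorphic", rank=None,
                                      highly_polymorphic=False))
        else:
            classified.append(replace(s, status="polymorphic"))
    poly = sorted((s for s in classified if s.status == "polymorphic"),
                  key=lambda s: (-s.hit_count, s.symbol))
    ranks = {s.symbol: i + 1 for i, s in enumerate(poly)}
    return [
        replace(s, rank=ranks[s.symbol],
                highly_polymorphic=ranks[s.symbol] <= top_k)
        if s.status == "polymorphic" else s
        for s in classified
    ]


def cross_breed_concordance(per_breed: dict[str, Sequence[LocusHitSummary]]
                            ) -> dict[str, list[str]]:
    """Group locus symbols by how many breeds call them monomorphic."""
    mono: dict[str, set[str]] = {}
    for breed, summaries in per_breed.items():
        for s in summaries:
            if s.status == "monomorphic":
                mono.setdefault(s.symbol, set()).add(breed)
    out = {"all_breeds": [], "two_breeds": [], "one_breed": []}
    for symbol, breeds in sorted(mono.items()):
        if len(breeds) >= 3:
            out["all_breeds"].append(symbol)
        elif len(breeds) == 2:
            out["two_breeds"].append(symbol)
        else:
            out["one_breed"].append(symbol)
    return out
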