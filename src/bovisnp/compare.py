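"""Set algebra among breed SNP databases.

Two breeds share a SNP only when the full key — chromosome, position AND
alternate allele — matches; a coincident position with a different
mutation is not shared.  The three-way Venn decomposition partitions the
union of the three key sets into seven regions; the pairwise and
two-versus-one unique sets reproduce the breed-comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import SnpDb, SnpKey, ValidationError


@dataclass(frozen=True)
class VennRegion:
    label: str            # e.g. "PolishRed" or "PolishRed&Hereford"
    members: frozenset    # breed labels whose sets contain these keys
    keys: frozenset
    count: int


def venn_regions(dbs: Sequence[SnpDb]) -> dict[str, VennRegion]:
    """Decompose three breed key sets into the 7 exclusive Venn regions.

    Region labels join the member breed names with '&'; the regions
    partition the union, so counts sum to |A or B or C|.
    """
    if len(dbs) != 3:
        raise ValidationError(f"venn_regions needs exactly 3 databases, got {len(dbs)}")
    names = [db.breed or f"set{i}" for i, db in enumerate(dbs)]
    if len(set(names)) != 3:
        raise ValidationError(f"duplicate breed labels: {names}")
    sets = {name: db.key_set() for name, db in zip(names, dbs)}
    universe = set().union(*sets.values())
    regions: dict[frozenset, set] = {}
    for key in universe:
        members = frozenset(n for n in names if key in sets[n])
        regions.setdefault(members, set()).add(key)
    out: dict[str, VennRegion] = {}
    for r in range(1, 4):
        for members in _combos(names, r):
            label = "&".join(members)
            keys = frozenset(regions.get(frozenset(members), set()))
            out[label] = VennRegion(label=label, members=frozenset(members),
                                    keys=keys, count=len(keys))
    return out


def _combos(names: list[str], r: int):
    from itertools import combinations
    return combinations(names, r)


def breed_unique_sets(focus: SnpDb, others: Sequence[SnpDb]) -> SnpDb:
    """Keys of ``focus`` absent from every database in ``others``.

    With two others this yields the "present in neither" unique set.
    """
    if not 1 <= len(others) <= 2:
        raise ValidationError("others must contain 1 or 2 databases")
    labels = {db.breed for db in others}
    if focus.breed in labels:
        raise ValidationError(
            f"focus breed {focus.breed!r} also appears among others")
    if len(labels) != len(others):
        raise ValidationError("duplicate breed labels among others")
    excluded: set[SnpKey] = set().union(*(db.key_set() for db in others))
    unique = [k for k in focus.records if k not in excluded]
    out = focus.subset(unique)
    out.stamp("breed_unique_sets", focus=focus.breed,
              others=sorted(str(b) for b in labels))
    return out
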