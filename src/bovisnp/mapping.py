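"""Aggregation of mapping summaries and alignment percentages.

Per-age flagstat profiles are pooled (per breed or globally) by summing
all ten counters, and two headline percentages are derived:

* properly-paired percentage = properly_paired / mapped x 100
* overall alignment percentage = mapped / total x 100

Both are truncated — not rounded — to two decimals, which is the
convention the source tables follow.  Truncation is done on integers
(``count * 10000 // denominator``) so no floating-point step can flip the
last digit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .model import FLAGSTAT_FIELDS, FlagstatProfile, ValidationError


def truncate_pct(numerator: int, denominator: int) -> float:
    """numerator/denominator as a percentage truncated to 2 decimals."""
    if denominator == 0:
        warnings.warn("zero denominator in percentage; reporting 0.00")
        return 0.0
    return (numerator * 10000 // denominator) / 100


@dataclass(frozen=True)
class MappingSummary:
    label: str
    totals: dict
    properly_paired_pct: float
    overall_alignment_pct: float


def aggregate_and_percentages(profiles: Sequence[FlagstatProfile],
                              grouping: str = "global",
                              label: str | None = None):
    """Pool profiles and compute the two alignment percentages.

    grouping='global' pools everything into one :class:`MappingSummary`;
    grouping='breed' groups profiles by the leading token of their label
    (e.g. ``PolishRed_6m``) and returns a dict of summaries.
    """
    if not profiles:
        raise ValidationError("aggregate_and_percentages needs >= 1 profile")
    if grouping == "breed":
        groups: dict[str, list[FlagstatProfile]] = {}
        for p in profiles:
            groups.setdefault(p.label.split("_")[0], []).append(p)
        return {name: _summarize(ps, name) for name, ps in groups.items()}
    if grouping == "global":
        return _summarize(list(profiles), label or "all")
    raise ValueError(f"unknown grouping {grouping!r}")


def _summarize(profiles: list[FlagstatProfile], label: str) -> MappingSummary:
    totals = {f: sum(getattr(p, f) for p in profiles) for f in FLAGSTAT_FIELDS}
    return MappingSummary(
        label=label,
        totals=totals,
        properly_paired_pct=truncate_pct(totals["properly_paired"],
                                         totals["mapped"]),
        overall_alignment_pct=truncate_pct(totals["mapped"], totals["total"]),
    )
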