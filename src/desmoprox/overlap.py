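"""Set-algebra summaries of the proximitome: bait uniqueness/sharing, Venn
cells (plakoglobin termini merged into one bait), per-condition totals, the
two-termini agreement, and overlap with external proximitome gene lists."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .maturation import PG_TERMINI, ProfileSet, dataset_label


@dataclass
class OverlapSummary:
    total: int
    per_bait: dict  # merged-bait -> prey count
    unique: int  # preys significant for exactly one merged bait
    shared: int  # preys significant for >= 2 merged baits
    per_condition: dict  # condition -> enriched prey count
    venn: dict  # exclusive Venn cells keyed by "&"-joined sorted bait tuple

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "per_bait": self.per_bait,
            "unique": self.unique,
            "shared": self.shared,
            "per_condition": self.per_condition,
            "venn": self.venn,
        }


def bait_overlap_stats(
    profiles: ProfileSet, calls: pd.DataFrame | None = None
) -> OverlapSummary:
    """Exact set algebra over the per-bait prey sets (PG termini merged).

    ``calls`` (maturation calls) is accepted for interface symmetry and, when
    provided, is checked for consistency with the profiles.
    """
    merged = profiles.merged_baits()
    bait_sets = {b: profiles.bait_preys(b) for b in merged}
    all_preys = set(profiles.preys)
    if calls is not None and set(calls["prey"]) != all_preys:
        raise InputError("maturation calls and profiles cover different preys")

    membership: dict = {}
    for prey in all_preys:
        key = tuple(sorted(b for b in merged if prey in bait_sets[b]))
        membership.setdefault(key, set()).add(prey)
    venn = {"&".join(key): len(preys) for key, preys in sorted(membership.items())}
    unique = sum(len(v) for k, v in membership.items() if len(k) == 1)
    shared = sum(len(v) for k, v in membership.items() if len(k) >= 2)
    per_condition = {
        c: len(profiles.significant_in_condition(c)) for c in profiles.conditions
    }
    return OverlapSummary(
        total=len(all_preys),
        per_bait={b: len(s) for b, s in bait_sets.items()},
        unique=unique,
        shared=shared,
        per_condition=per_condition,
        venn=venn,
    )


def pg_termini_overlap(profiles: ProfileSet) -> tuple[int, int]:
    """(n_union, n_both): preys significant for either plakoglobin terminus in
    any condition, and for both termini (each in any condition)."""
    term_sets = []
    for bait in PG_TERMINI:
        cols = [dataset_label(bait, c) for c in profiles.conditions]
        mask = profiles.binary[cols].sum(axis=1) > 0
        term_sets.append(set(profiles.binary.index[mask]))
    a, b = term_sets
    return len(a | b), len(a & b)


@dataclass
class ExternalOverlap:
    name: str
    count: int
    fraction: float  # denominator = this study's prey set
    members: list = field(default_factory=list)


def compare_external(
    preys, external, name: str = "external", by_bait_preys=None
) -> ExternalOverlap:
    """Overlap of the prey set with an external proximitome gene list.

    ``by_bait_preys`` optionally restricts the comparison to one bait's prey
    set.  Fractions use this study's (possibly restricted) prey set as the
    denominator.
    """
    external = set(external)
    if not external:
        raise InputError("external gene list is empty")
    preys = set(preys) if by_bait_preys is None else set(by_bait_preys)
    if not preys:
        raise InputError("prey set is empty")
    members = sorted(preys & external)
    return ExternalOverlap(
        name=name,
        count=len(members),
        fraction=len(members) / len(preys),
        members=members,
    )


def read_symbol_list(path) -> list:
    """One symbol per line; blank lines and '#' comments ignored."""
    with open(path) as handle:
        return [
            line.strip()
            for line in handle
            if line.strip() and not line.startswith("#")
        ]
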