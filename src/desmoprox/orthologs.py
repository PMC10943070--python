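"""Canine-to-human ortholog mapping and protein-group expansion.

The study system is a canine epithelial cell line, so quantified protein IDs
are mapped to human gene symbols (from a user-supplied two-column table)
before annotation-based analyses.  A handful of hits are protein groups whose
members cannot be distinguished by MS; for counting distinct preys the group
label is the identity, while network and enrichment inputs use the expanded
members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import MappingError

logger = logging.getLogger(__name__)

#: indistinguishable protein groups shipped as defaults ("/"-joined labels)
DEFAULT_PROTEIN_GROUPS = (
    "HLA-F/HLA-A/HLA-B/HLA-C",
    "RAB11A/RAB11B",
    "ANP32D/ANP32A",
    "TUBB2B/TUBB2A",
    "HSPA1B/HSPA1A",
    "DYNLRB2/MAP1LC3A",
    "DNAJB7/DNAJB6",
)


@dataclass(frozen=True)
class ProteinGroup:
    """A set of gene symbols indistinguishable at the protein level."""

    members: tuple

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise MappingError(f"protein group needs >= 2 members: {self.members}")

    @property
    def label(self) -> str:
        return "/".join(self.members)


@dataclass
class OrthologTable:
    """source ID -> human gene symbol lookup."""

    mapping: dict

    def __post_init__(self) -> None:
        bad = [k for k, v in self.mapping.items() if not str(v).strip()]
        if bad:
            raise MappingError(f"empty symbols for source IDs: {bad}")

    @classmethod
    def from_tsv(cls, path) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["source", "symbol"], dtype=str)
        if df["source"].duplicated().any():
            dupes = df.loc[df["source"].duplicated(), "source"].tolist()
            raise MappingError(f"duplicate source IDs in ortholog table: {dupes}")
        return cls(dict(zip(df["source"], df["symbol"])))


@dataclass
class MappingReport:
    unmapped: list
    collapsed: dict  # symbol -> list of source IDs that collapsed onto it


def map_orthologs(prey_ids, table: OrthologTable) -> tuple[list, MappingReport]:
    """Replace source IDs by ortholog symbols, order-preserving.

    Unmapped IDs are kept verbatim (counts are conserved) and reported;
    distinct sources mapping to the same symbol collapse to one occurrence
    with a warning.
    """
    if not table.mapping:
        raise MappingError("ortholog table is empty")
    mapped: list = []
    seen: dict = {}
    unmapped: list = []
    collapsed: dict = {}
    for pid in prey_ids:
        symbol = table.mapping.get(pid)
        if symbol is None:
            unmapped.append(pid)
            symbol = pid
        if symbol in seen:
            collapsed.setdefault(symbol, [seen[symbol]]).append(pid)
            logger.warning("map_orthologs: %r collapses onto %r", pid, symbol)
            continue
        seen[symbol] = pid
        mapped.append(symbol)
    return mapped, MappingReport(unmapped=unmapped, collapsed=collapsed)


def parse_groups(lines) -> list[ProteinGroup]:
    """Parse one "/"-joined label per line into protein groups."""
    groups = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        members = tuple(s for s in line.split("/") if s)
        groups.append(ProteinGroup(members))
    return groups


def default_groups() -> list[ProteinGroup]:
    return parse_groups(DEFAULT_PROTEIN_GROUPS)


def expand_protein_groups(symbols, groups) -> tuple[list, dict]:
    """Expand group labels into their members for network/enrichment inputs.

    Returns (expanded symbol list, origin map: expanded symbol -> source
    symbol).  The origin map lets distinct-prey counts be recovered on group
    labels after expansion.
    """
    by_label = {g.label: g for g in groups}
    expanded: list = []
    origin: dict = {}
    for symbol in symbols:
        group = by_label.get(symbol)
        if group is None:
            expanded.append(symbol)
            origin[symbol] = symbol
        else:
            for member in group.members:
                expanded.append(member)
                origin[member] = group.label
    return expanded, origin
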