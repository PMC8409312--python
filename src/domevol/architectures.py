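"""Partition KO groups into domain-architecture items.

A domain architecture (DA) is here the unordered set of unique-putative
family names of a protein.  Within one KO, proteins with identical DAs
form an *item*; the item carries matched organism and protein lists
(index-aligned, with repeated organisms encoding paralogs).  Comparing
each item's DA with the other items of the same KO yields its gained and
missing domain patterns — the raw material for event calling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .datastore import KoMembers
from .errors import ContractError


@dataclass(frozen=True)
class ArchitectureItem:
    """One distinct DA within a KO with its matched member lists."""

    ko_number: str
    item_index: int
    domain_set: frozenset[str]
    org_ids: tuple[str, ...]
    refseq_ids: tuple[str, ...]
    gained: frozenset[str] = frozenset()
    missing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.org_ids) != len(self.refseq_ids):
            raise ContractError("org_ids and refseq_ids must be matched lists")
        if len(self.refseq_ids) < 1:
            raise ContractError("an item needs at least one member")


def partition_ko(members: KoMembers) -> list[ArchitectureItem]:
    """Group a KO's proteins by identical domain sets.

    Item indices start at 1 and are assigned by descending member count,
    ties broken by the lexicographically smallest (sorted) domain list.
    Gain/loss patterns are filled by :func:`gain_loss_patterns`.
    """
    if len(members) == 0:
        raise ContractError(f"KO {members.ko_number} has no members")
    groups: dict[frozenset[str], list[int]] = {}
    for i, dset in enumerate(members.unique_putative):
        groups.setdefault(dset, []).append(i)

    def order_key(dset: frozenset[str]) -> tuple:
        return (-len(groups[dset]), tuple(sorted(dset)))

    items: list[ArchitectureItem] = []
    for index, dset in enumerate(sorted(groups, key=order_key), start=1):
        rows = groups[dset]
        items.append(
            ArchitectureItem(
                ko_number=members.ko_number,
                item_index=index,
                domain_set=dset,
                org_ids=tuple(members.org_ids[i] for i in rows),
                refseq_ids=tuple(members.refseq_ids[i] for i in rows),
            )
        )
    return gain_loss_patterns(items)


def gain_loss_patterns(items: list[ArchitectureItem]) -> list[ArchitectureItem]:
    """Fill each item's gained / missing sets relative to its KO siblings.

    For item *i*: ``missing`` is every domain present in some other item
    but not here; ``gained`` is every domain present here but absent from
    at least one other item.  With a single item both sets are empty —
    two items is the minimum for any non-empty pattern.
    """
    sets = [it.domain_set for it in items]
    if len(set(sets)) != len(sets):
        raise ContractError("domain sets must be pairwise distinct within a KO")
    if len(items) < 2:
        return [replace(it, gained=frozenset(), missing=frozenset()) for it in items]
    universe = frozenset().union(*sets)
    out = []
    for i, item in enumerate(items):
        others = [s for j, s in enumerate(sets) if j != i]
        missing = universe - item.domain_set
        gained = frozenset(
            d for d in item.domain_set if any(d not in s for s in others)
        )
        out.append(replace(item, gained=gained, missing=missing))
    return out


def write_items_tsv(items: list[ArchitectureItem], path) -> None:
    """Export items: ko, item, domains, matched lists, gain/loss patterns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ko_number\titem\tdomain_set\torg_ids\trefseq_ids\tgained\tmissing\n")
        for it in items:
            fh.write(
                "\t".join(
                    [
                        it.ko_number,
                        str(it.item_index),
                        ",".join(sorted(it.domain_set)),
                        ",".join(it.org_ids),
                        ",".join(it.refseq_ids),
                        ",".join(sorted(it.gained)),
                        ",".join(sorted(it.missing)),
                    ]
                )
                + "\n"
            )
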