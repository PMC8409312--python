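"""From raw Pfam hits to putative and unique-putative domain content.

A protein's reported Pfam hits may overlap or nest, which is inconsistent
with the linear backbone, and may contain several copies of one family.
Two reductions fix this:

* *putative* domains — a maximal-score, pairwise non-overlapping subset
  of the hits, chosen greedily per overlap conflict;
* *unique putative* domains — one representative per family name, the
  highest-scoring putative copy.

Event calling downstream works on unique-putative content, except
duplication calling which deliberately keeps the non-overlapping copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ContractError, FormatError

#: Sentinel clan id for families outside any Pfam clan ("No_clan").
UNKNOWN_CLAN = "9999.0"
UNKNOWN_CLAN_NAME = "Unknown"

PFAM_SCAN_COLUMNS = 15


@dataclass(frozen=True)
class DomainHit:
    """One Pfam match on one protein, on envelope coordinates.

    ``env_from``/``env_to`` are 1-based inclusive residue indices of the
    widest region supporting the match; ``bit_score`` is the hit's score.
    """

    refseq_id: str
    domain_name: str
    domain_acc: str
    clan_id: str
    env_from: int
    env_to: int
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if not (1 <= self.env_from <= self.env_to):
            raise FormatError(
                f"{self.refseq_id}/{self.domain_name}: bad envelope "
                f"[{self.env_from}, {self.env_to}]"
            )
        if self.e_value < 0:
            raise FormatError(f"{self.refseq_id}/{self.domain_name}: negative E-value")

    def overlaps(self, other: "DomainHit") -> bool:
        """Closed-interval overlap: the envelopes share >= 1 residue."""
        return self.env_from <= other.env_to and other.env_from <= self.env_to


@dataclass(frozen=True)
class DomainContent:
    """Resolved domain content of one protein."""

    refseq_id: str
    putative: tuple[DomainHit, ...]
    unique_putative: dict[str, DomainHit]

    @property
    def unique_names(self) -> frozenset[str]:
        return frozenset(self.unique_putative)


def _priority(hit: DomainHit) -> tuple:
    # Descending score; ties broken by lower E-value, then N-terminal
    # position, then name, so output is bit-stable.
    return (-hit.bit_score, hit.e_value, hit.env_from, hit.domain_name)


def read_pfam_hits(path: str | Path) -> list[DomainHit]:
    """Parse pfam_scan 15-column whitespace-delimited output.

    Columns: seq id, alignment start/end, envelope start/end, hmm acc,
    hmm name, type, hmm start/end/length, bit score, E-value,
    significance, clan.  ``#`` comment lines are skipped; clan
    ``No_clan`` maps to the :data:`UNKNOWN_CLAN` sentinel.
    """
    hits: list[DomainHit] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) < PFAM_SCAN_COLUMNS:
                raise FormatError(
                    f"expected {PFAM_SCAN_COLUMNS} columns, got {len(parts)}",
                    line=lineno,
                )
            try:
                env_from = int(parts[3])
                env_to = int(parts[4])
                bit_score = float(parts[11])
                e_value = float(parts[12])
            except ValueError as exc:
                raise FormatError(f"non-numeric field: {exc}", line=lineno) from exc
            clan = parts[14]
            if clan in ("No_clan", "NA", "-"):
                clan = UNKNOWN_CLAN
            try:
                hits.append(
                    DomainHit(
                        refseq_id=parts[0],
                        domain_name=parts[6],
                        domain_acc=parts[5],
                        clan_id=clan,
                        env_from=env_from,
                        env_to=env_to,
                        bit_score=bit_score,
                        e_value=e_value,
                    )
                )
            except FormatError as exc:
                raise FormatError(str(exc), line=lineno) from exc
    return hits


def write_pfam_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the pfam_scan dialect :func:`read_pfam_hits` reads.

    Alignment coordinates are written equal to the envelope and the hmm
    span is written as 1..(env length); only fields the model consumes
    round-trip faithfully.
    """
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "# <seq id> <aln start> <aln end> <env start> <env end> <hmm acc> "
            "<hmm name> <type> <hmm start> <hmm end> <hmm length> <bit score> "
            "<E-value> <significance> <clan>\n"
        )
        for h in hits:
            span = h.env_to - h.env_from + 1
            clan = "No_clan" if h.clan_id == UNKNOWN_CLAN else h.clan_id
            fh.write(
                f"{h.refseq_id} {h.env_from} {h.env_to} {h.env_from} {h.env_to} "
                f"{h.domain_acc} {h.domain_name} Domain 1 {span} {span} "
                f"{h.bit_score:g} {h.e_value:g} 1 {clan}\n"
            )


def read_hmmscan_domtblout(path: str | Path, clan_map: dict[str, str] | None = None) -> list[DomainHit]:
    """Parse hmmscan ``--domtblout`` as an alternative hit source.

    ``clan_map`` supplies family -> clan ids (domtblout carries none);
    unmapped families get the Unknown clan.
    """
    clan_map = clan_map or {}
    hits: list[DomainHit] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 23:
                raise FormatError(f"expected >= 23 columns, got {len(parts)}", line=lineno)
            try:
                hits.append(
                    DomainHit(
                        refseq_id=parts[3],
                        domain_name=parts[0],
                        domain_acc=parts[1],
                        clan_id=clan_map.get(parts[0], UNKNOWN_CLAN),
                        env_from=int(parts[19]),
                        env_to=int(parts[20]),
                        bit_score=float(parts[13]),
                        e_value=float(parts[12]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"non-numeric field: {exc}", line=lineno) from exc
    return hits


def resolve_putative(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy maximal-score selection of pairwise non-overlapping hits.

    Hits are visited in priority order (descending bit score, ties by
    E-value, position, name); a hit is kept iff it shares no residue
    with any already-kept hit.  Nested hits count as overlapping.  The
    result is returned N- to C-terminal (by env_from).

    All hits must belong to one protein; mixed ids raise
    :class:`ContractError`.
    """
    if not hits:
        return []
    ids = {h.refseq_id for h in hits}
    if len(ids) > 1:
        raise ContractError(f"hits from multiple proteins: {sorted(ids)}")
    kept: list[DomainHit] = []
    for hit in sorted(hits, key=_priority):
        if not any(hit.overlaps(k) for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: (h.env_from, h.env_to, h.domain_name))
    return kept


def resolve_unique_putative(putative: Sequence[DomainHit]) -> dict[str, DomainHit]:
    """One representative per family: the highest-priority putative copy."""
    best: dict[str, DomainHit] = {}
    for hit in putative:
        cur = best.get(hit.domain_name)
        if cur is None or _priority(hit) < _priority(cur):
            best[hit.domain_name] = hit
    return best


def domain_content(hits: Sequence[DomainHit]) -> DomainContent:
    """Resolve one protein's hits to putative + unique-putative content."""
    putative = resolve_putative(hits)
    refseq_id = hits[0].refseq_id if hits else ""
    return DomainContent(
        refseq_id=refseq_id,
        putative=tuple(putative),
        unique_putative=resolve_unique_putative(putative),
    )
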