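"""Readers, writers and filters for the per-organism input tables.

Three tabular dialects come in:

* an organism registry (TSV with superdomain taxonomy),
* a protein metadata table (TSV, one row per RefSeq protein product),
* KO assignments in the KofamKOALA ``--format detail-tsv`` dialect.

Two filters reduce them to the catalogue the model runs on: proteins must
carry exactly one confident KO assignment, and only the longest isoform
per gene is kept so alternative splicing cannot masquerade as domain
gain/loss.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, UniquenessError

SUPERDOMAINS = ("Eukaryota", "Bacteria", "Viruses")

# 3-5 characters, letter-initial; real registries mix pure-letter KEGG
# codes (hsa) with alphanumeric non-KEGG codes (HHV1, HPV16, SV40)
_ORG_ID_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]{2,4}$")

REGISTRY_COLUMNS = ["org_id", "name", "superdomain", "taxonomy_id", "source_tags"]
PROTEIN_COLUMNS = [
    "refseq_id",
    "gene_symbol",
    "org_id",
    "length_aa",
    "chromosome",
    "strand",
    "isoform_group",
]


@dataclass(frozen=True)
class Organism:
    """One organism with its superdomain taxonomy.

    ``org_id`` is a short (3-5 character) code; by convention lowercase
    codes are KEGG organism codes and uppercase codes are organisms
    outside KEGG.  ``source_tags`` carries ecology/group labels as
    opaque strings.
    """

    org_id: str
    name: str
    superdomain: str
    taxonomy_id: int
    source_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _ORG_ID_RE.match(self.org_id):
            raise FormatError(f"org_id {self.org_id!r} is not a 3-5 character code")
        if self.superdomain not in SUPERDOMAINS:
            raise FormatError(
                f"superdomain {self.superdomain!r} not one of {SUPERDOMAINS}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """One protein product (RefSeq) of one organism."""

    refseq_id: str
    gene_symbol: str
    org_id: str
    length_aa: int
    chromosome: str = ""
    strand: str = "unknown"
    isoform_group: str = ""
    is_longest: bool = False
    ko_number: str | None = None

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise FormatError(
                f"protein {self.refseq_id}: length_aa must be >= 1, got {self.length_aa}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise FormatError(
                f"protein {self.refseq_id}: strand must be '+', '-' or 'unknown'"
            )


@dataclass(frozen=True)
class KoalaAssignment:
    """One KofamKOALA hit row; ``significant`` mirrors the asterisk mark."""

    refseq_id: str
    ko_number: str
    score: float
    threshold: float
    e_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError(f"{self.refseq_id}: negative E-value")


# ---------------------------------------------------------------------------
# organism registry
# ---------------------------------------------------------------------------

def read_organism_registry(path: str | Path) -> list[Organism]:
    """Read the organism registry TSV.

    The header must name ``org_id, name, superdomain, taxonomy_id,
    source_tags`` (source_tags optional, comma-joined).  Duplicate org_id
    raises :class:`UniquenessError`; an unknown superdomain raises
    :class:`FormatError` naming the row.
    """
    path = Path(path)
    organisms: list[Organism] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError("empty registry file", line=1)
        cols = [c.strip() for c in header.rstrip("\n").split("\t")]
        for required in REGISTRY_COLUMNS[:4]:
            if required not in cols:
                raise FormatError(f"missing column {required!r} in header", line=1)
        idx = {c: i for i, c in enumerate(cols)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                tags_raw = (
                    parts[idx["source_tags"]] if "source_tags" in idx and idx["source_tags"] < len(parts) else ""
                )
                org = Organism(
                    org_id=parts[idx["org_id"]].strip(),
                    name=parts[idx["name"]].strip(),
                    superdomain=parts[idx["superdomain"]].strip(),
                    taxonomy_id=int(parts[idx["taxonomy_id"]]),
                    source_tags=tuple(t.strip() for t in tags_raw.split(",") if t.strip()),
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(str(exc), line=lineno) from exc
            except FormatError as exc:
                raise FormatError(str(exc), line=lineno) from exc
            if org.org_id in seen:
                raise UniquenessError(f"duplicate org_id {org.org_id!r} at line {lineno}")
            seen.add(org.org_id)
            organisms.append(org)
    return organisms


def write_organism_registry(organisms: Iterable[Organism], path: str | Path) -> None:
    """Write the registry in the same dialect :func:`read_organism_registry` reads."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(REGISTRY_COLUMNS) + "\n")
        for org in organisms:
            fh.write(
                "\t".join(
                    [
                        org.org_id,
                        org.name,
                        org.superdomain,
                        str(org.taxonomy_id),
                        ",".join(org.source_tags),
                    ]
                )
                + "\n"
            )


def registry_index(organisms: Iterable[Organism]) -> dict[str, Organism]:
    """org_id -> Organism lookup (case-sensitive, per the code convention)."""
    index: dict[str, Organism] = {}
    for org in organisms:
        if org.org_id in index:
            raise UniquenessError(f"duplicate org_id {org.org_id!r}")
        index[org.org_id] = org
    return index


# ---------------------------------------------------------------------------
# protein metadata
# ---------------------------------------------------------------------------

def read_protein_table(path: str | Path) -> list[ProteinRecord]:
    """Read the protein metadata TSV (one row per RefSeq product)."""
    path = Path(path)
    records: list[ProteinRecord] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError("empty protein table", line=1)
        cols = [c.strip() for c in header.rstrip("\n").split("\t")]
        for required in PROTEIN_COLUMNS:
            if required not in cols:
                raise FormatError(f"missing column {required!r} in header", line=1)
        idx = {c: i for i, c in enumerate(cols)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                records.append(
                    ProteinRecord(
                        refseq_id=parts[idx["refseq_id"]].strip(),
                        gene_symbol=parts[idx["gene_symbol"]].strip(),
                        org_id=parts[idx["org_id"]].strip(),
                        length_aa=int(parts[idx["length_aa"]]),
                        chromosome=parts[idx["chromosome"]].strip(),
                        strand=parts[idx["strand"]].strip(),
                        isoform_group=parts[idx["isoform_group"]].strip(),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(str(exc), line=lineno) from exc
            except FormatError as exc:
                raise FormatError(str(exc), line=lineno) from exc
    return records


def write_protein_table(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(PROTEIN_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.refseq_id,
                        rec.gene_symbol,
                        rec.org_id,
                        str(rec.length_aa),
                        rec.chromosome,
                        rec.strand,
                        rec.isoform_group,
                    ]
                )
                + "\n"
            )


def crosscheck_lengths(records: Iterable[ProteinRecord], fasta_path: str | Path) -> list[str]:
    """Compare table lengths against a companion protein FASTA.

    Returns the refseq_ids whose FASTA sequence length disagrees with
    ``length_aa``.  The FASTA is advisory: records absent from it are not
    reported.
    """
    from Bio import SeqIO

    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    return [
        rec.refseq_id
        for rec in records
        if rec.refseq_id in lengths and lengths[rec.refseq_id] != rec.length_aa
    ]


# ---------------------------------------------------------------------------
# KofamKOALA assignments
# ---------------------------------------------------------------------------

def read_koala_assignments(path: str | Path) -> list[KoalaAssignment]:
    """Parse KofamKOALA ``--format detail-tsv`` output.

    Columns: significance mark ("*" or blank), gene name, KO number,
    adaptive threshold, score (bits), E-value, KO definition.  Lines
    starting with ``#`` are comments.
    """
    path = Path(path)
    assignments: list[KoalaAssignment] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(f"expected >= 6 columns, got {len(parts)}", line=lineno)
            mark = parts[0].strip()
            if mark not in ("", "*"):
                raise FormatError(f"bad significance mark {mark!r}", line=lineno)
            try:
                threshold = float(parts[3])
                score = float(parts[4])
                e_value = float(parts[5])
            except ValueError as exc:
                raise FormatError(f"non-numeric field: {exc}", line=lineno) from exc
            assignments.append(
                KoalaAssignment(
                    refseq_id=parts[1].strip(),
                    ko_number=parts[2].strip(),
                    score=score,
                    threshold=threshold,
                    e_value=e_value,
                    significant=(mark == "*"),
                )
            )
    return assignments


def write_koala_assignments(assignments: Iterable[KoalaAssignment], path: str | Path) -> None:
    """Write assignments back in the detail-TSV dialect (canonical formatting)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#\tgene name\tKO\tthrshld\tscore\tE-value\tKO definition\n")
        for a in assignments:
            fh.write(
                "\t".join(
                    [
                        "*" if a.significant else "",
                        a.refseq_id,
                        a.ko_number,
                        f"{a.threshold:g}",
                        f"{a.score:g}",
                        f"{a.e_value:g}",
                        "",
                    ]
                )
                + "\n"
            )


@dataclass
class UniqueKoReport:
    """Book-keeping for the unique-KO filter."""

    n_assigned: int = 0
    n_dropped_no_significant: int = 0
    n_dropped_multi_ko: int = 0
    dropped_multi_ko: list[str] = field(default_factory=list)


def select_unique_ko(
    assignments: Iterable[KoalaAssignment],
) -> tuple[dict[str, str], UniqueKoReport]:
    """Keep proteins with exactly one distinct confident KO.

    Only significant (asterisk-marked) rows count.  A protein maps to a KO
    iff its significant rows name exactly one distinct KO; proteins with
    zero or two-plus distinct KOs are dropped and tallied in the report.
    Idempotent and order-independent over input rows.
    """
    per_protein: dict[str, set[str]] = {}
    seen_proteins: set[str] = set()
    for a in assignments:
        seen_proteins.add(a.refseq_id)
        if a.significant:
            per_protein.setdefault(a.refseq_id, set()).add(a.ko_number)
    mapping: dict[str, str] = {}
    report = UniqueKoReport()
    for refseq_id in seen_proteins:
        kos = per_protein.get(refseq_id, set())
        if len(kos) == 1:
            mapping[refseq_id] = next(iter(kos))
            report.n_assigned += 1
        elif not kos:
            report.n_dropped_no_significant += 1
        else:
            report.n_dropped_multi_ko += 1
            report.dropped_multi_ko.append(refseq_id)
    report.dropped_multi_ko.sort()
    return mapping, report


def select_longest_isoform(records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Pick one protein per isoform group: maximal length, ties by the
    lexicographically smallest refseq_id.

    Returns only the selected records, flagged ``is_longest=True``, in
    input order of first group appearance.
    """
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        key = rec.isoform_group
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            cur = best[key]
            if rec.length_aa > cur.length_aa or (
                rec.length_aa == cur.length_aa and rec.refseq_id < cur.refseq_id
            ):
                best[key] = rec
    return [replace(best[k], is_longest=True) for k in order]


def attach_ko_numbers(
    records: Iterable[ProteinRecord], ko_map: Mapping[str, str]
) -> list[ProteinRecord]:
    """Stamp each record's ko_number from the unique-KO map (None if absent)."""
    return [replace(rec, ko_number=ko_map.get(rec.refseq_id)) for rec in records]
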