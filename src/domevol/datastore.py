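"""The embedded relational store behind the analysis.

Six relations mirror the model's database: four annotation tables
(``taxonomy``, ``ko_annotation``, ``clan_domain``, ``pfam_domain``) and
two data tables (``org_protein_annotation`` for proteins,
``pfam_data`` for domain hits with their putative / unique-putative
flags).  SQLite keeps the store a single portable file; ``:memory:``
works for throwaway builds.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .domains import DomainHit, UNKNOWN_CLAN, UNKNOWN_CLAN_NAME, domain_content
from .errors import DataIntegrityError
from .ingest import Organism, ProteinRecord

_SCHEMA = """
CREATE TABLE taxonomy (
    org_id      TEXT PRIMARY KEY,
    name        TEXT NOT NULL,
    superdomain TEXT NOT NULL CHECK (superdomain IN ('Eukaryota','Bacteria','Viruses')),
    taxonomy_id INTEGER NOT NULL,
    source_tags TEXT NOT NULL DEFAULT ''
);
CREATE TABLE ko_annotation (
    ko_number   TEXT PRIMARY KEY,
    description TEXT NOT NULL DEFAULT ''
);
CREATE TABLE clan_domain (
    clan_id     TEXT PRIMARY KEY,
    clan_name   TEXT NOT NULL DEFAULT '',
    description TEXT NOT NULL DEFAULT ''
);
CREATE TABLE pfam_domain (
    domain_name TEXT PRIMARY KEY,
    domain_acc  TEXT NOT NULL DEFAULT '',
    description TEXT NOT NULL DEFAULT '',
    clan_id     TEXT NOT NULL REFERENCES clan_domain(clan_id)
);
CREATE TABLE org_protein_annotation (
    refseq_id     TEXT PRIMARY KEY,
    gene_symbol   TEXT NOT NULL DEFAULT '',
    org_id        TEXT NOT NULL REFERENCES taxonomy(org_id),
    length_aa     INTEGER NOT NULL CHECK (length_aa >= 1),
    chromosome    TEXT NOT NULL DEFAULT '',
    strand        TEXT NOT NULL DEFAULT 'unknown',
    isoform_group TEXT NOT NULL DEFAULT '',
    is_longest    INTEGER NOT NULL DEFAULT 0,
    ko_number     TEXT REFERENCES ko_annotation(ko_number)
);
CREATE TABLE pfam_data (
    hit_id          INTEGER PRIMARY KEY,
    refseq_id       TEXT NOT NULL REFERENCES org_protein_annotation(refseq_id),
    domain_name     TEXT NOT NULL REFERENCES pfam_domain(domain_name),
    env_from        INTEGER NOT NULL,
    env_to          INTEGER NOT NULL,
    bit_score       REAL NOT NULL,
    e_value         REAL NOT NULL,
    putative        INTEGER NOT NULL DEFAULT 0,
    unique_putative INTEGER NOT NULL DEFAULT 0,
    CHECK (env_from >= 1 AND env_from <= env_to),
    CHECK (unique_putative = 0 OR putative = 1)
);
CREATE INDEX ix_protein_ko ON org_protein_annotation(ko_number);
CREATE INDEX ix_hit_refseq ON pfam_data(refseq_id);
"""

TABLES = (
    "taxonomy",
    "ko_annotation",
    "clan_domain",
    "pfam_domain",
    "org_protein_annotation",
    "pfam_data",
)


@dataclass
class BuildReport:
    """Row counts and filter tallies from one build."""

    table_counts: dict[str, int] = field(default_factory=dict)
    n_proteins_without_ko: int = 0
    n_longest_isoforms: int = 0


@dataclass
class KoMembers:
    """Matched member lists of one KO (index-aligned)."""

    ko_number: str
    refseq_ids: list[str]
    org_ids: list[str]
    unique_putative: list[frozenset[str]]

    def __len__(self) -> int:
        return len(self.refseq_ids)


class EvoProDomDB:
    """Thin wrapper over the sqlite3 connection with query helpers."""

    def __init__(self, conn: sqlite3.Connection, report: BuildReport | None = None):
        self.conn = conn
        self.report = report or BuildReport()

    # -- construction -------------------------------------------------

    @classmethod
    def create(cls, path: str | Path = ":memory:") -> "EvoProDomDB":
        conn = sqlite3.connect(str(path))
        conn.execute("PRAGMA foreign_keys = ON")
        conn.executescript(_SCHEMA)
        return cls(conn)

    @classmethod
    def open(cls, path: str | Path) -> "EvoProDomDB":
        conn = sqlite3.connect(str(path))
        conn.execute("PRAGMA foreign_keys = ON")
        return cls(conn)

    def close(self) -> None:
        self.conn.close()

    # -- queries ------------------------------------------------------

    def ko_numbers(self) -> list[str]:
        rows = self.conn.execute(
            "SELECT DISTINCT ko_number FROM org_protein_annotation "
            "WHERE ko_number IS NOT NULL AND is_longest = 1 ORDER BY ko_number"
        )
        return [r[0] for r in rows]

    def query_ko_members(self, ko_number: str) -> KoMembers:
        """Matched lists for one KO, longest isoforms only.

        Unknown KOs yield empty lists, not an error.
        """
        rows = self.conn.execute(
            "SELECT refseq_id, org_id FROM org_protein_annotation "
            "WHERE ko_number = ? AND is_longest = 1 ORDER BY refseq_id",
            (ko_number,),
        ).fetchall()
        refseq_ids = [r[0] for r in rows]
        org_ids = [r[1] for r in rows]
        sets: list[frozenset[str]] = []
        for refseq_id in refseq_ids:
            names = self.conn.execute(
                "SELECT domain_name FROM pfam_data "
                "WHERE refseq_id = ? AND unique_putative = 1",
                (refseq_id,),
            ).fetchall()
            sets.append(frozenset(n[0] for n in names))
        return KoMembers(ko_number, refseq_ids, org_ids, sets)

    def putative_copy_counts(self, refseq_id: str) -> dict[str, int]:
        """Per-family putative copy counts for one protein (copies kept)."""
        rows = self.conn.execute(
            "SELECT domain_name, COUNT(*) FROM pfam_data "
            "WHERE refseq_id = ? AND putative = 1 GROUP BY domain_name",
            (refseq_id,),
        ).fetchall()
        return {name: n for name, n in rows}

    def clan_of(self, domain_name: str) -> str:
        row = self.conn.execute(
            "SELECT clan_id FROM pfam_domain WHERE domain_name = ?", (domain_name,)
        ).fetchone()
        return row[0] if row else UNKNOWN_CLAN

    def superdomain_of(self, org_id: str) -> str:
        row = self.conn.execute(
            "SELECT superdomain FROM taxonomy WHERE org_id = ?", (org_id,)
        ).fetchone()
        if row is None:
            raise LookupError(f"unknown organism {org_id!r}")
        return row[0]

    def table_count(self, table: str) -> int:
        if table not in TABLES:
            raise ValueError(f"unknown table {table!r}")
        return self.conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    # -- export / import ----------------------------------------------

    def export_tables(self, out_dir: str | Path) -> None:
        """Dump each relation to ``<out_dir>/<table>.tsv`` (canonical order)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for table in TABLES:
            cur = self.conn.execute(f"SELECT * FROM {table}")
            cols = [d[0] for d in cur.description]
            rows = sorted(cur.fetchall())
            with (out_dir / f"{table}.tsv").open("w", encoding="utf-8") as fh:
                fh.write("\t".join(cols) + "\n")
                for row in rows:
                    fh.write(
                        "\t".join("" if v is None else str(v) for v in row) + "\n"
                    )

    @classmethod
    def import_tables(cls, in_dir: str | Path, path: str | Path = ":memory:") -> "EvoProDomDB":
        """Rebuild a database from :meth:`export_tables` output."""
        in_dir = Path(in_dir)
        db = cls.create(path)
        for table in TABLES:
            tsv = in_dir / f"{table}.tsv"
            with tsv.open(encoding="utf-8") as fh:
                cols = fh.readline().rstrip("\n").split("\t")
                placeholders = ",".join("?" for _ in cols)
                stmt = f"INSERT INTO {table} ({','.join(cols)}) VALUES ({placeholders})"
                for line in fh:
                    values = [v if v != "" else None for v in line.rstrip("\n").split("\t")]
                    # empty string columns legitimately round-trip as ''
                    values = [
                        "" if (v is None and cols[i] not in ("ko_number",)) else v
                        for i, v in enumerate(values)
                    ]
                    db.conn.execute(stmt, values)
        db.conn.commit()
        return db

    def dump_canonical(self) -> dict[str, list[tuple]]:
        """All tables as sorted row lists, for equality comparison."""
        out = {}
        for table in TABLES:
            cur = self.conn.execute(f"SELECT * FROM {table}")
            rows = [tuple("" if v is None else str(v) for v in row) for row in cur.fetchall()]
            out[table] = sorted(rows)
        return out


def build_db(
    registry: Sequence[Organism],
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    ko_map: Mapping[str, str],
    clan_map: Mapping[str, tuple[str, str]] | Mapping[str, str],
    ko_descriptions: Mapping[str, str] | None = None,
    clan_names: Mapping[str, str] | None = None,
    path: str | Path = ":memory:",
) -> EvoProDomDB:
    """Populate all six relations and compute the putative flags.

    Parameters
    ----------
    clan_map:
        family name -> clan id (or ``(clan id, family description)``).
        Families seen in hits but absent from the map get the Unknown
        clan.
    ko_map:
        refseq_id -> KO from the unique-KO filter.  Proteins outside the
        map are stored with a NULL ko_number and take no part in event
        detection.

    Longest-isoform flags are taken from the records as given (run
    :func:`domevol.ingest.select_longest_isoform` first when loading raw
    tables); records not flagged are stored as alternative isoforms.

    Raises :class:`DataIntegrityError` on any dangling reference.
    """
    ko_descriptions = ko_descriptions or {}
    clan_names = clan_names or {}
    db = EvoProDomDB.create(path)
    conn = db.conn

    org_ids = set()
    for org in registry:
        if org.org_id in org_ids:
            raise DataIntegrityError(f"taxonomy: duplicate org_id {org.org_id!r}")
        org_ids.add(org.org_id)
        conn.execute(
            "INSERT INTO taxonomy VALUES (?,?,?,?,?)",
            (org.org_id, org.name, org.superdomain, org.taxonomy_id,
             ",".join(org.source_tags)),
        )

    kos = sorted(set(ko_map.values()))
    for ko in kos:
        conn.execute(
            "INSERT INTO ko_annotation VALUES (?,?)", (ko, ko_descriptions.get(ko, ""))
        )

    # clan table always carries the Unknown sentinel row
    def _clan_of(name: str) -> tuple[str, str]:
        entry = clan_map.get(name, UNKNOWN_CLAN)
        if isinstance(entry, tuple):
            return entry
        return entry, ""

    clan_ids = {UNKNOWN_CLAN}
    for name in clan_map:
        clan_ids.add(_clan_of(name)[0])
    for clan_id in sorted(clan_ids):
        cname = clan_names.get(clan_id, UNKNOWN_CLAN_NAME if clan_id == UNKNOWN_CLAN else "")
        conn.execute("INSERT INTO clan_domain VALUES (?,?,?)", (clan_id, cname, ""))

    domain_names = sorted({h.domain_name for h in hits} | set(clan_map))
    accs = {h.domain_name: h.domain_acc for h in hits}
    for name in domain_names:
        clan_id, desc = _clan_of(name)
        if clan_id not in clan_ids:
            raise DataIntegrityError(f"pfam_domain: unknown clan {clan_id!r} for {name!r}")
        conn.execute(
            "INSERT INTO pfam_domain VALUES (?,?,?,?)",
            (name, accs.get(name, ""), desc, clan_id),
        )

    refseq_ids = set()
    report = BuildReport()
    for rec in proteins:
        if rec.org_id not in org_ids:
            raise DataIntegrityError(
                f"org_protein_annotation: unknown org_id {rec.org_id!r} "
                f"for protein {rec.refseq_id!r}"
            )
        if rec.refseq_id in refseq_ids:
            raise DataIntegrityError(
                f"org_protein_annotation: duplicate refseq_id {rec.refseq_id!r}"
            )
        refseq_ids.add(rec.refseq_id)
        ko = ko_map.get(rec.refseq_id)
        if ko is None:
            report.n_proteins_without_ko += 1
        if rec.is_longest:
            report.n_longest_isoforms += 1
        conn.execute(
            "INSERT INTO org_protein_annotation VALUES (?,?,?,?,?,?,?,?,?)",
            (rec.refseq_id, rec.gene_symbol, rec.org_id, rec.length_aa,
             rec.chromosome, rec.strand, rec.isoform_group,
             int(rec.is_longest), ko),
        )

    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.refseq_id not in refseq_ids:
            raise DataIntegrityError(
                f"pfam_data: hit references unknown protein {hit.refseq_id!r}"
            )
        by_protein.setdefault(hit.refseq_id, []).append(hit)

    hit_id = 0
    for refseq_id in sorted(by_protein):
        content = domain_content(by_protein[refseq_id])
        putative = set(map(id, content.putative))
        unique = set(map(id, content.unique_putative.values()))
        for hit in by_protein[refseq_id]:
            hit_id += 1
            conn.execute(
                "INSERT INTO pfam_data VALUES (?,?,?,?,?,?,?,?,?)",
                (hit_id, hit.refseq_id, hit.domain_name, hit.env_from, hit.env_to,
                 hit.bit_score, hit.e_value,
                 int(id(hit) in putative), int(id(hit) in unique)),
            )

    conn.commit()
    for table in TABLES:
        report.table_counts[table] = db.table_count(table)
    db.report = report
    return db
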