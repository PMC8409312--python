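"""Mobile-domain, translocation, indel and duplication calling.

The model's event logic, on top of the architecture items:

* A unique-putative domain is *mobile* within a KO when the organisms
  split into a domain-containing group A and a domain-lacking group B
  with ``4 <= |A| < |T| - 4`` (T = A ∪ B), i.e. at least four organisms
  on both sides with strict slack on the containing side.
* A domain mobile in two KOs *translocates* between them when the
  reciprocal intersections A* = A1 ∩ B2 and B* = A2 ∩ B1 both have at
  least four organisms; otherwise each mobile (domain, KO) record is an
  *indel* event.  The two outcomes are mutually exclusive per domain.
* Duplication works on putative copies (not unique-putative): a domain
  is nonduplicated in a KO iff its copy number is constant across the
  member proteins that contain it; the global verdict compares the
  number of duplicated vs nonduplicated KOs against a 99%-percentile
  significance cutoff.

Organism groups are classified by superdomain taxonomy (Eukaryota,
Bacteria, Viruses) — or "Mixed" when members disagree — and events are
labelled with the composite class of their two groups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .architectures import ArchitectureItem
from .config import RunConfig
from .datastore import EvoProDomDB
from .domains import UNKNOWN_CLAN
from .errors import ContractError
from .ingest import Organism

MIXED = "Mixed"


@dataclass(frozen=True)
class MobileDomainRecord:
    """Presence/absence split of one domain across one KO's organisms.

    ``A`` holds organisms whose proteins all contain the domain, ``B``
    those whose proteins all lack it; organisms carrying both containing
    and lacking paralogs land in ``excluded`` (under the default
    ambiguity policy) and count in neither side nor in T.
    """

    domain_name: str
    ko_number: str
    A: frozenset[str]
    B: frozenset[str]
    excluded: frozenset[str]
    is_mobile: bool

    @property
    def T_size(self) -> int:
        return len(self.A) + len(self.B)


@dataclass(frozen=True)
class TranslocationEvent:
    """Reciprocal exchange of one domain between two KOs.

    Orientation is canonical: ko1 is the numerically smaller KO, and
    A* = A1 ∩ B2, B* = A2 ∩ B1 are computed from that ordering.
    """

    domain_name: str
    ko1: str
    ko2: str
    A_star: frozenset[str]
    B_star: frozenset[str]
    class_label: str
    clan_id: str


@dataclass(frozen=True)
class IndelEvent:
    """A mobile (domain, KO) record that translocates nowhere."""

    domain_name: str
    ko_number: str
    A: frozenset[str]
    B: frozenset[str]
    class_label: str
    clan_id: str


@dataclass(frozen=True)
class DuplicationCall:
    """Per-KO copy-number-constancy statuses and the global verdict."""

    domain_name: str
    per_ko_status: Mapping[str, str]
    diff: int
    global_status: str


def _ko_sort_key(ko: str) -> tuple:
    m = re.search(r"(\d+)", ko)
    return (int(m.group(1)) if m else -1, ko)


def superdomain_class(orgs: Iterable[str], registry: Mapping[str, Organism] | Sequence[Organism]) -> str:
    """Shared superdomain of a non-empty organism set, else ``"Mixed"``.

    Permutation-invariant; unknown organisms raise :class:`LookupError`.
    """
    if not isinstance(registry, Mapping):
        registry = {o.org_id: o for o in registry}
    orgs = list(orgs)
    if not orgs:
        raise ContractError("superdomain_class needs a non-empty organism set")
    labels = set()
    for org in orgs:
        if org not in registry:
            raise LookupError(f"unknown organism {org!r}")
        labels.add(registry[org].superdomain)
    return labels.pop() if len(labels) == 1 else MIXED


def mobile_domains(
    items: Sequence[ArchitectureItem],
    min_group_size: int = 4,
    ambiguity_policy: str = "exclude",
) -> list[MobileDomainRecord]:
    """Split each domain of one KO into containing/lacking organism groups.

    For every domain appearing in the KO: an organism joins A when all
    its proteins' architectures contain the domain, B when none do.
    Organisms with both kinds of paralogs follow ``ambiguity_policy``
    (excluded by default).  The record is mobile iff
    ``min_group_size <= |A| < T - min_group_size``.
    """
    if not items:
        return []
    kos = {it.ko_number for it in items}
    if len(kos) > 1:
        raise ContractError(f"items from multiple KOs: {sorted(kos)}")
    ko = items[0].ko_number

    universe: set[str] = set()
    for it in items:
        universe |= it.domain_set
    # organism -> list of domain sets of its proteins (via item membership)
    per_org: dict[str, list[frozenset[str]]] = {}
    for it in items:
        for org in it.org_ids:
            per_org.setdefault(org, []).append(it.domain_set)

    records = []
    for domain in sorted(universe):
        A, B, excluded = set(), set(), set()
        for org, dsets in per_org.items():
            has = [domain in s for s in dsets]
            if all(has):
                A.add(org)
            elif not any(has):
                B.add(org)
            elif ambiguity_policy == "to_A":
                A.add(org)
            elif ambiguity_policy == "to_B":
                B.add(org)
            else:
                excluded.add(org)
        t = len(A) + len(B)
        mobile = min_group_size <= len(A) < t - min_group_size
        records.append(
            MobileDomainRecord(
                domain_name=domain,
                ko_number=ko,
                A=frozenset(A),
                B=frozenset(B),
                excluded=frozenset(excluded),
                is_mobile=mobile,
            )
        )
    return records


def detect_translocations(
    records: Sequence[MobileDomainRecord],
    registry: Mapping[str, Organism] | Sequence[Organism],
    clan_map: Mapping[str, str] | None = None,
    min_group_size: int = 4,
) -> list[TranslocationEvent]:
    """Find reciprocal exchanges among all mobile records.

    For each domain mobile in two KOs k1 < k2 (numeric KO order), the
    reciprocal groups are A* = A1 ∩ B2 and B* = A2 ∩ B1; an event is
    emitted iff both reach ``min_group_size``.  One event per
    (domain, KO pair).
    """
    if not isinstance(registry, Mapping):
        registry = {o.org_id: o for o in registry}
    clan_map = clan_map or {}
    by_domain: dict[str, list[MobileDomainRecord]] = {}
    for rec in records:
        if rec.is_mobile:
            by_domain.setdefault(rec.domain_name, []).append(rec)

    events = []
    for domain in sorted(by_domain):
        recs = sorted(by_domain[domain], key=lambda r: _ko_sort_key(r.ko_number))
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                r1, r2 = recs[i], recs[j]
                a_star = r1.A & r2.B
                b_star = r2.A & r1.B
                if len(a_star) >= min_group_size and len(b_star) >= min_group_size:
                    label = (
                        f"{superdomain_class(a_star, registry)}-"
                        f"{superdomain_class(b_star, registry)}"
                    )
                    events.append(
                        TranslocationEvent(
                            domain_name=domain,
                            ko1=r1.ko_number,
                            ko2=r2.ko_number,
                            A_star=frozenset(a_star),
                            B_star=frozenset(b_star),
                            class_label=label,
                            clan_id=clan_map.get(domain, UNKNOWN_CLAN),
                        )
                    )
    return events


def classify_indels(
    records: Sequence[MobileDomainRecord],
    events: Sequence[TranslocationEvent],
    registry: Mapping[str, Organism] | Sequence[Organism],
    clan_map: Mapping[str, str] | None = None,
) -> list[IndelEvent]:
    """Turn the non-translocating mobile records into indel events.

    A domain with at least one translocation contributes no indels;
    every other mobile (domain, KO) record becomes one indel event,
    labelled containing-side first.
    """
    if not isinstance(registry, Mapping):
        registry = {o.org_id: o for o in registry}
    clan_map = clan_map or {}
    translocated = {ev.domain_name for ev in events}
    indels = []
    for rec in records:
        if not rec.is_mobile or rec.domain_name in translocated:
            continue
        label = (
            f"{superdomain_class(rec.A, registry)}-"
            f"{superdomain_class(rec.B, registry)}"
        )
        indels.append(
            IndelEvent(
                domain_name=rec.domain_name,
                ko_number=rec.ko_number,
                A=rec.A,
                B=rec.B,
                class_label=label,
                clan_id=clan_map.get(rec.domain_name, UNKNOWN_CLAN),
            )
        )
    return indels


# ---------------------------------------------------------------------------
# duplication
# ---------------------------------------------------------------------------

DUPLICATED = "duplicated"
NONDUPLICATED = "nonduplicated"
UNDETERMINED = "undetermined"


def per_ko_duplication_status(copy_counts: Sequence[int]) -> str:
    """Nonduplicated iff the copy number is the same in every containing
    protein; the counts are from proteins that contain the domain, so
    every entry is >= 1."""
    counts = [c for c in copy_counts if c >= 1]
    if not counts:
        raise ContractError("no containing proteins")
    return NONDUPLICATED if len(set(counts)) == 1 else DUPLICATED


def duplication_calls(
    db: EvoProDomDB,
    percentile: float = 0.99,
    rule: str = "empirical",
) -> list[DuplicationCall]:
    """Global duplicated/nonduplicated verdicts over all domains.

    Per KO a domain's status is copy-number constancy across its
    containing member proteins (putative copies, so tandem repeats
    count).  Globally ``diff = n_duplicated - n_nonduplicated`` over the
    KOs containing the domain; under the default ``"empirical"`` rule
    the verdict is duplicated when ``diff > 0`` and ``diff`` reaches the
    requested percentile of the |diff| distribution over all domains
    (symmetrically nonduplicated for negative diff), else undetermined.
    The ``"cumsum-rank"`` rule instead takes the cutoff as the |diff|
    value where the descending cumulative sum of |diff| crosses the
    percentile of its total.
    """
    per_domain: dict[str, dict[str, str]] = {}
    for ko in db.ko_numbers():
        members = db.query_ko_members(ko)
        counts: dict[str, list[int]] = {}
        for refseq_id in members.refseq_ids:
            for name, n in db.putative_copy_counts(refseq_id).items():
                counts.setdefault(name, []).append(n)
        for name, cc in counts.items():
            per_domain.setdefault(name, {})[ko] = per_ko_duplication_status(cc)

    domains = sorted(per_domain)
    diffs = {
        d: sum(1 for s in per_domain[d].values() if s == DUPLICATED)
        - sum(1 for s in per_domain[d].values() if s == NONDUPLICATED)
        for d in domains
    }
    cutoff = duplication_cutoff(list(diffs.values()), percentile, rule)

    calls = []
    for d in domains:
        diff = diffs[d]
        if diff > 0 and diff >= cutoff:
            status = DUPLICATED
        elif diff < 0 and -diff >= cutoff:
            status = NONDUPLICATED
        else:
            status = UNDETERMINED
        calls.append(
            DuplicationCall(
                domain_name=d,
                per_ko_status=dict(per_domain[d]),
                diff=diff,
                global_status=status,
            )
        )
    return calls


def duplication_cutoff(diffs: Sequence[int], percentile: float, rule: str) -> float:
    """Significance cutoff on |diff| under either rule; infinite for an
    empty input so nothing is called."""
    mags = np.abs(np.asarray(diffs, dtype=float))
    if mags.size == 0:
        return np.inf
    if rule == "empirical":
        return float(np.percentile(mags, 100.0 * percentile))
    if rule == "cumsum-rank":
        order = np.sort(mags)[::-1]
        total = order.sum()
        if total == 0:
            return np.inf
        csum = np.cumsum(order)
        k = int(np.searchsorted(csum, percentile * total))
        return float(order[min(k, order.size - 1)])
    raise ValueError(f"unknown duplication rule {rule!r}")


# ---------------------------------------------------------------------------
# summaries and exports
# ---------------------------------------------------------------------------

def summarize_by_superfamily(
    events: Sequence[TranslocationEvent | IndelEvent],
    clan_names: Mapping[str, str] | None = None,
) -> list[tuple[str, str, str, int]]:
    """(class_label, clan_id, clan_name, count) rows, count-descending."""
    clan_names = clan_names or {}
    counter = Counter((ev.class_label, ev.clan_id) for ev in events)
    rows = [
        (label, clan, clan_names.get(clan, ""), n)
        for (label, clan), n in counter.items()
    ]
    rows.sort(key=lambda r: (-r[3], r[0], r[1]))
    return rows


@dataclass
class EventResults:
    """Bundle returned by :func:`call_events`."""

    mobile: list[MobileDomainRecord] = field(default_factory=list)
    translocations: list[TranslocationEvent] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)
    duplications: list[DuplicationCall] = field(default_factory=list)

    @property
    def mobile_domains(self) -> list[MobileDomainRecord]:
        return [r for r in self.mobile if r.is_mobile]


def call_events(
    db: EvoProDomDB,
    config: RunConfig | None = None,
) -> EventResults:
    """Run the whole event-calling stage on a built database."""
    from .architectures import partition_ko

    config = config or RunConfig()
    registry = {
        org_id: Organism(org_id, name, superdomain, taxonomy_id, tuple())
        for org_id, name, superdomain, taxonomy_id, _ in db.conn.execute(
            "SELECT * FROM taxonomy"
        )
    }
    clan_map = {
        name: clan for name, clan in db.conn.execute(
            "SELECT domain_name, clan_id FROM pfam_domain"
        )
    }
    records: list[MobileDomainRecord] = []
    for ko in db.ko_numbers():
        members = db.query_ko_members(ko)
        if len(members) == 0:
            continue
        items = partition_ko(members)
        if len(items) < 2:
            continue
        records.extend(
            mobile_domains(items, config.min_group_size, config.ambiguity_policy)
        )
    translocations = detect_translocations(
        records, registry, clan_map, config.min_group_size
    )
    indels = classify_indels(records, translocations, registry, clan_map)
    duplications = duplication_calls(
        db, config.duplication_percentile, config.duplication_rule
    )
    return EventResults(
        mobile=records,
        translocations=translocations,
        indels=indels,
        duplications=duplications,
    )


def write_event_tables(
    results: EventResults,
    out_dir: str | Path,
    clan_names: Mapping[str, str] | None = None,
) -> None:
    """Write the supplementary-style TSVs: raw translocations, class
    counts, raw indels, indel class frequencies, per-superfamily counts
    for both event kinds, and duplication calls."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with (out / "translocations.tsv").open("w", encoding="utf-8") as fh:
        fh.write("domain_name\tclan_id\tko1\tko2\tA_star\tB_star\tclass\n")
        for ev in results.translocations:
            fh.write(
                f"{ev.domain_name}\t{ev.clan_id}\t{ev.ko1}\t{ev.ko2}\t"
                f"{','.join(sorted(ev.A_star))}\t{','.join(sorted(ev.B_star))}\t"
                f"{ev.class_label}\n"
            )

    with (out / "translocation_class_counts.tsv").open("w", encoding="utf-8") as fh:
        fh.write("class\tcount\n")
        for label, n in sorted(
            Counter(ev.class_label for ev in results.translocations).items(),
            key=lambda kv: (-kv[1], kv[0]),
        ):
            fh.write(f"{label}\t{n}\n")

    with (out / "indels.tsv").open("w", encoding="utf-8") as fh:
        fh.write("domain_name\tclan_id\tko_number\tA\tB\tclass\n")
        for ev in results.indels:
            fh.write(
                f"{ev.domain_name}\t{ev.clan_id}\t{ev.ko_number}\t"
                f"{','.join(sorted(ev.A))}\t{','.join(sorted(ev.B))}\t"
                f"{ev.class_label}\n"
            )

    with (out / "indel_class_counts.tsv").open("w", encoding="utf-8") as fh:
        fh.write("class\tcount\n")
        for label, n in sorted(
            Counter(ev.class_label for ev in results.indels).items(),
            key=lambda kv: (-kv[1], kv[0]),
        ):
            fh.write(f"{label}\t{n}\n")

    for name, evs in (
        ("translocations_per_superfamily.tsv", results.translocations),
        ("indels_per_superfamily.tsv", results.indels),
    ):
        with (out / name).open("w", encoding="utf-8") as fh:
            fh.write("class\tclan_id\tclan_name\tcount\n")
            for label, clan, cname, n in summarize_by_superfamily(evs, clan_names):
                fh.write(f"{label}\t{clan}\t{cname}\t{n}\n")

    with (out / "duplications.tsv").open("w", encoding="utf-8") as fh:
        fh.write("domain_name\tn_duplicated_kos\tn_nonduplicated_kos\tdiff\tglobal_status\n")
        for call in results.duplications:
            n_dup = sum(1 for s in call.per_ko_status.values() if s == DUPLICATED)
            n_non = sum(1 for s in call.per_ko_status.values() if s == NONDUPLICATED)
            fh.write(
                f"{call.domain_name}\t{n_dup}\t{n_non}\t{call.diff}\t{call.global_status}\n"
            )
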