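"""Self-contained synthetic cohorts with planted evolutionary events.

Everything the ingest stage reads — organism registry, protein metadata,
Pfam hits, KO assignments — can be generated here, with translocations,
indels and duplications planted at known organism-group sizes and a
manifest stating what a correct detector must report.  The manifest is
computed by applying the model's printed thresholds directly to the
constructed presence/absence patterns, independently of the detection
code, so generator and detector can be checked against each other
end to end.

The construction keeps background variation *below* the event
thresholds (domain drop-outs touch at most three organisms per KO), so
at noiseless settings the only events present are the planted ones.
Decoy hits — overlapping lower-scoring matches, nested same-family
copies — are injected so the putative/unique-putative filtering is
actually exercised on every cohort.

The worked reciprocal-translocation example (the FERM_C domain swapping
between the FRMD6 and MYLIP ortholog groups across eleven vertebrate
genomes) ships as :func:`ferm_c_fixture`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .domains import DomainHit, UNKNOWN_CLAN, UNKNOWN_CLAN_NAME, write_pfam_hits
from .errors import FixtureSpecError
from .ingest import (
    KoalaAssignment,
    Organism,
    ProteinRecord,
    write_koala_assignments,
    write_organism_registry,
    write_protein_table,
)

MIN_GROUP_SIZE = 4  # the model's published group-size threshold


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTranslocation:
    """Plant ``domain`` reciprocally between ``ko1`` and ``ko2`` with
    requested reciprocal-group sizes.  Sub-threshold sizes are padded
    with shared containing organisms so the domain stays mobile and the
    event degrades to indels, not to nothing."""

    domain: str
    ko1: str
    ko2: str
    a_size: int
    b_size: int


@dataclass(frozen=True)
class PlantedIndel:
    domain: str
    ko: str
    a_size: int


@dataclass(frozen=True)
class PlantedDuplication:
    """``n_dup_kos`` KOs with varying copy number, ``n_nondup_kos`` with
    a constant two copies per protein."""

    domain: str
    n_dup_kos: int
    n_nondup_kos: int


@dataclass
class FixtureSpec:
    """Deterministic recipe for one synthetic cohort.

    Defaults describe a small mixed-superdomain cohort: a dozen
    eukaryotes (the corpus the model targets is eukaryote-dominated),
    a couple of bacteria and one virus, four KO groups.  ``seed`` fully
    determines the output.
    """

    n_eukaryota: int = 12
    n_bacteria: int = 2
    n_viruses: int = 1
    n_kos: int = 4
    domain_pool: Sequence[tuple[str, str]] = ()
    planted_translocations: Sequence[PlantedTranslocation | tuple] = ()
    planted_indels: Sequence[PlantedIndel | tuple] = ()
    planted_duplications: Sequence[PlantedDuplication | tuple] = ()
    paralog_rate: float = 0.1
    ambiguity_rate: float = 0.0
    isoform_rate: float = 0.2
    decoy_rate: float = 0.3
    seed: int = 0

    def normalized(self) -> "FixtureSpec":
        return replace(
            self,
            planted_translocations=[
                p if isinstance(p, PlantedTranslocation) else PlantedTranslocation(*p)
                for p in self.planted_translocations
            ],
            planted_indels=[
                p if isinstance(p, PlantedIndel) else PlantedIndel(*p)
                for p in self.planted_indels
            ],
            planted_duplications=[
                p if isinstance(p, PlantedDuplication) else PlantedDuplication(*p)
                for p in self.planted_duplications
            ],
        )


@dataclass
class Manifest:
    """What a correct detector must report on this cohort."""

    expected_translocations: list[tuple] = field(default_factory=list)
    # (domain, ko1, ko2, frozenset A*, frozenset B*)
    expected_indels: list[tuple[str, str]] = field(default_factory=list)
    # (domain, ko)
    expected_mobile: list[tuple[str, str]] = field(default_factory=list)
    expected_duplications: dict[str, str] = field(default_factory=dict)
    # every domain's expected global duplication status


@dataclass
class Cohort:
    """In-memory cohort in exactly the shapes the ingest stage produces."""

    registry: list[Organism]
    proteins: list[ProteinRecord]
    hits: list[DomainHit]
    koala: list[KoalaAssignment]
    clan_map: dict[str, str]
    clan_names: dict[str, str]
    ko_descriptions: dict[str, str]
    manifest: Manifest


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _org_codes(n: int, superdomain: str) -> list[str]:
    # lowercase = KEGG-style codes; viruses get uppercase (non-KEGG) codes
    prefix = {"Eukaryota": "e", "Bacteria": "b", "Viruses": "V"}[superdomain]
    letters = "abcdefghijklmnopqrstuvwxyz"
    codes = []
    for i in range(n):
        tail = letters[i // 26] + letters[i % 26]
        code = prefix + tail
        codes.append(code.upper() if superdomain == "Viruses" else code)
    return codes


def generate_cohort(spec: FixtureSpec) -> Cohort:
    """Build a full cohort from a :class:`FixtureSpec`.

    Raises :class:`FixtureSpecError` when a planting cannot fit: planted
    and padding organisms plus the five lacking organisms mobility
    requires must not exceed the cohort, and no domain may be planted
    twice.
    """
    spec = spec.normalized()
    rng = np.random.default_rng(spec.seed)

    registry: list[Organism] = []
    taxid = 9000
    for n, sd in (
        (spec.n_eukaryota, "Eukaryota"),
        (spec.n_bacteria, "Bacteria"),
        (spec.n_viruses, "Viruses"),
    ):
        for code in _org_codes(n, sd):
            taxid += 1
            registry.append(Organism(code, f"Synthetic {sd} {code}", sd, taxid))
    orgs = [o.org_id for o in registry]
    n_orgs = len(orgs)
    if n_orgs == 0:
        raise FixtureSpecError("cohort needs at least one organism")

    kos = [f"K{i:05d}" for i in range(1, spec.n_kos + 1)]
    ko_set = set(kos)

    planted_domains: set[str] = set()

    def _claim(domain: str) -> None:
        if domain in planted_domains:
            raise FixtureSpecError(f"domain {domain!r} planted more than once")
        planted_domains.add(domain)

    # organisms whose presence pattern a planting depends on — ambiguity
    # injection must not touch them
    planted_orgs: dict[str, set[str]] = {}

    # content[ko][org] -> list of domain-count dicts, one per protein
    content: dict[str, dict[str, list[dict[str, int]]]] = {
        ko: {org: [] for org in orgs} for ko in kos
    }

    # base architecture: two core families per KO; the second is dropped
    # from up to three organisms — diversity below the event threshold
    ko_double_core: dict[str, bool] = {}
    for ko in kos:
        core1, core2 = f"Core{ko[1:]}a", f"Core{ko[1:]}b"
        double = bool(rng.random() < 0.5)  # exercise unique-putative collapse
        ko_double_core[ko] = double
        n_drop = int(min(3, max(1, n_orgs - 1))) if n_orgs > 1 else 0
        dropped = set(rng.choice(orgs, size=n_drop, replace=False)) if n_drop else set()
        for org in orgs:
            counts = {core1: 2 if double else 1}
            if org not in dropped:
                counts[core2] = 1
            content[ko][org].append(counts)

    def _add_domain(ko: str, org_list, domain: str) -> None:
        for org in org_list:
            for counts in content[ko][org]:
                counts.setdefault(domain, 1)

    # --- planted translocations ---------------------------------------
    for p in spec.planted_translocations:
        _claim(p.domain)
        for ko in (p.ko1, p.ko2):
            if ko not in ko_set:
                raise FixtureSpecError(f"unknown KO {ko!r} in planting of {p.domain!r}")
        if p.ko1 == p.ko2:
            raise FixtureSpecError(f"{p.domain!r}: ko1 and ko2 must differ")
        pad = max(0, MIN_GROUP_SIZE - p.a_size, MIN_GROUP_SIZE - p.b_size)
        need = p.a_size + p.b_size + pad + 5
        if need > n_orgs:
            raise FixtureSpecError(
                f"{p.domain!r}: needs {need} organisms, cohort has {n_orgs}"
            )
        perm = list(rng.permutation(orgs))
        a_orgs = perm[: p.a_size]
        b_orgs = perm[p.a_size : p.a_size + p.b_size]
        c_orgs = perm[p.a_size + p.b_size : p.a_size + p.b_size + pad]
        _add_domain(p.ko1, a_orgs + c_orgs, p.domain)
        _add_domain(p.ko2, b_orgs + c_orgs, p.domain)
        planted_orgs[p.domain] = set(a_orgs) | set(b_orgs) | set(c_orgs)

    # --- planted indels -------------------------------------------------
    for p in spec.planted_indels:
        _claim(p.domain)
        if p.ko not in ko_set:
            raise FixtureSpecError(f"unknown KO {p.ko!r} in planting of {p.domain!r}")
        if p.a_size > n_orgs:
            raise FixtureSpecError(
                f"{p.domain!r}: |A|={p.a_size} exceeds the {n_orgs}-organism cohort"
            )
        # sub-threshold or slack-less sizes are allowed: the manifest
        # simply expects no mobile record for them
        perm = list(rng.permutation(orgs))
        _add_domain(p.ko, perm[: p.a_size], p.domain)
        planted_orgs[p.domain] = set(perm[: p.a_size])

    # --- planted duplications ------------------------------------------
    for p in spec.planted_duplications:
        _claim(p.domain)
        total = p.n_dup_kos + p.n_nondup_kos
        if total > len(kos):
            raise FixtureSpecError(
                f"{p.domain!r}: needs {total} KOs, cohort has {len(kos)}"
            )
        if p.n_dup_kos and n_orgs < 2:
            raise FixtureSpecError("varying copy number needs >= 2 organisms")
        chosen = list(rng.choice(kos, size=total, replace=False))
        for idx, ko in enumerate(chosen):
            duplicated_here = idx < p.n_dup_kos
            for oi, org in enumerate(sorted(content[ko])):
                copies = (1 + oi % 2) if duplicated_here else 2
                for counts in content[ko][org]:
                    counts[p.domain] = copies

    # --- paralogs (same architecture twice in one organism) -------------
    for ko in kos:
        for org in orgs:
            if spec.paralog_rate and rng.random() < spec.paralog_rate:
                content[ko][org].append(dict(content[ko][org][0]))

    # --- ambiguity injection (both-pattern paralogs) ---------------------
    ambiguous: dict[tuple[str, str], set[str]] = {}
    if spec.ambiguity_rate:
        for p in list(spec.planted_translocations) + list(spec.planted_indels):
            targets = [(p.ko1, p.domain), (p.ko2, p.domain)] if isinstance(
                p, PlantedTranslocation
            ) else [(p.ko, p.domain)]
            for ko, domain in targets:
                lacking = [
                    org
                    for org in orgs
                    if all(domain not in c for c in content[ko][org])
                ]
                slack = len(lacking) - 5  # keep the lacking side mobile-sized
                eligible = [o for o in lacking if o not in planted_orgs[domain]]
                injected: set[str] = set()
                for org in eligible:
                    if len(injected) >= max(0, slack):
                        break
                    if rng.random() < spec.ambiguity_rate:
                        extra = dict(content[ko][org][0])
                        extra[domain] = 1
                        content[ko][org].append(extra)
                        injected.add(org)
                if injected:
                    ambiguous[(ko, domain)] = injected

    # --- materialize proteins, hits, KO assignments ----------------------
    clan_pool = dict(spec.domain_pool)
    clan_map: dict[str, str] = {}
    clan_names: dict[str, str] = {UNKNOWN_CLAN: UNKNOWN_CLAN_NAME}

    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    koala: list[KoalaAssignment] = []

    def _clan_for(domain: str) -> str:
        return clan_pool.get(domain, UNKNOWN_CLAN)

    def _emit_hits(refseq: str, counts: Mapping[str, int]) -> int:
        """Append hits for one protein; returns the protein length."""
        pos = 1
        first_interval = None
        for domain in sorted(counts):
            clan_map.setdefault(domain, _clan_for(domain))
            for _ in range(counts[domain]):
                start, end = pos + 9, pos + 58
                score = float(np.round(60.0 + 30.0 * rng.random(), 1))
                hits.append(
                    DomainHit(refseq, domain, f"PF{zlib.crc32(domain.encode()) % 90000 + 10000}",
                              clan_map[domain], start, end, score, 1e-12)
                )
                if first_interval is None:
                    first_interval = (start, end, score)
                pos = end + 12
        if first_interval is not None and rng.random() < spec.decoy_rate:
            # overlapping lower-score decoy: must vanish in putative filtering
            s, e, sc = first_interval
            clan_map.setdefault("Decoy_ov", UNKNOWN_CLAN)
            hits.append(
                DomainHit(refseq, "Decoy_ov", "PF99901", UNKNOWN_CLAN,
                          s + 5, e + 20, float(np.round(sc - 25.0, 1)), 1e-3)
            )
        if first_interval is not None and rng.random() < spec.decoy_rate:
            # nested same-family copy, lower score: also filtered
            s, e, sc = first_interval
            name = sorted(counts)[0]
            hits.append(
                DomainHit(refseq, name, f"PF{zlib.crc32(name.encode()) % 90000 + 10000}",
                          clan_map[name], s + 3, e - 3,
                          float(np.round(sc - 10.0, 1)), 1e-6)
            )
        return pos + 40

    for ko in kos:
        for org in sorted(content[ko]):
            for pi, counts in enumerate(content[ko][org]):
                gene = f"g_{org}_{ko}_{pi}"
                refseq = f"XP_{ko}_{org}_{pi}"
                length = _emit_hits(refseq, counts)
                proteins.append(
                    ProteinRecord(refseq, gene, org, length,
                                  chromosome=f"chr{1 + pi}", strand="+",
                                  isoform_group=gene)
                )
                koala.append(
                    KoalaAssignment(refseq, ko, score=150.0, threshold=50.0,
                                    e_value=1e-40, significant=True)
                )
                if rng.random() < spec.isoform_rate:
                    # shorter alternative isoform of the same gene — must be
                    # removed by longest-isoform selection
                    iso = f"{refseq}_i1"
                    proteins.append(
                        ProteinRecord(iso, gene, org, max(1, length - 60),
                                      chromosome=f"chr{1 + pi}", strand="+",
                                      isoform_group=gene)
                    )
                    koala.append(
                        KoalaAssignment(iso, ko, 140.0, 50.0, 1e-38, True)
                    )

    # decoy proteins that must be dropped by the unique-KO filter
    if len(kos) >= 2 and orgs:
        for di in range(2):
            org = orgs[di % len(orgs)]
            refseq = f"XP_multiko_{di}"
            proteins.append(
                ProteinRecord(refseq, f"g_multiko_{di}", org, 222,
                              isoform_group=f"g_multiko_{di}")
            )
            koala.append(KoalaAssignment(refseq, kos[0], 120.0, 50.0, 1e-30, True))
            koala.append(KoalaAssignment(refseq, kos[1], 110.0, 50.0, 1e-28, True))
        # a sub-threshold row that must not influence uniqueness
        koala.append(
            KoalaAssignment(proteins[0].refseq_id, kos[-1], 20.0, 50.0, 0.5, False)
        )

    manifest = _expected_events(content, registry, spec)
    return Cohort(
        registry=registry,
        proteins=proteins,
        hits=hits,
        koala=koala,
        clan_map=dict(clan_map),
        clan_names=clan_names,
        ko_descriptions={ko: "" for ko in kos},
        manifest=manifest,
    )


def _expected_events(
    content: Mapping[str, Mapping[str, list[Mapping[str, int]]]],
    registry: Sequence[Organism],
    spec: FixtureSpec,
) -> Manifest:
    """Apply the printed thresholds directly to the construction.

    Straight-line loops over the constructed presence patterns — kept
    independent of the detection modules on purpose.
    """
    manifest = Manifest()
    g = MIN_GROUP_SIZE

    # presence split per (ko, domain)
    splits: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    mobile: dict[str, list[str]] = {}
    for ko in sorted(content):
        universe: set[str] = set()
        for org in content[ko]:
            for counts in content[ko][org]:
                universe |= set(counts)
        for domain in sorted(universe):
            A, B = set(), set()
            for org, prots in content[ko].items():
                has = [domain in c for c in prots]
                if all(has):
                    A.add(org)
                elif not any(has):
                    B.add(org)
            t = len(A) + len(B)
            splits[(ko, domain)] = (A, B)
            if g <= len(A) < t - g:
                mobile.setdefault(domain, []).append(ko)
                manifest.expected_mobile.append((domain, ko))

    def _ko_num(ko: str) -> int:
        return int("".join(ch for ch in ko if ch.isdigit()) or -1)

    translocated: set[str] = set()
    for domain, dkos in sorted(mobile.items()):
        dkos = sorted(dkos, key=_ko_num)
        for i in range(len(dkos)):
            for j in range(i + 1, len(dkos)):
                a1, b1 = splits[(dkos[i], domain)]
                a2, b2 = splits[(dkos[j], domain)]
                a_star, b_star = a1 & b2, a2 & b1
                if len(a_star) >= g and len(b_star) >= g:
                    translocated.add(domain)
                    manifest.expected_translocations.append(
                        (domain, dkos[i], dkos[j], frozenset(a_star), frozenset(b_star))
                    )
    for domain, dkos in sorted(mobile.items()):
        if domain in translocated:
            continue
        for ko in dkos:
            manifest.expected_indels.append((domain, ko))

    # duplication expectations: copy-number constancy per KO, then the
    # percentile rule on the signed KO-count difference
    per_domain: dict[str, dict[str, str]] = {}
    for ko in sorted(content):
        counts_by_domain: dict[str, list[int]] = {}
        for org in content[ko]:
            for counts in content[ko][org]:
                for domain, c in counts.items():
                    if c >= 1:
                        counts_by_domain.setdefault(domain, []).append(c)
        for domain, cc in counts_by_domain.items():
            status = "nonduplicated" if len(set(cc)) == 1 else "duplicated"
            per_domain.setdefault(domain, {})[ko] = status
    diffs = {
        d: sum(1 for s in st.values() if s == "duplicated")
        - sum(1 for s in st.values() if s == "nonduplicated")
        for d, st in per_domain.items()
    }
    if diffs:
        cutoff = float(
            np.percentile(np.abs(list(diffs.values())), 100.0 * 0.99)
        )
        for d in sorted(diffs):
            diff = diffs[d]
            if diff > 0 and diff >= cutoff:
                manifest.expected_duplications[d] = "duplicated"
            elif diff < 0 and -diff >= cutoff:
                manifest.expected_duplications[d] = "nonduplicated"
            else:
                manifest.expected_duplications[d] = "undetermined"
    return manifest


# ---------------------------------------------------------------------------
# the worked reciprocal-translocation example
# ---------------------------------------------------------------------------

#: Organisms whose FRMD6-group proteins carry FERM_C while their
#: MYLIP-group proteins lack it (the 5-member reciprocal group) ...
FERM_A_SIDE = ("CAA", "CHL", "ECTE", "ccar", "lav")
#: ... and the 6-member group with the opposite pattern.
FERM_B_SIDE = ("CHA", "MIO", "PEM", "cge", "ola", "rno")

FERM_KO_FRMD6 = "K16822"
FERM_KO_MYLIP = "K10637"

_FERM_ORGS = {
    "CAA": ("Carassius auratus", 7957),
    "CHL": ("Chinchilla lanigera", 34839),
    "ECTE": ("Echinops telfairi", 9371),
    "ccar": ("Cyprinus carpio", 7962),
    "lav": ("Loxodonta africana", 9785),
    "CHA": ("Chrysochloris asiatica", 185453),
    "MIO": ("Microtus ochrogaster", 79684),
    "PEM": ("Peromyscus maniculatus bairdii", 230844),
    "cge": ("Cricetulus griseus", 10029),
    "ola": ("Oryzias latipes", 8090),
    "rno": ("Rattus norvegicus", 10116),
}

_PH_CLAN = "0266.9"
_RING_CLAN = "0229.11"


def ferm_c_fixture() -> Cohort:
    """Eleven-organism, two-KO cohort reproducing the FERM_C swap.

    The FERM_C domain sits in the FRMD6 ortholog group (K16822) for the
    five A-side organisms and in the MYLIP group (K10637) for the six
    B-side organisms, and is absent from the reciprocal partner in each
    case — one translocation event, class Eukaryota-Eukaryota, zero
    indels for FERM_C.  A couple of paralogs, one alternative isoform
    and one overlapping decoy hit exercise the upstream filters.
    """
    registry = [
        Organism(code, name, "Eukaryota", taxid)
        for code, (name, taxid) in sorted(_FERM_ORGS.items())
    ]
    clan_map = {
        "FERM_N": _PH_CLAN,
        "FERM_M": UNKNOWN_CLAN,
        "FERM_C": _PH_CLAN,
        "zf-C3HC4": _RING_CLAN,
    }
    clan_names = {
        _PH_CLAN: "PH",
        _RING_CLAN: "RING",
        UNKNOWN_CLAN: UNKNOWN_CLAN_NAME,
    }
    ko_descriptions = {
        FERM_KO_FRMD6: "FRMD6; FERM domain-containing protein 6",
        FERM_KO_MYLIP: "MYLIP; E3 ubiquitin-protein ligase MYLIP",
    }

    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    koala: list[KoalaAssignment] = []

    layout = {  # domain -> (env_from, env_to, bit_score)
        "FERM_N": (20, 120, 81.5),
        "FERM_M": (130, 260, 76.2),
        "FERM_C": (270, 360, 70.4),
        "zf-C3HC4": (400, 440, 55.3),
    }

    def add_protein(org: str, ko: str, domains: Sequence[str], copy: int = 0) -> None:
        gene = f"{'FRMD6' if ko == FERM_KO_FRMD6 else 'MYLIP'}_{org}"
        refseq = f"XP_{org}_{ko}_{copy}"
        hit_rows = []
        for d in domains:
            s, e, score = layout[d]
            hit_rows.append(
                DomainHit(refseq, d, f"PF_{d}", clan_map[d], s, e, score, 1e-20)
            )
        proteins.append(
            ProteinRecord(refseq, gene, org, 480, chromosome="chr1", strand="+",
                          isoform_group=f"{gene}_{copy}")
        )
        hits.extend(hit_rows)
        koala.append(KoalaAssignment(refseq, ko, 200.0, 60.0, 1e-50, True))

    frmd6_with = ("FERM_N", "FERM_M", "FERM_C")
    frmd6_without = ("FERM_N", "FERM_M")
    mylip_with = ("FERM_N", "FERM_M", "FERM_C", "zf-C3HC4")
    mylip_without = ("FERM_N", "FERM_M", "zf-C3HC4")

    for org in FERM_A_SIDE:
        add_protein(org, FERM_KO_FRMD6, frmd6_with)
        add_protein(org, FERM_KO_MYLIP, mylip_without)
    for org in FERM_B_SIDE:
        add_protein(org, FERM_KO_FRMD6, frmd6_without)
        add_protein(org, FERM_KO_MYLIP, mylip_with)

    # paralogs: duplicated organisms within one item's matched lists
    add_protein("ccar", FERM_KO_FRMD6, frmd6_with, copy=1)
    add_protein("ola", FERM_KO_MYLIP, mylip_with, copy=1)

    # an alternative isoform that the longest-isoform filter must drop —
    # it deceptively lacks FERM_C
    iso = "XP_rno_K10637_0_i1"
    proteins.append(
        ProteinRecord(iso, "MYLIP_rno", "rno", 300, chromosome="chr1",
                      strand="+", isoform_group="MYLIP_rno_0")
    )
    for d in mylip_without:
        s, e, score = layout[d]
        hits.append(DomainHit(iso, d, f"PF_{d}", clan_map[d], s, e, score, 1e-20))
    koala.append(KoalaAssignment(iso, FERM_KO_MYLIP, 180.0, 60.0, 1e-45, True))

    # an overlapping lower-score decoy on one protein: putative filtering
    # must remove it
    hits.append(
        DomainHit("XP_CAA_K16822_0", "Decoy_ov", "PF99901", UNKNOWN_CLAN,
                  300, 380, 12.5, 0.01)
    )
    clan_map = dict(clan_map, Decoy_ov=UNKNOWN_CLAN)

    manifest = Manifest(
        expected_translocations=[
            (
                "FERM_C",
                FERM_KO_MYLIP,
                FERM_KO_FRMD6,
                frozenset(FERM_B_SIDE),
                frozenset(FERM_A_SIDE),
            )
        ],
        expected_indels=[],
        expected_mobile=[
            ("FERM_C", FERM_KO_MYLIP),
            ("FERM_C", FERM_KO_FRMD6),
        ],
    )
    return Cohort(
        registry=registry,
        proteins=proteins,
        hits=hits,
        koala=koala,
        clan_map=clan_map,
        clan_names=clan_names,
        ko_descriptions=ko_descriptions,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# writing cohorts in the ingest dialects
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write all ingest-dialect files plus clans and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_organism_registry(cohort.registry, out / "registry.tsv")
    write_protein_table(cohort.proteins, out / "proteins.tsv")
    write_pfam_hits(cohort.hits, out / "pfam_hits.txt")
    write_koala_assignments(cohort.koala, out / "koala.tsv")
    with (out / "clans.tsv").open("w", encoding="utf-8") as fh:
        fh.write("domain_name\tclan_id\tclan_name\n")
        for name in sorted(cohort.clan_map):
            clan = cohort.clan_map[name]
            fh.write(f"{name}\t{clan}\t{cohort.clan_names.get(clan, '')}\n")
    with (out / "ko_descriptions.tsv").open("w", encoding="utf-8") as fh:
        fh.write("ko_number\tdescription\n")
        for ko in sorted(cohort.ko_descriptions):
            fh.write(f"{ko}\t{cohort.ko_descriptions[ko]}\n")
    with (out / "manifest.tsv").open("w", encoding="utf-8") as fh:
        fh.write("kind\tdomain\tko1\tko2\tgroup1\tgroup2\tstatus\n")
        for d, k1, k2, a, b in cohort.manifest.expected_translocations:
            fh.write(
                f"translocation\t{d}\t{k1}\t{k2}\t{','.join(sorted(a))}\t"
                f"{','.join(sorted(b))}\t\n"
            )
        for d, ko in cohort.manifest.expected_indels:
            fh.write(f"indel\t{d}\t{ko}\t\t\t\t\n")
        for d, ko in cohort.manifest.expected_mobile:
            fh.write(f"mobile\t{d}\t{ko}\t\t\t\t\n")
        for d, status in sorted(cohort.manifest.expected_duplications.items()):
            fh.write(f"duplication\t{d}\t\t\t\t\t{status}\n")


def read_clan_table(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read ``clans.tsv`` back: (domain -> clan id, clan id -> clan name)."""
    clan_map: dict[str, str] = {}
    clan_names: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            name, clan, cname = (line.rstrip("\n").split("\t") + ["", ""])[:3]
            clan_map[name] = clan
            if cname:
                clan_names[clan] = cname
    return clan_map, clan_names
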