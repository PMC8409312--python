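"""Mobile/translocation/indel/duplication calling against independent oracles."""

import itertools

import numpy as np
import pytest

from domevol.architectures import partition_ko
from domevol.datastore import KoMembers
from domevol.errors import ContractError
from domevol.events import (
    classify_indels,
    detect_translocations,
    duplication_calls,
    mobile_domains,
    per_ko_duplication_status,
    summarize_by_superfamily,
    superdomain_class,
    TranslocationEvent,
)
from domevol.ingest import Organism


def euk(org):
    return Organism(org, org, "Eukaryota", 1000)


def registry_for(orgs, superdomain="Eukaryota"):
    return {o: Organism(o, o, superdomain, 1) for o in orgs}


def ko_members(ko, per_org_sets):
    """per_org_sets: {org: [domain-set, ...]} -> KoMembers."""
    refseqs, orgs, sets = [], [], []
    for org in sorted(per_org_sets):
        for i, s in enumerate(per_org_sets[org]):
            refseqs.append(f"XP_{ko}_{org}_{i}")
            orgs.append(org)
            sets.append(frozenset(s))
    return KoMembers(ko, refseqs, orgs, sets)


def presence_members(ko, containing, lacking, domain="DX", base=("B1",)):
    per_org = {o: [set(base) | {domain}] for o in containing}
    per_org.update({o: [set(base)] for o in lacking})
    return ko_members(ko, per_org)


# ---------------------------------------------------------------------------
# mobility
# ---------------------------------------------------------------------------

class TestMobileDomains:
    def test_boundary_t9_a4_is_mobile(self):
        orgs = [f"o{i:02d}" for i in range(9)]
        items = partition_ko(presence_members("K00001", orgs[:4], orgs[4:]))
        rec = {r.domain_name: r for r in mobile_domains(items)}["DX"]
        assert rec.T_size == 9 and len(rec.A) == 4
        assert rec.is_mobile  # 4 <= 4 < 9 - 4

    def test_boundary_t8_a4_is_not_mobile(self):
        orgs = [f"o{i:02d}" for i in range(8)]
        items = partition_ko(presence_members("K00001", orgs[:4], orgs[4:]))
        rec = {r.domain_name: r for r in mobile_domains(items)}["DX"]
        assert not rec.is_mobile  # 4 < 8 - 4 fails

    def test_ambiguous_organism_excluded_by_default(self):
        orgs = [f"o{i:02d}" for i in range(10)]
        per_org = {o: [{"B1", "DX"}] for o in orgs[:4]}
        per_org.update({o: [{"B1"}] for o in orgs[4:9]})
        per_org[orgs[9]] = [{"B1", "DX"}, {"B1"}]  # both-pattern paralogs
        items = partition_ko(ko_members("K00001", per_org))
        rec = {r.domain_name: r for r in mobile_domains(items)}["DX"]
        assert rec.excluded == frozenset({orgs[9]})
        assert rec.A.isdisjoint(rec.B)
        assert rec.T_size == 9
        # policies reassign instead of excluding
        rec_a = {r.domain_name: r for r in mobile_domains(
            items, ambiguity_policy="to_A")}["DX"]
        assert orgs[9] in rec_a.A
        rec_b = {r.domain_name: r for r in mobile_domains(
            items, ambiguity_policy="to_B")}["DX"]
        assert orgs[9] in rec_b.B

    def test_mixed_ko_items_rejected(self):
        items1 = partition_ko(presence_members("K00001", ["o1"], ["o2"]))
        items2 = partition_ko(presence_members("K00002", ["o1"], ["o2"]))
        with pytest.raises(ContractError):
            mobile_domains(items1 + items2)

    def test_random_pattern_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        orgs = [f"o{i:02d}" for i in range(12)]
        domains = list("ABCDEFGH")
        for _ in range(50):
            per_org = {
                o: [{d for d in domains if rng.random() < 0.5} | {"base"}]
                for o in orgs
            }
            items = partition_ko(ko_members("K00001", per_org))
            got = {r.domain_name: r for r in mobile_domains(items)}
            for d in domains:
                A = {o for o in orgs if d in per_org[o][0]}
                B = set(orgs) - A
                t = len(A) + len(B)
                assert got[d].A == A and got[d].B == B
                assert got[d].is_mobile == (4 <= len(A) < t - 4)


# ---------------------------------------------------------------------------
# translocation vs indel
# ---------------------------------------------------------------------------

def mobile_pair(domain, ko1, ko2, a1, b1, a2, b2):
    """Two mobile records of one domain from explicit org groups."""
    items1 = partition_ko(presence_members(ko1, a1, b1, domain))
    items2 = partition_ko(presence_members(ko2, a2, b2, domain))
    return mobile_domains(items1) + mobile_domains(items2)


class TestTranslocations:
    def test_reciprocal_groups_found(self):
        orgs = [f"o{i:02d}" for i in range(10)]
        # perfect reciprocity: A1 = B2, A2 = B1 (5/5 split keeps both
        # KOs inside the mobility window, 4 <= 5 < 10 - 4)
        records = mobile_pair("DX", "K00001", "K00002",
                              orgs[:5], orgs[5:], orgs[5:], orgs[:5])
        events = detect_translocations(records, registry_for(orgs))
        assert len(events) == 1
        ev = events[0]
        assert ev.A_star == frozenset(orgs[:5])
        assert ev.B_star == frozenset(orgs[5:])
        assert ev.ko1 == "K00001" and ev.ko2 == "K00002"
        assert ev.class_label == "Eukaryota-Eukaryota"

    def test_small_reciprocal_group_is_indel_path(self):
        orgs = [f"o{i:02d}" for i in range(12)]
        # A1 has 4+ members but only 3 of them lie in B2
        a1 = orgs[:4]
        a2 = orgs[3:9]          # o03 contains the domain in both KOs
        records = mobile_pair("DX", "K00001", "K00002",
                              a1, orgs[4:], a2, orgs[:3] + orgs[9:])
        events = detect_translocations(records, registry_for(orgs))
        assert events == []
        indels = classify_indels(records, events, registry_for(orgs))
        assert {(e.domain_name, e.ko_number) for e in indels} == {
            ("DX", "K00001"), ("DX", "K00002")}

    def test_orientation_canonical_under_relabeling(self):
        orgs = [f"o{i:02d}" for i in range(10)]
        fwd = mobile_pair("DX", "K00001", "K00002",
                          orgs[:5], orgs[5:], orgs[5:], orgs[:5])
        rev = mobile_pair("DX", "K00002", "K00001",
                          orgs[5:], orgs[:5], orgs[:5], orgs[5:])
        ev_f = detect_translocations(fwd, registry_for(orgs))
        ev_r = detect_translocations(list(reversed(rev)), registry_for(orgs))
        assert ev_f == ev_r

    def test_domain_with_translocation_yields_no_indels(self):
        orgs = [f"o{i:02d}" for i in range(10)]
        records = mobile_pair("DX", "K00001", "K00002",
                              orgs[:5], orgs[5:], orgs[5:], orgs[:5])
        # a third KO where DX is mobile but reciprocates with neither
        extra = mobile_domains(partition_ko(
            presence_members("K00003", orgs[:5], orgs[5:], "DX")))
        all_records = records + extra
        events = detect_translocations(all_records, registry_for(orgs))
        indels = classify_indels(all_records, events, registry_for(orgs))
        assert [e for e in indels if e.domain_name == "DX"] == []

    def test_single_ko_mobile_domain_is_one_indel(self):
        orgs = [f"o{i:02d}" for i in range(9)]
        records = mobile_domains(partition_ko(
            presence_members("K00005", orgs[:4], orgs[4:], "DX")))
        indels = classify_indels(records, [], registry_for(orgs))
        assert len(indels) == 1
        assert indels[0].class_label == "Eukaryota-Eukaryota"


class TestSuperdomainClass:
    def test_shared_label(self):
        reg = {"hsa": euk("hsa"), "mmu": euk("mmu")}
        assert superdomain_class({"hsa", "mmu"}, reg) == "Eukaryota"

    def test_disagreement_is_mixed(self):
        reg = {"hsa": euk("hsa"), "eco": Organism("eco", "E. coli", "Bacteria", 511145)}
        assert superdomain_class({"hsa", "eco"}, reg) == "Mixed"

    def test_empty_set_rejected(self):
        with pytest.raises(ContractError):
            superdomain_class(set(), {})

    def test_unknown_org_rejected(self):
        with pytest.raises(LookupError):
            superdomain_class({"zzz"}, {"hsa": euk("hsa")})

    def test_permutation_invariant(self):
        reg = registry_for(["aaa", "bbb", "ccc"])
        for perm in itertools.permutations(["aaa", "bbb", "ccc"]):
            assert superdomain_class(list(perm), reg) == "Eukaryota"


# ---------------------------------------------------------------------------
# duplication
# ---------------------------------------------------------------------------

class TestDuplication:
    def test_constant_copy_number_is_nonduplicated(self):
        assert per_ko_duplication_status([2, 2, 2]) == "nonduplicated"

    def test_varying_copy_number_is_duplicated(self):
        assert per_ko_duplication_status([1, 2]) == "duplicated"

    def test_extreme_diff_called_globally(self):
        """One domain duplicated in every one of 30 KOs among 30
        single-KO background domains must be the only global call,
        matching an independent percentile computation."""
        from domevol.datastore import build_db
        from domevol.ingest import ProteinRecord
        from domevol.domains import DomainHit

        n_kos = 30
        registry = [euk("aaa"), euk("bbb")]
        proteins, hits, ko_map = [], [], {}
        domains = [f"Bg{i:02d}" for i in range(n_kos)] + ["Hot"]
        for k in range(n_kos):
            ko = f"K{k + 1:05d}"
            for oi, org in enumerate(("aaa", "bbb")):
                refseq = f"XP_{ko}_{org}"
                proteins.append(ProteinRecord(refseq, "g", org, 5000,
                                              isoform_group=refseq, is_longest=True))
                ko_map[refseq] = ko
                pos = 1
                # background domain for this KO: constant single copy
                bg = domains[k]
                hits.append(DomainHit(refseq, bg, "PF1", "9999.0",
                                      pos, pos + 40, 50.0, 1e-9))
                pos += 60
                # Hot: copy number varies between the two organisms
                for _ in range(1 + oi):
                    hits.append(DomainHit(refseq, "Hot", "PF2", "9999.0",
                                          pos, pos + 40, 60.0, 1e-9))
                    pos += 60
        db = build_db(registry, proteins, hits, ko_map,
                      {d: "9999.0" for d in domains})
        calls = {c.domain_name: c for c in duplication_calls(db)}
        assert calls["Hot"].diff == n_kos
        # independent oracle: percentile of |diff| over all 50 domains
        diffs = [calls[d].diff for d in domains]
        cutoff = np.percentile(np.abs(diffs), 99)
        assert calls["Hot"].diff >= cutoff
        assert calls["Hot"].global_status == "duplicated"
        for d in domains[:-1]:
            assert calls[d].global_status == "undetermined", d

    def test_cumsum_rank_rule_accepts_extreme(self):
        from domevol.events import duplication_cutoff
        diffs = [1] * 49 + [30]
        cut_emp = duplication_cutoff(diffs, 0.99, "empirical")
        cut_rank = duplication_cutoff(diffs, 0.99, "cumsum-rank")
        assert 30 >= cut_emp and 30 >= cut_rank


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def T(domain, clan, label="Eukaryota-Eukaryota"):
    return TranslocationEvent(domain, "K00001", "K00002",
                              frozenset({"a"}), frozenset({"b"}), label, clan)


class TestSummaries:
    def test_counts_grouped_and_sorted(self):
        events = [T("Ig_3", "0011.26"), T("ig", "0011.26"), T("I-set", "0011.26"),
                  T("SH3_1", "0010.21")]
        rows = summarize_by_superfamily(events)
        assert rows[0][:2] == ("Eukaryota-Eukaryota", "0011.26")
        assert rows[0][3] == 3 and rows[1][3] == 1

    def test_empty(self):
        assert summarize_by_superfamily([]) == []

    def test_total_conserved(self):
        rng = np.random.default_rng(3)
        events = [T(f"D{i}", f"C{rng.integers(4)}",
                    ["Eukaryota-Eukaryota", "Mixed-Mixed"][int(rng.integers(2))])
                  for i in range(37)]
        rows = summarize_by_superfamily(events)
        assert sum(r[3] for r in rows) == len(events)
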