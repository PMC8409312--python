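"""domevol — protein evolution through the lens of domain architectures.

Proteins are modelled as sets of Pfam domains; orthology comes from KEGG
Orthology (KO) groups.  Comparing domain-architecture variation within
and between KO groups yields calls of mobile domains, reciprocal
translocations, indels and duplications, classified by superdomain
taxonomy and summarized per Pfam clan.
"""

from .architectures import ArchitectureItem, gain_loss_patterns, partition_ko
from .config import RunConfig
from .datastore import BuildReport, EvoProDomDB, KoMembers, build_db
from .domains import (
    DomainContent,
    DomainHit,
    UNKNOWN_CLAN,
    domain_content,
    read_pfam_hits,
    resolve_putative,
    resolve_unique_putative,
)
from .errors import (
    ContractError,
    DataIntegrityError,
    DomevolError,
    FixtureSpecError,
    FormatError,
    UniquenessError,
)
from .events import (
    DuplicationCall,
    EventResults,
    IndelEvent,
    MobileDomainRecord,
    TranslocationEvent,
    call_events,
    classify_indels,
    detect_translocations,
    duplication_calls,
    mobile_domains,
    summarize_by_superfamily,
    superdomain_class,
    write_event_tables,
)
from .ingest import (
    KoalaAssignment,
    Organism,
    ProteinRecord,
    attach_ko_numbers,
    read_koala_assignments,
    read_organism_registry,
    read_protein_table,
    select_longest_isoform,
    select_unique_ko,
)
from .synthetic import (
    Cohort,
    FixtureSpec,
    Manifest,
    PlantedDuplication,
    PlantedIndel,
    PlantedTranslocation,
    ferm_c_fixture,
    generate_cohort,
    write_cohort,
)

__version__ = "0.1.0"


def build_cohort_db(cohort: Cohort, path=":memory:") -> EvoProDomDB:
    """Run the full ingest stage on an in-memory cohort and build the DB.

    Applies the unique-KO and longest-isoform filters exactly as the
    file-based pipeline does.
    """
    ko_map, _ = select_unique_ko(cohort.koala)
    longest = {rec.refseq_id: rec for rec in select_longest_isoform(cohort.proteins)}
    records = [longest.get(rec.refseq_id, rec) for rec in cohort.proteins]
    return build_db(
        registry=cohort.registry,
        proteins=records,
        hits=cohort.hits,
        ko_map=ko_map,
        clan_map=cohort.clan_map,
        ko_descriptions=cohort.ko_descriptions,
        clan_names=cohort.clan_names,
        path=path,
    )
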