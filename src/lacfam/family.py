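"""Gene-family identification from domain and similarity evidence.

The funnel mirrors the standard workflow for plant multigene families:
HMM domain hits (laccase Cu-oxidase profiles) at e <= 0.001, union with
protein-similarity hits against reference (Arabidopsis) laccases at
e <= 1e-5, collapse of isoforms to one representative per locus, then
verification that the representative carries the full three-domain
Cu-oxidase architecture. Surviving genes are named by chromosomal position.

All e-value thresholds are inclusive (<=).
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence

from .models import DomainHit, FamilyMember, GeneModel, SimilarityHit

#: the three Cu-oxidase domains characteristic of plant laccases
REQUIRED_DOMAINS = frozenset({"Cu_oxidase", "Cu_oxidase_2", "Cu_oxidase_3"})

DEFAULT_HMM_EVALUE = 1e-3
DEFAULT_SIM_EVALUE = 1e-5


def filter_hmm_candidates(hits: Iterable[DomainHit], cutoff: float = DEFAULT_HMM_EVALUE) -> set[str]:
    """Protein ids with at least one domain hit at e-value <= cutoff."""
    if cutoff <= 0:
        raise ValueError("e-value cutoff must be > 0")
    return {h.protein_id for h in hits if h.evalue <= cutoff}


def merge_similarity_candidates(
    hmm_set: set[str],
    sim_hits: Iterable[SimilarityHit],
    cutoff: float = DEFAULT_SIM_EVALUE,
) -> set[str]:
    """Union of the HMM candidates with query ids hitting a reference
    laccase at e-value <= cutoff."""
    if cutoff <= 0:
        raise ValueError("e-value cutoff must be > 0")
    return set(hmm_set) | {h.query_id for h in sim_hits if h.evalue <= cutoff}


def eliminate_redundancy(
    candidates: set[str],
    isoform_map: Mapping[str, str],
    proteome: Mapping[str, str],
) -> dict[str, str]:
    """Collapse candidate proteins to one representative per gene locus.

    The representative is the longest isoform; ties break lexicographically
    by protein id. Cross-locus near-identical copies are *kept* — they are
    the duplication signal, not redundancy.
    """
    by_gene: dict[str, list[str]] = defaultdict(list)
    for pid in sorted(candidates):
        gene = isoform_map.get(pid)
        if gene is None:
            raise ValueError(f"candidate protein {pid!r} has no gene mapping")
        if pid not in proteome:
            raise ValueError(f"candidate protein {pid!r} missing from proteome")
        by_gene[gene].append(pid)
    return {
        gene: min(pids, key=lambda p: (-len(proteome[p]), p))
        for gene, pids in by_gene.items()
    }


def verify_domain_architecture(
    reps: Mapping[str, str],
    hits: Iterable[DomainHit],
    required: frozenset[str] = REQUIRED_DOMAINS,
    cutoff: float = DEFAULT_HMM_EVALUE,
) -> set[str]:
    """Genes whose representative protein has a sub-cutoff hit for EVERY
    required domain."""
    if not required:
        raise ValueError("required domain set must be non-empty")
    domains_of: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.evalue <= cutoff:
            domains_of[h.protein_id].add(h.domain_name)
    return {gene for gene, rep in reps.items() if required <= domains_of[rep]}


def assign_family_names(
    members: set[str],
    models: Sequence[GeneModel],
    reps: Mapping[str, str],
    hits: Iterable[DomainHit] = (),
    prefix: str = "LAC",
    chromosome_order: Sequence[str] | None = None,
    unanchored: frozenset[str] = frozenset(),
    cutoff: float = DEFAULT_HMM_EVALUE,
) -> list[FamilyMember]:
    """Name members ``prefix``1..N by (chromosome rank, start).

    ``chromosome_order`` fixes the chromosome ranking (default: lexicographic
    over observed chromosomes). Chromosomes in ``unanchored`` (unplaced
    contigs) sort after every named chromosome, among themselves
    lexicographically. A member on a chromosome that is neither ranked nor
    marked unanchored is an error.
    """
    model_of = {m.gene_id: m for m in models}
    missing = members - model_of.keys()
    if missing:
        raise ValueError(f"members without gene models: {sorted(missing)}")
    if chromosome_order is None:
        chromosome_order = sorted(
            {model_of[g].chromosome for g in members} - set(unanchored)
        )
    rank = {c: i for i, c in enumerate(chromosome_order)}

    def key(gene_id: str):
        m = model_of[gene_id]
        if m.chromosome in rank:
            return (0, rank[m.chromosome], m.start, gene_id)
        if m.chromosome in unanchored:
            return (1, m.chromosome, m.start, gene_id)
        raise ValueError(
            f"{gene_id}: chromosome {m.chromosome!r} not in chromosome_order "
            "and not marked unanchored"
        )

    domains_of: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.evalue <= cutoff:
            domains_of[h.protein_id].add(h.domain_name)

    out = []
    for i, gene_id in enumerate(sorted(members, key=key), start=1):
        m = model_of[gene_id]
        rep = reps.get(gene_id, gene_id)
        out.append(
            FamilyMember(
                gene_id=gene_id,
                assigned_name=f"{prefix}{i}",
                representative_protein_id=rep,
                chromosome=m.chromosome,
                start=m.start,
                end=m.end,
                strand=m.strand,
                domains_present=frozenset(domains_of.get(rep, ())),
            )
        )
    return out


def identify_family(
    domain_hits: Sequence[DomainHit],
    sim_hits: Sequence[SimilarityHit],
    isoform_map: Mapping[str, str],
    proteome: Mapping[str, str],
    models: Sequence[GeneModel],
    hmm_evalue: float = DEFAULT_HMM_EVALUE,
    sim_evalue: float = DEFAULT_SIM_EVALUE,
    required: frozenset[str] = REQUIRED_DOMAINS,
    prefix: str = "LAC",
    chromosome_order: Sequence[str] | None = None,
    unanchored: frozenset[str] = frozenset(),
) -> list[FamilyMember]:
    """Run the whole identification funnel; convenience for the CLI."""
    cands = filter_hmm_candidates(domain_hits, hmm_evalue)
    cands = merge_similarity_candidates(cands, sim_hits, sim_evalue)
    reps = eliminate_redundancy(cands, isoform_map, proteome)
    verified = verify_domain_architecture(reps, domain_hits, required, hmm_evalue)
    return assign_family_names(
        verified, models, reps, domain_hits, prefix, chromosome_order, unanchored, hmm_evalue
    )
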