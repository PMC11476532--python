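"""Tandem/segmental duplication classification, collinear-block detection,
and cross-species ortholog bookkeeping.

Tandem rule: two family genes are tandem-linked iff they sit on the same
chromosome with at most ``max_intervening`` annotated genes (of any family)
strictly between them and the containing fragment — upstream gene start to
downstream gene end — spans at most ``window_bp``. Arrays are the connected
components of this relation.

Segmental rule: a non-tandem pair is segmental iff the global-alignment
coverage and similarity both strictly exceed 75%.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .models import GeneModel, GenePair, SimilarityHit

DEFAULT_MAX_INTERVENING = 5
DEFAULT_WINDOW_BP = 100_000
DEFAULT_MIN_COVERAGE = 0.75
DEFAULT_MIN_SIMILARITY = 0.75


# ---------------------------------------------------------------------------
# tandem arrays

class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def classify_tandem(
    members: set[str],
    all_genes: Sequence[GeneModel],
    max_intervening: int = DEFAULT_MAX_INTERVENING,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> dict[str, str]:
    """Map member gene id -> tandem array id ('TA1', 'TA2', ...).

    Genes in no array are absent from the map. Intervening genes are counted
    over ALL annotated genes in positional order; array ids are assigned in
    (chromosome, leftmost start) order.
    """
    model_of = {g.gene_id: g for g in all_genes}
    missing = members - model_of.keys()
    if missing:
        raise ValueError(f"members missing from gene annotation: {sorted(missing)}")

    uf = _UnionFind(members)
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in all_genes:
        by_chrom[g.chromosome].append(g)
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        ranks = {g.gene_id: i for i, g in enumerate(genes)}
        chrom_members = sorted((m for m in members if model_of[m].chromosome == chrom),
                               key=lambda m: ranks[m])
        for a, b in itertools.combinations(chrom_members, 2):
            ga, gb = model_of[a], model_of[b]
            if abs(ranks[a] - ranks[b]) - 1 > max_intervening:
                continue
            lo, hi = (ga, gb) if ga.start <= gb.start else (gb, ga)
            if hi.end - lo.start + 1 <= window_bp:
                uf.union(a, b)

    comps: dict[str, list[str]] = defaultdict(list)
    for m in members:
        comps[uf.find(m)].append(m)
    arrays = [sorted(v) for v in comps.values() if len(v) >= 2]
    arrays.sort(key=lambda arr: (model_of[arr[0]].chromosome,
                                 min(model_of[m].start for m in arr)))
    out: dict[str, str] = {}
    for i, arr in enumerate(arrays, start=1):
        for m in arr:
            out[m] = f"TA{i}"
    return out


# ---------------------------------------------------------------------------
# pairwise alignment statistics

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -1.0
    return a


def global_align_stats(a: str, b: str) -> tuple[float, float]:
    """(coverage, similarity) from a Needleman-Wunsch global alignment
    (BLOSUM62, gap open 10, extend 1).

    coverage: aligned span of the shorter sequence as a fraction of the
    longer one (for a global alignment, len(shorter)/len(longer)).
    similarity: identical columns / alignment columns, terminal-gap columns
    excluded.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    # trim terminal gap runs (columns where either row is a gap at an end)
    start = 0
    end = len(s1)
    while start < end and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols == 0:
        return (min(len(a), len(b)) / max(len(a), len(b)), 0.0)
    ident = sum(1 for k in range(start, end) if s1[k] == s2[k] and s1[k] != "-")
    coverage = min(len(a), len(b)) / max(len(a), len(b))
    return coverage, ident / cols


def classify_segmental(
    members: set[str],
    proteome: Mapping[str, str],
    tandem_map: Mapping[str, str] | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    blocks: Sequence["CollinearBlock"] | None = None,
) -> set[GenePair]:
    """Segmental pairs among ``members``: coverage AND similarity strictly
    above their thresholds, pair not tandem-linked.

    ``proteome`` maps member gene id -> representative protein sequence.
    ``tandem_map`` is the output of :func:`classify_tandem`; a pair sharing
    an array id is excluded. If ``blocks`` is given, pairs must additionally
    co-occur as anchors of one collinear block (MCScanX-like mode).
    """
    tandem_map = tandem_map or {}
    block_pairs: set[frozenset[str]] | None = None
    if blocks is not None:
        block_pairs = {frozenset(p) for blk in blocks for p in blk.anchors}
    out: set[GenePair] = set()
    for a, b in itertools.combinations(sorted(members), 2):
        ta, tb = tandem_map.get(a), tandem_map.get(b)
        if ta is not None and ta == tb:
            continue
        if block_pairs is not None and frozenset((a, b)) not in block_pairs:
            continue
        sa, sb = proteome[a], proteome[b]
        # length ratio bounds coverage: skip alignment when it cannot pass
        if min(len(sa), len(sb)) / max(len(sa), len(sb)) <= min_coverage:
            continue
        coverage, similarity = global_align_stats(sa, sb)
        if coverage > min_coverage and similarity > min_similarity:
            out.add(GenePair(a, b, "segmental", coverage, similarity))
    return out


# ---------------------------------------------------------------------------
# collinear blocks

@dataclass(frozen=True)
class Anchor:
    """A homologous gene pair with ordinal positions in both genomes."""

    gene_a: str
    gene_b: str
    chrom_a: str
    pos_a: int  # gene ordinal along chrom_a
    chrom_b: str
    pos_b: int


@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: tuple[tuple[str, str], ...]
    orientation: int  # +1 ascending, -1 descending in genome B
    score: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "score", len(self.anchors))


def _best_chain(anchors: list[Anchor], sign: int, max_gap: int) -> list[int]:
    """Longest strictly-monotone chain (ascending if sign=+1 in genome B,
    descending if -1) with inter-anchor gaps <= max_gap in both genomes.
    Ties break toward the lexicographically smallest index sequence over
    anchors sorted by (pos_a, pos_b, ids)."""
    n = len(anchors)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: (anchors[i].pos_a, anchors[i].pos_b,
                                            anchors[i].gene_a, anchors[i].gene_b))
    # best[idx] = (chain length, chain as tuple of sorted positions) ending at
    # sorted position idx
    best: list[tuple[int, tuple[int, ...]]] = [(1, (idx,)) for idx in range(n)]
    for idx_j in range(n):
        aj = anchors[order[idx_j]]
        for idx_i in range(idx_j):
            ai = anchors[order[idx_i]]
            if not (ai.pos_a < aj.pos_a and sign * ai.pos_b < sign * aj.pos_b):
                continue
            if aj.pos_a - ai.pos_a - 1 > max_gap or abs(aj.pos_b - ai.pos_b) - 1 > max_gap:
                continue
            cand = (best[idx_i][0] + 1, best[idx_i][1] + (idx_j,))
            if cand[0] > best[idx_j][0] or (
                cand[0] == best[idx_j][0] and cand[1] < best[idx_j][1]
            ):
                best[idx_j] = cand
    length = max(t[0] for t in best)
    chain = min(t[1] for t in best if t[0] == length)
    return [order[k] for k in chain]


def detect_collinear_blocks(
    anchors: Sequence[Anchor],
    min_anchors: int = 5,
    max_gap_genes: int = 25,
) -> list[CollinearBlock]:
    """Greedy extraction of maximal monotone anchor chains per chromosome
    pair (longest-increasing-chain DP, both orientations); chains shorter
    than ``min_anchors`` are discarded."""
    by_pair: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for a in anchors:
        by_pair[(a.chrom_a, a.chrom_b)].append(a)
    blocks: list[CollinearBlock] = []
    for (ca, cb), group in sorted(by_pair.items()):
        remaining = list(group)
        while True:
            cands = []
            for sign in (+1, -1):
                idxs = _best_chain(remaining, sign, max_gap_genes)
                cands.append((len(idxs), sign, idxs))
            cands.sort(key=lambda t: (-t[0], -t[1]))
            length, sign, idxs = cands[0]
            if length < min_anchors:
                break
            chain = [remaining[i] for i in idxs]
            blocks.append(
                CollinearBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=tuple((a.gene_a, a.gene_b) for a in chain),
                    orientation=sign,
                )
            )
            used = set(idxs)
            remaining = [a for i, a in enumerate(remaining) if i not in used]
    return blocks


# ---------------------------------------------------------------------------
# orthologs

def reciprocal_best_hits(
    sim_ab: Iterable[SimilarityHit],
    sim_ba: Iterable[SimilarityHit],
    evalue_cutoff: float = 1e-5,
) -> set[tuple[str, str]]:
    """(a, b) pairs where b is a's best hit and a is b's best hit, both at
    e <= cutoff. Ties: lower e-value, then higher identity, then
    lexicographic subject id."""

    def best(hits: Iterable[SimilarityHit]) -> dict[str, str]:
        per_query: dict[str, SimilarityHit] = {}
        for h in hits:
            if h.evalue > evalue_cutoff:
                continue
            cur = per_query.get(h.query_id)
            if cur is None or (h.evalue, -h.identity, h.subject_id) < (
                cur.evalue, -cur.identity, cur.subject_id
            ):
                per_query[h.query_id] = h
        return {q: h.subject_id for q, h in per_query.items()}

    ab, ba = best(sim_ab), best(sim_ba)
    return {(a, b) for a, b in ab.items() if ba.get(b) == a}


def ortholog_intersections(
    tables: Mapping[str, set[str]], exclusive: bool = True
) -> dict[tuple[str, ...], int]:
    """Counts of focal-genome genes per species subset.

    With ``exclusive=True`` (Venn-style), a gene is counted for the subset of
    species whose ortholog sets contain it and no other. With False, the
    count for each subset is plain |intersection| over its members.
    """
    if not tables:
        raise ValueError("at least one species required")
    species = sorted(tables)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(species) + 1):
        for subset in itertools.combinations(species, r):
            inter = set.intersection(*(tables[s] for s in subset))
            if exclusive:
                rest = set().union(*(tables[s] for s in species if s not in subset)) \
                    if len(subset) < len(species) else set()
                inter = inter - rest
            out[subset] = len(inter)
    return out
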