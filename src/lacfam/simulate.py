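"""Synthetic fixtures with planted, machine-readable ground truth.

Every downstream stage of the pipeline is testable without external data:
the generator emits a genome, gene models, a proteome, domain/similarity
evidence tables, stage-structured expression, metabolite profiles and
promoters with planted PWM sites — together with a truth object recording
exactly what was planted.

Construction guarantees (the truth IS the oracle):

* family genes carry all three Cu-oxidase domain signatures below the HMM
  cutoff; partial decoys carry only two (they enter the candidate funnel and
  fail architecture verification); plain decoys fail both evidence filters;
* planted tandem arrays satisfy the <=5-intervening-genes / 100-kb rule,
  while isolated genes are separated by more than the window;
* segmental partners are substitution-mutated copies (identity ~85%, full
  length), safely above the >75% / >75% criteria;
* planted gene-metabolite pairs follow the bivariate construction
  m = r * z_g + sqrt(1 - r^2) * eps, so the sample correlation converges to
  the target r;
* planted promoter sites are maximum-probability consensus draws written at
  recorded offsets and strands, never overlapping.

One RNG stream per fixture type, all derived from ``SimConfig.seed`` by
fixed stream offsets: adding one fixture never perturbs another's draws.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .models import DomainHit, GeneModel, SimilarityHit
from .pwm import BASES, Pwm, revcomp

AA = "ACDEFGHIKLMNPQRSTVWY"
_CLADE_TYPES = ("I", "II", "III", "IV", "V", "VI", "VII")

# fixed stream offsets (see module docstring)
_S_GENOME, _S_PLACE, _S_PROTEIN, _S_EVIDENCE, _S_EXPR, _S_METAB, _S_PROM, _S_PWM = range(8)


class CapacityError(ValueError):
    """Requested gene layout does not fit on the configured chromosomes."""


class SitePlacementError(ValueError):
    """Planted promoter sites could not be placed without overlap."""


def _stream(offset: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([offset, seed])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome/family fixture."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    n_family_genes: int = 20
    n_decoy_genes: int = 10
    tandem_arrays: tuple[tuple[int, int], ...] = ()  # (size, intra-array spacing bp)
    segmental_pairs: int = 0
    n_stages: int = 9
    n_metabolites: int = 20
    planted_correlations: tuple[tuple[int, int, float], ...] = ()
    planted_tf_sites: tuple[tuple[str, int, int], ...] = ()  # (pwm id, gene idx, count)
    # generator shape parameters
    gene_length_bp: int = 1_500
    isolation_gap_bp: int = 150_000
    n_redundant_loci: int = 0  # loci carrying a second, shorter isoform
    n_partial_decoys: int = 0  # decoys with 2 of 3 domains (fail verification only)
    segmental_sub_rate: float = 0.15
    protein_length_range: tuple[int, int] = (480, 600)
    type_sizes: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_family_genes": self.n_family_genes,
            "n_decoy_genes": self.n_decoy_genes,
            "segmental_pairs": self.segmental_pairs,
            "n_stages": self.n_stages,
            "n_metabolites": self.n_metabolites,
            "n_redundant_loci": self.n_redundant_loci,
            "n_partial_decoys": self.n_partial_decoys,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_chromosomes == 0 and (self.n_family_genes or self.n_decoy_genes):
            raise CapacityError("genes configured but no chromosomes")
        arr_total = sum(size for size, _ in self.tandem_arrays)
        if any(size < 2 for size, _ in self.tandem_arrays):
            raise ValueError("tandem arrays need at least 2 genes")
        if arr_total > self.n_family_genes:
            raise ValueError("sum of tandem array sizes exceeds n_family_genes")
        if 2 * self.segmental_pairs > self.n_family_genes - arr_total:
            raise ValueError("not enough isolated family genes for segmental pairs")
        for gi, mi, r in self.planted_correlations:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"target correlation out of [-1, 1]: {r}")
            if not 0 <= gi < self.n_family_genes:
                raise ValueError(f"planted correlation gene index out of range: {gi}")
            if not 0 <= mi < self.n_metabolites:
                raise ValueError(f"planted correlation metabolite index out of range: {mi}")
        if len({mi for _, mi, _ in self.planted_correlations}) != len(
            self.planted_correlations
        ):
            raise ValueError("each metabolite may carry at most one planted correlation")
        for _, gi, count in self.planted_tf_sites:
            if not 0 <= gi < self.n_family_genes:
                raise ValueError(f"planted TF site gene index out of range: {gi}")
            if count < 0:
                raise ValueError("site count must be >= 0")
        if self.n_partial_decoys > self.n_decoy_genes:
            raise ValueError("n_partial_decoys exceeds n_decoy_genes")
        if self.n_redundant_loci > self.n_family_genes + self.n_decoy_genes:
            raise ValueError("n_redundant_loci exceeds locus count")


@dataclass(frozen=True)
class PlantedSite:
    pwm_id: str
    gene_id: str
    offset: int  # 0-based within the promoter, gene orientation
    strand: str  # relative to the promoter


@dataclass
class SyntheticTruth:
    """Machine-readable record of everything the generator planted."""

    family_genes: list[str] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)
    partial_decoy_genes: list[str] = field(default_factory=list)
    tandem_membership: dict[str, str] = field(default_factory=dict)
    segmental_pairs: set[frozenset[str]] = field(default_factory=set)
    type_label: dict[str, str] = field(default_factory=dict)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    planted_correlations: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "family_genes": self.family_genes,
            "decoy_genes": self.decoy_genes,
            "partial_decoy_genes": self.partial_decoy_genes,
            "tandem_membership": self.tandem_membership,
            "segmental_pairs": sorted(sorted(p) for p in self.segmental_pairs),
            "type_label": self.type_label,
            "planted_sites": [dataclasses.asdict(s) for s in self.planted_sites],
            "planted_correlations": [list(t) for t in self.planted_correlations],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            family_genes=list(d["family_genes"]),
            decoy_genes=list(d["decoy_genes"]),
            partial_decoy_genes=list(d["partial_decoy_genes"]),
            tandem_membership=dict(d["tandem_membership"]),
            segmental_pairs={frozenset(p) for p in d["segmental_pairs"]},
            type_label=dict(d["type_label"]),
            planted_sites=[PlantedSite(**s) for s in d["planted_sites"]],
            planted_correlations=[tuple(t) for t in d["planted_correlations"]],
        )


@dataclass
class FamilyFixture:
    config: SimConfig
    genome: dict[str, str]
    models: list[GeneModel]
    proteome: dict[str, str]  # protein id -> sequence
    isoform_map: dict[str, str]  # protein id -> gene id
    domain_hits: list[DomainHit]
    similarity_hits: list[SimilarityHit]
    truth: SyntheticTruth

    @property
    def representative_seqs(self) -> dict[str, str]:
        """gene id -> sequence of its '.1' (primary) isoform."""
        return {
            gene: self.proteome[pid]
            for pid, gene in self.isoform_map.items()
            if pid.endswith(".1")
        }


def _random_dna(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return np.frombuffer(b"ACGT", dtype="S1")[codes].tobytes().decode("ascii")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 20, size=length)
    return "".join(AA[c] for c in codes)


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = AA.replace(out[i], "")
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _assign_types(cfg: SimConfig, family: list[str]) -> dict[str, str]:
    if cfg.type_sizes is not None:
        sizes = list(cfg.type_sizes)
        if sum(n for _, n in sizes) != len(family):
            raise ValueError("type_sizes must sum to n_family_genes")
        out: dict[str, str] = {}
        i = 0
        for label, n in sizes:
            for g in family[i : i + n]:
                out[g] = label
            i += n
        return out
    out = {}
    for i, g in enumerate(family):
        out[g] = "I" if i < min(2, len(family)) else _CLADE_TYPES[1 + (i - 2) % 6]
    return out


def build_family_fixture(cfg: SimConfig) -> FamilyFixture:
    """Genome + gene models + proteome + evidence tables + truth."""
    place_rng = _stream(_S_PLACE, cfg.seed)
    prot_rng = _stream(_S_PROTEIN, cfg.seed)
    ev_rng = _stream(_S_EVIDENCE, cfg.seed)

    chroms = [f"chr{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    cursors = {c: 0 for c in chroms}  # last used 1-based position

    # layout plan: arrays first, then shuffled singles (family + decoys)
    arr_total = sum(size for size, _ in cfg.tandem_arrays)
    n_single_family = cfg.n_family_genes - arr_total
    singles = ["family"] * n_single_family + ["decoy"] * cfg.n_decoy_genes
    place_rng.shuffle(singles)
    units: list[tuple[str, int, int]] = [
        ("array", size, spacing) for size, spacing in cfg.tandem_arrays
    ] + [(kind, 1, 0) for kind in singles]

    models: list[GeneModel] = []
    family: list[str] = []
    decoys: list[str] = []
    planted_arrays: list[list[str]] = []
    counter = 0

    for kind, size, spacing in units:
        gap = cfg.isolation_gap_bp + int(place_rng.integers(0, max(1, cfg.isolation_gap_bp // 4)))
        span = size * cfg.gene_length_bp + (size - 1) * spacing
        # greedy: chromosome with most remaining room, ties to the first
        target = max(
            chroms,
            key=lambda c: (cfg.chrom_length_bp - cursors[c], -chroms.index(c)),
            default=None,
        )
        if target is None or cursors[target] + gap + span > cfg.chrom_length_bp:
            raise CapacityError(
                f"cannot place a unit of {size} gene(s): chromosomes are full "
                f"(chrom_length_bp={cfg.chrom_length_bp})"
            )
        pos = cursors[target] + gap + 1  # 1-based start
        ids_here = []
        for k in range(size):
            counter += 1
            gid = f"g{counter:04d}"
            start = pos + k * (cfg.gene_length_bp + spacing)
            end = start + cfg.gene_length_bp - 1
            strand = "+" if place_rng.random() < 0.5 else "-"
            models.append(GeneModel(gid, target, start, end, strand))
            ids_here.append(gid)
        cursors[target] = models[-1].end
        if kind == "array":
            planted_arrays.append(ids_here)
            family.extend(ids_here)
        elif kind == "family":
            family.extend(ids_here)
        else:
            decoys.extend(ids_here)

    genome_rng = _stream(_S_GENOME, cfg.seed)
    genome = {c: _random_dna(genome_rng, cfg.chrom_length_bp) for c in chroms}

    # proteome (placement order keeps draws deterministic)
    lo, hi = cfg.protein_length_range
    proteome: dict[str, str] = {}
    isoform_map: dict[str, str] = {}
    model_order = sorted(models, key=lambda m: m.gene_id)
    for m in model_order:
        pid = f"{m.gene_id}.1"
        proteome[pid] = _random_protein(prot_rng, int(prot_rng.integers(lo, hi + 1)))
        isoform_map[pid] = m.gene_id

    # segmental partners: mutate copies of isolated family genes
    family_set = set(family)
    arrayed = {g for arr in planted_arrays for g in arr}
    isolated = [g for g in family if g not in arrayed]
    seg_pairs: set[frozenset[str]] = set()
    pick = place_rng.permutation(len(isolated))
    for p in range(cfg.segmental_pairs):
        a = isolated[pick[2 * p]]
        b = isolated[pick[2 * p + 1]]
        proteome[f"{b}.1"] = _mutate_protein(prot_rng, proteome[f"{a}.1"], cfg.segmental_sub_rate)
        seg_pairs.add(frozenset((a, b)))

    # extra isoforms (shorter truncations) at some loci
    all_loci = family + decoys
    if cfg.n_redundant_loci:
        idx = place_rng.choice(len(all_loci), size=cfg.n_redundant_loci, replace=False)
        for i in sorted(idx):
            gene = all_loci[i]
            rep = proteome[f"{gene}.1"]
            pid = f"{gene}.2"
            proteome[pid] = rep[: max(50, int(0.7 * len(rep)))]
            isoform_map[pid] = gene

    # evidence tables
    partial = decoys[: cfg.n_partial_decoys]
    plain = decoys[cfg.n_partial_decoys :]
    domain_hits: list[DomainHit] = []
    sim_hits: list[SimilarityHit] = []
    domains = ("Cu_oxidase", "Cu_oxidase_2", "Cu_oxidase_3")

    def domain_rows(pid: str, names: Sequence[str], low: bool) -> None:
        n = len(proteome[pid])
        third = max(1, n // 3)
        for j, d in enumerate(names):
            ev = 10.0 ** ev_rng.uniform(-30, -4) if low else 10.0 ** ev_rng.uniform(-2.4, 0)
            s = 1 + j * third
            domain_hits.append(DomainHit(pid, d, float(ev), s, min(n, s + third - 1)))

    for gene in sorted(family):
        for pid in (p for p, g in isoform_map.items() if g == gene):
            domain_rows(pid, domains, low=True)
            sim_hits.append(
                SimilarityHit(
                    query_id=pid,
                    subject_id=f"AtLAC{1 + int(ev_rng.integers(0, 17))}",
                    evalue=float(10.0 ** ev_rng.uniform(-50, -6)),
                    identity=float(ev_rng.uniform(0.4, 0.8)),
                    aln_len=len(proteome[pid]),
                    query_coverage=float(ev_rng.uniform(0.8, 1.0)),
                )
            )
    for gene in sorted(partial):
        for pid in (p for p, g in isoform_map.items() if g == gene):
            domain_rows(pid, domains[:2], low=True)
    for gene in sorted(plain):
        for pid in (p for p, g in isoform_map.items() if g == gene):
            if ev_rng.random() < 0.5:
                domain_rows(pid, domains[:1], low=False)

    # truth: array ids follow (chromosome, leftmost start) order, matching
    # the classifier's convention
    model_of = {m.gene_id: m for m in models}
    planted_arrays.sort(
        key=lambda arr: (model_of[arr[0]].chromosome, min(model_of[g].start for g in arr))
    )
    tandem_membership = {
        g: f"TA{i}" for i, arr in enumerate(planted_arrays, start=1) for g in arr
    }

    truth = SyntheticTruth(
        family_genes=sorted(family_set),
        decoy_genes=sorted(plain),
        partial_decoy_genes=sorted(partial),
        tandem_membership=tandem_membership,
        segmental_pairs=seg_pairs,
        type_label=_assign_types(cfg, sorted(family_set)),
        planted_correlations=[],
    )
    return FamilyFixture(
        config=cfg,
        genome=genome,
        models=models,
        proteome=proteome,
        isoform_map=isoform_map,
        domain_hits=domain_hits,
        similarity_hits=sim_hits,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# expression / metabolites

@dataclass
class ExpressionFixture:
    values: pd.DataFrame  # genes x samples (FPKM)
    samples: pd.DataFrame  # index sample; columns stage, replicate, year
    profiles: pd.DataFrame  # noiseless genes x stages
    peak_class: dict[str, str]  # planted 'pre' / 'post'
    low_mean_genes: set[str]
    veraison_index: int

    @property
    def stage_of(self) -> dict[str, int]:
        return self.samples["stage"].to_dict()


def build_expression_fixture(
    genes: Sequence[str] | SyntheticTruth,
    n_stages: int,
    veraison_index: int,
    seed: int,
    n_replicates: int = 3,
    n_years: int = 1,
    low_fraction: float = 0.2,
    noise_sd: float = 0.25,
    base_fpkm: float = 30.0,
) -> ExpressionFixture:
    """Stage-structured FPKM with planted pre-/post-véraison peaks.

    Each gene gets a Gaussian-bump stage profile whose peak falls before
    (early, 'pre') or at/after (late, 'post') the véraison stage, scaled to
    a target mean; an exact ``low_fraction`` share of genes is scaled to
    mean FPKM < 1 to exercise the expression filter. Noise is multiplicative
    log-normal with sd ``noise_sd`` (0 = deterministic profiles).
    """
    if isinstance(genes, SyntheticTruth):
        genes = genes.family_genes
    genes = list(genes)
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    if not 1 <= veraison_index <= n_stages:
        raise ValueError("veraison index must lie in [1, n_stages]")
    rng = _stream(_S_EXPR, seed)
    stages = np.arange(1, n_stages + 1)
    sigma = max(1.0, n_stages / 6.0)

    n_low = int(round(low_fraction * len(genes)))
    low_idx = set(rng.choice(len(genes), size=n_low, replace=False)) if n_low else set()

    profiles = {}
    peak_class = {}
    for i, g in enumerate(genes):
        early_possible = veraison_index > 1
        is_early = early_possible and rng.random() < 0.5
        if is_early:
            peak = int(rng.integers(1, veraison_index))
        else:
            peak = int(rng.integers(veraison_index, n_stages + 1))
        shape = np.exp(-((stages - peak) ** 2) / (2 * sigma**2))
        shape = shape / shape.mean()
        if i in low_idx:
            target_mean = float(rng.uniform(0.1, 0.5))
        else:
            target_mean = float(base_fpkm * rng.lognormal(0.0, 0.4))
        profiles[g] = shape * target_mean
        peak_class[g] = "pre" if peak < veraison_index else "post"
    prof = pd.DataFrame.from_dict(profiles, orient="index", columns=stages)
    prof.index.name = "gene"

    cols = []
    ann = []
    for y in range(1, n_years + 1):
        for s in stages:
            for r in range(1, n_replicates + 1):
                name = f"Y{y}S{s:02d}R{r}"
                cols.append(name)
                ann.append({"sample": name, "stage": int(s), "replicate": r, "year": y})
    values = np.zeros((len(genes), len(cols)))
    for j, a in enumerate(ann):
        values[:, j] = prof[a["stage"]].values
    if noise_sd > 0:
        values = values * rng.lognormal(0.0, noise_sd, size=values.shape)
    vdf = pd.DataFrame(values, index=prof.index, columns=cols)
    sdf = pd.DataFrame(ann).set_index("sample")
    return ExpressionFixture(
        values=vdf,
        samples=sdf,
        profiles=prof,
        peak_class=peak_class,
        low_mean_genes={genes[i] for i in low_idx},
        veraison_index=veraison_index,
    )


def build_metabolite_fixture(
    expr: pd.DataFrame,
    planted: Sequence[tuple[str | int, int, float]],
    n_metabolites: int,
    seed: int,
    scale: float = 100.0,
    spread: float = 20.0,
    noise: bool = True,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Metabolite x sample abundances with planted gene correlations.

    ``planted`` entries are (gene id or row index, metabolite index, target
    r). The planted profile is m = r * z_g + sqrt(1-r^2) * eps mapped
    affinely to the abundance scale; with ``noise=False`` and |r| = 1 the
    metabolite is an exact affine image of the gene profile. Returns the
    matrix and the resolved (gene_id, metabolite_id, r) list.
    """
    rng = _stream(_S_METAB, seed)
    n = expr.shape[1]
    metab_ids = [f"M{i + 1:03d}" for i in range(n_metabolites)]
    data = rng.standard_normal((n_metabolites, n))
    resolved = []
    for gene, mi, r in planted:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target correlation out of [-1, 1]: {r}")
        if not 0 <= mi < n_metabolites:
            raise ValueError(f"metabolite index out of range: {mi}")
        gid = expr.index[gene] if isinstance(gene, (int, np.integer)) else gene
        if gid not in expr.index:
            raise ValueError(f"planted gene {gid!r} absent from expression matrix")
        row = expr.loc[gid].to_numpy(dtype=float)
        sd = row.std(ddof=1)
        if sd == 0:
            raise ValueError(f"planted gene {gid!r} has a constant profile")
        z = (row - row.mean()) / sd
        eps = data[mi] if noise else np.zeros(n)
        data[mi] = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        resolved.append((gid, metab_ids[mi], float(r)))
    return (
        pd.DataFrame(scale + spread * data, index=metab_ids, columns=expr.columns),
        resolved,
    )


# ---------------------------------------------------------------------------
# promoters

def random_pwm(
    motif_id: str,
    width: int,
    rng: np.random.Generator,
    dominant: float = 0.85,
    background: np.ndarray | None = None,
) -> Pwm:
    """Information-rich PWM: one dominant base per column."""
    probs = np.full((width, 4), (1.0 - dominant) / 3.0)
    for i in range(width):
        probs[i, int(rng.integers(0, 4))] = dominant
    bg = background if background is not None else np.full(4, 0.25)
    return Pwm(motif_id=motif_id, probs=probs, background=bg)


def build_promoter_fixture(
    pwms: Sequence[Pwm],
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    truth: SyntheticTruth,
    seed: int,
    sites: Sequence[tuple[str, str | int, int]] | None = None,
    upstream_bp: int = 2000,
) -> dict[str, str]:
    """Plant consensus PWM sites in promoter windows; returns a new genome.

    ``sites`` entries are (pwm id, gene id or family-gene index, count);
    defaults to nothing. Placements are non-overlapping within each
    promoter; offsets and strands are recorded in ``truth.planted_sites``.
    """
    rng = _stream(_S_PROM, seed)
    pwm_of = {p.motif_id: p for p in pwms}
    model_of = {m.gene_id: m for m in models}
    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    occupied: dict[str, list[tuple[int, int]]] = {}

    for pwm_id, gene, count in sites or ():
        if pwm_id not in pwm_of:
            raise ValueError(f"unknown PWM id {pwm_id!r}")
        gid = truth.family_genes[gene] if isinstance(gene, (int, np.integer)) else gene
        if gid not in model_of:
            raise ValueError(f"planted site gene {gid!r} has no model")
        m = model_of[gid]
        pwm = pwm_of[pwm_id]
        w = pwm.width
        chrom_len = len(genome[m.chromosome])
        win = min(upstream_bp, m.start - 1) if m.strand == "+" else min(
            upstream_bp, chrom_len - m.end
        )
        if win < w:
            raise SitePlacementError(f"promoter of {gid} shorter than motif {pwm_id}")
        for _ in range(count):
            placed = False
            for _try in range(200):
                off = int(rng.integers(0, win - w + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                taken = occupied.setdefault(gid, [])
                if any(off < e and o < off + w for o, e in taken):
                    continue
                site = pwm.consensus() if strand == "+" else revcomp(pwm.consensus())
                if m.strand == "+":
                    g0 = (m.start - 1) - win + off  # 0-based genome offset
                    mutable[m.chromosome][g0 : g0 + w] = site.encode("ascii")
                else:
                    g0 = m.end + win - w - off
                    mutable[m.chromosome][g0 : g0 + w] = revcomp(site).encode("ascii")
                taken.append((off, off + w))
                truth.planted_sites.append(PlantedSite(pwm_id, gid, off, strand))
                placed = True
                break
            if not placed:
                raise SitePlacementError(
                    f"could not place a non-overlapping {pwm_id} site in {gid}'s promoter"
                )
    truth.planted_sites.sort(key=lambda s: (s.gene_id, s.offset, s.pwm_id))
    return {c: b.decode("ascii") for c, b in mutable.items()}


# ---------------------------------------------------------------------------
# clade-structured trees

def build_clade_tree(
    members_by_type: Mapping[str, Sequence[str]],
    n_anchors: Mapping[str, int],
    stem: float = 1.0,
    tip_len: float = 0.1,
    internal_len: float = 0.05,
) -> tuple[str, dict[str, str]]:
    """Newick tree with one balanced clade per type, anchors included.

    Each type's clade hangs off a central polytomy on a long stem, so clade
    depths (~``tip_len`` + log2(size) * ``internal_len``) stay well below the
    stem and midpoint rooting lands between clades, never inside one. Two
    anchors (named ``<type>_anchor<i>``) are placed at the extremes of each
    anchored clade's leaf order, making their LCA span the whole clade.
    Returns (newick, anchor name -> type label).
    """

    def bal(leaves: Sequence[str]) -> str:
        if len(leaves) == 1:
            return f"{leaves[0]}:{tip_len}"
        mid = len(leaves) // 2
        return f"({bal(leaves[:mid])},{bal(leaves[mid:])}):{internal_len}"

    anchors: dict[str, str] = {}
    clades = []
    for label in members_by_type:
        leaves = list(members_by_type[label])
        k = n_anchors.get(label, 0)
        names = [f"{label}_anchor{i + 1}" for i in range(k)]
        for nm in names:
            anchors[nm] = label
        if k >= 2:
            leaves = [names[0]] + names[2:] + leaves + [names[1]]
        elif k == 1:
            leaves = [names[0]] + leaves
        if not leaves:
            continue
        sub = bal(leaves)
        # re-root the clade on its stem
        if sub.endswith(f":{internal_len}"):
            sub = sub[: -len(f":{internal_len}")] + f":{stem}"
        else:  # single leaf clade
            sub = f"({sub}):{stem}"
        clades.append(sub)
    if len(clades) < 2:
        raise ValueError("need at least two clades")
    return "(" + ",".join(clades) + ");", anchors


# ---------------------------------------------------------------------------
# persistence & validation

def write_fixture(fix: FamilyFixture, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lio.write_fasta(fix.genome, out / "genome.fasta")
    lio.write_fasta(fix.proteome, out / "proteome.fasta")
    lio.write_gff3(
        fix.models, out / "genes.gff3",
        chrom_lengths={c: len(s) for c, s in fix.genome.items()},
    )
    lio.write_domain_hits(fix.domain_hits, out / "domain_hits.tsv")
    lio.write_similarity_hits(fix.similarity_hits, out / "similarity_hits.tsv")
    pd.DataFrame(
        sorted(fix.isoform_map.items()), columns=["protein_id", "gene_id"]
    ).to_csv(out / "isoforms.tsv", sep="\t", index=False)
    lio.write_json(fix.truth.to_dict(), out / "truth.json")


def validate_fixture(fix: FamilyFixture) -> None:
    """Truth-consistency check: every id the truth references resolves
    against the emitted models/genome/proteome."""
    gene_ids = {m.gene_id for m in fix.models}
    t = fix.truth
    referenced = (
        set(t.family_genes)
        | set(t.decoy_genes)
        | set(t.partial_decoy_genes)
        | set(t.tandem_membership)
        | {g for p in t.segmental_pairs for g in p}
        | set(t.type_label)
        | {s.gene_id for s in t.planted_sites}
    )
    dangling = referenced - gene_ids
    if dangling:
        raise ValueError(f"truth references unknown genes: {sorted(dangling)}")
    for m in fix.models:
        if m.chromosome not in fix.genome:
            raise ValueError(f"{m.gene_id}: chromosome {m.chromosome} missing from genome")
        if m.end > len(fix.genome[m.chromosome]):
            raise ValueError(f"{m.gene_id}: extends past its chromosome")
    for pid, gene in fix.isoform_map.items():
        if pid not in fix.proteome:
            raise ValueError(f"isoform map references unknown protein {pid}")
        if gene not in gene_ids:
            raise ValueError(f"isoform map references unknown gene {gene}")
    for s in t.planted_sites:
        if s.offset < 0:
            raise ValueError("planted site with negative offset")
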