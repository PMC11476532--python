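"""File formats: FASTA, gene-only GFF3, evidence/matrix TSVs, MEME-minimal
motifs, truth JSON.

Coordinates in GFF3 are 1-based closed and are stored as such on
:class:`~lacfam.models.GeneModel`. All writers emit rows in a deterministic
order so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import DomainHit, FamilyMember, GeneModel, MotifHit, SimilarityHit
from .pwm import BASES, Pwm

# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, sort: bool = True) -> None:
    ids = sorted(seqs) if sort else list(seqs)
    records = [SeqRecord(Seq(seqs[i]), id=i, description="") for i in ids]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (gene features with ID= attributes)

def read_gff3(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].rstrip(";").split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise ValueError(f"gene feature without ID attribute: {line!r}")
            models.append(
                GeneModel(
                    gene_id=attrs["ID"],
                    chromosome=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return models


def write_gff3(
    models: Sequence[GeneModel],
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom in sorted(chrom_lengths):
                fh.write(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}\n")
        for m in sorted(models, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{m.chromosome}\tlacfam\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# evidence tables

_DOMAIN_COLS = ["protein_id", "domain_name", "evalue", "ali_start", "ali_end"]
_SIM_COLS = ["query", "subject", "evalue", "identity", "aln_len", "qcov"]


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        DomainHit(r.protein_id, r.domain_name, float(r.evalue), int(r.ali_start), int(r.ali_end))
        for r in df.itertuples()
    ]


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    rows = sorted(
        ((h.protein_id, h.domain_name, h.evalue, h.ali_start, h.ali_end) for h in hits)
    )
    pd.DataFrame(rows, columns=_DOMAIN_COLS).to_csv(path, sep="\t", index=False)


def read_similarity_hits(path: str | Path) -> list[SimilarityHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        SimilarityHit(r.query, r.subject, float(r.evalue), float(r.identity),
                      int(r.aln_len), float(r.qcov))
        for r in df.itertuples()
    ]


def write_similarity_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    rows = sorted(
        (h.query_id, h.subject_id, h.evalue, h.identity, h.aln_len, h.query_coverage)
        for h in hits
    )
    pd.DataFrame(rows, columns=_SIM_COLS).to_csv(path, sep="\t", index=False)


def write_members(members: Sequence[FamilyMember], path: str | Path) -> None:
    rows = [
        {
            "gene_id": m.gene_id,
            "assigned_name": m.assigned_name,
            "chromosome": m.chromosome,
            "start": m.start,
            "end": m.end,
            "strand": m.strand,
            "representative_protein_id": m.representative_protein_id,
            "domains": ",".join(sorted(m.domains_present)),
        }
        for m in members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_members(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# matrices

def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Sidecar table: sample, stage, replicate, year."""
    return pd.read_csv(path, sep="\t").set_index("sample")


def write_motif_hits(hits: Sequence[MotifHit], path: str | Path) -> None:
    rows = [
        {
            "motif": h.motif_id,
            "gene": h.gene_id,
            "offset": h.offset,
            "strand": h.strand,
            "score_bits": h.score_bits,
            "pvalue": h.pvalue,
        }
        for h in hits
    ]
    pd.DataFrame(
        rows, columns=["motif", "gene", "offset", "strand", "score_bits", "pvalue"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format

def write_meme(pwms: Sequence[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(BASES, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in p.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path, pseudocount: float = 0.1) -> list[Pwm]:
    with open(path) as fh:
        records = motifs.parse(fh, "minimal")
    out = []
    for m in records:
        probs = np.array([[m.pwm[b][i] for b in BASES] for i in range(m.length)])
        bg = np.array([m.background[b] for b in BASES])
        out.append(Pwm(motif_id=m.name, probs=probs, background=bg, pseudocount=pseudocount))
    return out


# ---------------------------------------------------------------------------
# JSON

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
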