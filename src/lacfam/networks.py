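"""Promoter extraction, gene-metabolite correlation networks, and the
TF -> target regulatory network from promoter motif hits.

Correlation edges carry the Pearson coefficient over matched samples and a
two-sided p-value from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
freedom. The correlation network keeps edges with |r| above a threshold and
p below a cap; node weight is the degree (connectivity). The TF network
draws an edge TF -> gene when at least one promoter hit survives, weighs it
by -log10 of the best hit p-value, and weighs nodes by the mean of incident
edge weights ("average node weight").
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .models import CorrelationEdge, GeneModel, MotifHit, Promoter
from .pwm import revcomp

DEFAULT_UPSTREAM_BP = 2000


def extract_promoters(
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
) -> dict[str, Promoter]:
    """Upstream regions, 5'->3' relative to each gene.

    '+' gene starting at s (1-based): bases [max(1, s - upstream_bp), s - 1].
    '-' gene ending at e: reverse complement of [e + 1, min(L, e + upstream_bp)].
    Windows clamped at chromosome edges are flagged ``truncated``.
    """
    out: dict[str, Promoter] = {}
    for m in models:
        if m.chromosome not in genome:
            raise ValueError(f"{m.gene_id}: chromosome {m.chromosome!r} not in genome")
        chrom = genome[m.chromosome]
        L = len(chrom)
        if m.strand == "+":
            lo1 = max(1, m.start - upstream_bp)  # 1-based inclusive
            seq = chrom[lo1 - 1 : m.start - 1]
            truncated = m.start - upstream_bp < 1
        else:
            hi1 = min(L, m.end + upstream_bp)
            seq = revcomp(chrom[m.end : hi1])
            truncated = m.end + upstream_bp > L
        out[m.gene_id] = Promoter(gene_id=m.gene_id, sequence=seq, truncated=truncated)
    return out


def gene_metabolite_correlation(
    expr: pd.DataFrame, metab: pd.DataFrame
) -> list[CorrelationEdge]:
    """Pearson r and two-sided p for every (gene, metabolite) pair over
    matched sample columns. Constant rows are dropped with a warning."""
    unmatched = sorted(set(expr.columns) ^ set(metab.columns))
    if unmatched:
        raise ValueError(f"unmatched sample columns: {unmatched}")
    cols = list(expr.columns)
    n = len(cols)
    if n < 3:
        raise ValueError("need at least 3 matched samples")
    me = metab[cols]

    def standardize(df: pd.DataFrame, kind: str) -> pd.DataFrame:
        sd = df.std(axis=1, ddof=1)
        const = sd == 0
        if const.any():
            warnings.warn(
                f"dropping {int(const.sum())} constant {kind} row(s): "
                f"{list(df.index[const])}",
                stacklevel=2,
            )
            df = df.loc[~const]
            sd = sd[~const]
        return df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)

    zg = standardize(expr, "gene")
    zm = standardize(me, "metabolite")
    r = zg.values @ zm.values.T / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    edges = []
    for i, g in enumerate(zg.index):
        for j, mmet in enumerate(zm.index):
            edges.append(CorrelationEdge(g, mmet, float(r[i, j]), float(min(p[i, j], 1.0))))
    return edges


def build_correlation_network(
    edges: Iterable[CorrelationEdge],
    min_abs_r: float = 0.8,
    max_p: float = 0.05,
) -> nx.Graph:
    """Thresholded gene-metabolite network.

    Edge attributes: weight = |r|, r, sign, pvalue. Node attributes: kind
    ('gene'/'metabolite'), weight = degree. Isolated nodes never appear.
    """
    if not 0 <= min_abs_r <= 1:
        raise ValueError("min_abs_r must be in [0, 1]")
    g = nx.Graph()
    for e in edges:
        if abs(e.r) >= min_abs_r and e.pvalue <= max_p:
            g.add_node(e.gene_id, kind="gene")
            g.add_node(e.metabolite_id, kind="metabolite")
            g.add_edge(
                e.gene_id,
                e.metabolite_id,
                weight=abs(e.r),
                r=e.r,
                sign=1 if e.r >= 0 else -1,
                pvalue=e.pvalue,
            )
    for node in g.nodes:
        g.nodes[node]["weight"] = g.degree[node]
    return g


def build_tf_network(
    hits: Iterable[MotifHit],
    motif_to_tf: Mapping[str, str],
    tf_filter: set[str] | None = None,
) -> nx.DiGraph:
    """TF -> target network from promoter motif hits.

    Edge weight is -log10 of the best (smallest) p-value among the pair's
    hits; ``tf_filter``, when given, keeps only those TFs (e.g. the
    differentially expressed ones). Node weight is the mean of incident edge
    weights.
    """
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.motif_id not in motif_to_tf:
            raise ValueError(f"motif {h.motif_id!r} has no TF mapping")
        tf = motif_to_tf[h.motif_id]
        if tf_filter is not None and tf not in tf_filter:
            continue
        key = (tf, h.gene_id)
        if key not in best or h.pvalue < best[key]:
            best[key] = h.pvalue
    g = nx.DiGraph()
    for (tf, target), p in sorted(best.items()):
        w = -math.log10(max(p, 1e-300))
        g.add_node(tf, kind="TF")
        g.add_node(target, kind="gene")
        g.add_edge(tf, target, weight=w, pvalue=p)
    und = g.to_undirected(as_view=True)
    for node in g.nodes:
        ws = [und.edges[e]["weight"] for e in und.edges(node)]
        g.nodes[node]["weight"] = float(np.mean(ws)) if ws else 0.0
    return g


def edges_table(g: nx.Graph) -> pd.DataFrame:
    """Flat edge table (source, target, weight, + extra attributes)."""
    rows = []
    for u, v, data in g.edges(data=True):
        rows.append({"source": u, "target": v, **data})
    return pd.DataFrame(rows)
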