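"""Position weight matrices: log-odds scoring, exact p-values, promoter scanning.

Scoring follows the FIMO convention: a position probability matrix (PPM) over
{A, C, G, T} is converted to a log-odds matrix in bits against a background
base composition, with a pseudocount spread proportionally to the background:

    score(i, b) = log2( (p_ib + c * bg_b) / ((1 + c) * bg_b) )

Site significance is the exact p-value of the observed score under the
background model, obtained by position-wise dynamic programming over a
discretised score lattice. On the lattice the DP is exact: it agrees with
brute-force enumeration of all 4^w words.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import MotifHit

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: byte-level lookup: A->0 C->1 G->2 T->3, everything else -> 4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Pwm:
    """Position probability matrix with background and pseudocount.

    ``probs`` has shape (width, 4) in A, C, G, T order; each row sums to 1.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be a (width, 4) matrix with width >= 1")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM column must sum to 1 (+-1e-6)")
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


def pwm_log_odds(pwm: Pwm) -> np.ndarray:
    """Per-position log-odds score table in bits, shape (width, 4)."""
    if np.any(pwm.background <= 0):
        raise ValueError("background probabilities must be strictly positive")
    c = pwm.pseudocount
    return np.log2((pwm.probs + c * pwm.background) / ((1.0 + c) * pwm.background))


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact lattice distribution of PWM scores under the background model.

    Scores are rounded to multiples of ``granularity`` (bits). ``survival[k]``
    is P(lattice score >= kmin + k); p-values are therefore non-increasing
    in the score and total probability mass is conserved.
    """

    granularity: float
    kmin: int
    survival: np.ndarray
    lattice: np.ndarray  # integer log-odds table, shape (width, 4)

    def pvalue_of_lattice(self, k: int) -> float:
        idx = k - self.kmin
        if idx < 0:
            return 1.0
        if idx >= len(self.survival):
            return 0.0
        return float(self.survival[idx])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_of_lattice(int(round(score_bits / self.granularity)))


def pwm_exact_pvalues(
    pwm: Pwm, granularity: float = 1e-3, max_width: int = 30
) -> ScoreDistribution:
    """Exact score -> p-value map by position-wise convolution.

    The log-odds table is rounded to the ``granularity`` lattice; the exact
    distribution of the lattice score of a background-generated word is then
    a w-fold convolution of 4-point distributions, done in O(w * range).
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    if pwm.width > max_width:
        raise ValueError(f"PWM width {pwm.width} exceeds maximum {max_width}")
    lom = pwm_log_odds(pwm)
    lattice = np.rint(lom / granularity).astype(np.int64)
    lo = int(lattice.min(axis=1).sum())
    hi = int(lattice.max(axis=1).sum())
    size = hi - lo + 1
    # dist[k] = P(partial score == lo_partial + k); re-anchored each step
    dist = np.zeros(1)
    dist[0] = 1.0
    cur_lo = 0
    for i in range(pwm.width):
        col = lattice[i]
        col_lo, col_hi = int(col.min()), int(col.max())
        new = np.zeros(len(dist) + (col_hi - col_lo))
        for b in range(4):
            off = int(col[b]) - col_lo
            new[off : off + len(dist)] += pwm.background[b] * dist
        dist = new
        cur_lo += col_lo
    assert cur_lo == lo and len(dist) == size
    # clip guards against |1 - mass| ~ 1e-16 breaking "p <= 1" semantics
    survival = np.minimum(np.cumsum(dist[::-1])[::-1], 1.0)
    return ScoreDistribution(granularity=granularity, kmin=lo, survival=survival, lattice=lattice)


def _scan_one_strand(
    enc: np.ndarray, lattice: np.ndarray, width: int
) -> np.ndarray | None:
    """Integer lattice scores for every window; windows with non-ACGT bases
    are set to INT64_MIN. Returns None if the sequence is shorter than the PWM."""
    n = len(enc) - width + 1
    if n <= 0:
        return None
    valid = enc < 4
    safe = np.where(valid, enc, 0)
    scores = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(width):
        scores += lattice[i, safe[i : i + n]]
        ok &= valid[i : i + n]
    scores[~ok] = np.iinfo(np.int64).min
    return scores


def scan_promoters(
    pwms: list[Pwm],
    promoters: dict[str, str],
    alpha: float = 1e-5,
    both_strands: bool = True,
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """Score every window of every promoter; emit hits with p-value <= alpha.

    Reverse-strand hits are reported at the window's forward offset with
    strand '-'. Overlapping hits are all reported. Promoters shorter than a
    motif simply yield no hits for it.
    """
    if not promoters:
        raise ValueError("no promoters supplied")
    hits: list[MotifHit] = []
    for pwm in pwms:
        strands = [("+", pwm_exact_pvalues(pwm, granularity=granularity))]
        if both_strands:
            strands.append(
                ("-", pwm_exact_pvalues(pwm.reverse_complement(), granularity=granularity))
            )
        for strand, dist in strands:
            # p <= alpha iff lattice score >= k_thresh (survival non-increasing)
            above = np.nonzero(dist.survival <= alpha)[0]
            if len(above) == 0:
                continue
            k_thresh = dist.kmin + int(above[0])
            for gene_id, seq in promoters.items():
                scores = _scan_one_strand(encode(seq), dist.lattice, pwm.width)
                if scores is None:
                    continue
                for off in np.nonzero(scores >= k_thresh)[0]:
                    k = int(scores[off])
                    hits.append(
                        MotifHit(
                            motif_id=pwm.motif_id,
                            gene_id=gene_id,
                            offset=int(off),
                            strand=strand,
                            score_bits=k * granularity,
                            pvalue=dist.pvalue_of_lattice(k),
                        )
                    )
    hits.sort(key=lambda h: (h.gene_id, h.offset, h.motif_id, h.strand))
    return hits
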