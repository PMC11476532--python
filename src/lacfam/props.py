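"""Physicochemical protein properties: length, average molecular weight,
isoelectric point.

The molecular weight is the sum of average-isotopic residue masses plus one
water (18.01524 Da), the ProtParam convention. The isoelectric point is the
pH at which the Henderson-Hasselbalch net charge over the termini and the
ionizable side chains (D, E, C, Y, H, K, R) crosses zero; the charge is
strictly decreasing in pH, so bisection on [0, 14] converges to a unique
root.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import pandas as pd
from Bio.Data.IUPACData import protein_weights

WATER = 18.01524

#: pK sets for the ionizable groups. Keys: Nterm/Cterm plus side chains.
PK_TABLES: dict[str, dict[str, float]] = {
    # EMBOSS iep defaults
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    # Bjellqvist et al. values as commonly tabulated
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0,
    },
}

_ACIDIC = "DECY"
_BASIC = "HKR"
_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    length: int
    molecular_weight: float  # Da
    isoelectric_point: float


def _clean(seq: str, on_unknown: str) -> str:
    seq = seq.upper().replace("*", "")
    bad = sorted(set(seq) - _CANONICAL)
    if bad:
        if on_unknown == "error":
            raise ValueError(f"non-canonical residues: {''.join(bad)}")
        seq = "".join(c for c in seq if c in _CANONICAL)
    return seq


def molecular_weight(seq: str, on_unknown: str = "error") -> float:
    """Average molecular weight in Da: residue masses + one water.

    ``on_unknown``: 'error' rejects X/B/Z etc.; 'skip' drops them.
    """
    seq = _clean(seq, on_unknown)
    if not seq:
        raise ValueError("empty sequence")
    # IUPAC weights are free amino acids; each peptide bond releases a water
    return sum(protein_weights[a] for a in seq) - (len(seq) - 1) * WATER


def net_charge(seq: str, ph: float, pk_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge at the given pH."""
    pk = PK_TABLES[pk_set]
    pos = 10 ** (pk["Nterm"] - ph) / (1 + 10 ** (pk["Nterm"] - ph))
    neg = 10 ** (ph - pk["Cterm"]) / (1 + 10 ** (ph - pk["Cterm"]))
    for a in seq:
        if a in _BASIC:
            pos += 10 ** (pk[a] - ph) / (1 + 10 ** (pk[a] - ph))
        elif a in _ACIDIC:
            neg += 10 ** (ph - pk[a]) / (1 + 10 ** (ph - pk[a]))
    return pos - neg


def isoelectric_point(
    seq: str, pk_set: str = "emboss", tol: float = 1e-4, on_unknown: str = "error"
) -> float:
    """pH where the net charge crosses zero, by bisection on [0, 14]."""
    seq = _clean(seq, on_unknown)
    if not seq:
        raise ValueError("no ionizable groups: empty sequence")
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo, pk_set) < 0 or net_charge(seq, hi, pk_set) > 0:
        # cannot happen with termini present, but guard degenerate pK configs
        raise ValueError("net charge does not cross zero on [0, 14]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pk_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def properties_table(
    proteome: Mapping[str, str],
    protein_ids: list[str] | None = None,
    pk_set: str = "emboss",
    on_unknown: str = "error",
) -> pd.DataFrame:
    """Property table (protein_id, length, mw_da, pi) for the given proteins
    (default: the whole proteome). Every requested protein yields a row."""
    ids = list(protein_ids) if protein_ids is not None else sorted(proteome)
    rows = []
    for pid in ids:
        seq = proteome[pid]
        rows.append(
            {
                "protein_id": pid,
                "length": len(seq),
                "mw_da": molecular_weight(seq, on_unknown),
                "pi": isoelectric_point(seq, pk_set, on_unknown=on_unknown),
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "length", "mw_da", "pi"])
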