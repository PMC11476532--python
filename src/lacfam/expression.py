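"""Berry-development expression processing and qPCR relative quantification.

Expression matrices are pandas DataFrames (genes x samples, FPKM) with a
sample annotation table (sample, stage, replicate, year). Stages index
berry development; the véraison stage (color transformation) splits the
series into pre- and post-véraison, and genes are classified by where their
stage-averaged profile peaks.

Relative qPCR expression uses the 2^-ddCt method against a reference gene
(e.g. beta-TUB4) and a calibrator sample.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CtTable:
    """Long-format Ct values: rows (gene, sample, ct)."""

    values: pd.DataFrame  # columns gene, sample, ct
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        need = {"gene", "sample", "ct"}
        if not need <= set(self.values.columns):
            raise ValueError(f"CtTable needs columns {sorted(need)}")
        if (self.values["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")


def filter_min_mean(m: pd.DataFrame, min_mean: float = 1.0) -> pd.DataFrame:
    """Drop genes whose mean FPKM over ALL samples is below ``min_mean``.

    A row with mean exactly ``min_mean`` is kept (the filter deletes '< 1').
    Idempotent and monotone in ``min_mean``.
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    if m.empty:
        return m
    return m.loc[m.mean(axis=1) >= min_mean]


def row_zscore(m: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardization (x - mean) / sd with sample sd (ddof=1).

    Constant rows map to all-zeros with a warning (heat-map convention)."""
    mean = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant row(s) mapped to zeros", stacklevel=2
        )
    sd = sd.mask(const, 1.0)
    return m.sub(mean, axis=0).div(sd, axis=0)


def stage_means(m: pd.DataFrame, stage_of: Mapping[str, int]) -> pd.DataFrame:
    """Average replicate/year columns within each stage; columns become the
    sorted stage indices."""
    missing = [c for c in m.columns if c not in stage_of]
    if missing:
        raise ValueError(f"samples without stage labels: {missing}")
    grouped = m.T.groupby(m.columns.map(stage_of).astype(int)).mean().T
    return grouped.reindex(sorted(grouped.columns), axis=1)


def peak_stage_class(
    m: pd.DataFrame, stage_of: Mapping[str, int], veraison_index: int
) -> dict[str, str]:
    """'pre' if a gene's stage-mean profile peaks before the véraison stage,
    else 'post'. Ties break toward the earlier stage."""
    sm = stage_means(m, stage_of)
    stages = list(sm.columns)
    if veraison_index < min(stages) or veraison_index > max(stages):
        raise ValueError(f"veraison index {veraison_index} outside stages {stages}")
    # idxmax returns the first (earliest) stage on ties
    peaks = sm.idxmax(axis=1)
    return {g: ("pre" if int(p) < veraison_index else "post") for g, p in peaks.items()}


def relative_expression_ddct(ct: CtTable) -> pd.DataFrame:
    """Fold changes by 2^-ddCt, genes x samples.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the calibrator
    sample's dCt; fold = 2^-ddCt. The calibrator column is exactly 1 for
    every gene measured in it.
    """
    wide = ct.values.pivot_table(index="gene", columns="sample", values="ct", aggfunc="mean")
    if ct.reference_gene not in wide.index:
        raise ValueError(f"reference gene {ct.reference_gene!r} absent from table")
    ref = wide.loc[ct.reference_gene]
    no_ref = ref[ref.isna()].index.tolist()
    if no_ref:
        raise ValueError(f"reference Ct missing in sample(s): {no_ref}")
    if ct.calibrator_sample not in wide.columns:
        raise ValueError(f"calibrator sample {ct.calibrator_sample!r} absent from table")
    dct = wide.sub(ref, axis=1).drop(index=ct.reference_gene)
    ddct = dct.sub(dct[ct.calibrator_sample], axis=0)
    return np.power(2.0, -ddct)
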