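"""FPKM expression summarization.

Counts are mapped-fragment totals per gene and tissue; the effective
length is the CDS length (reads are mapped to coding sequences) and the
library total is the library-wide mapped-fragment count, so

    FPKM = count * 1e9 / (effective_length_bp * total_mapped)

A gene is called expressed in a tissue when more than one fragment maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .io_formats import read_tsv, write_tsv

SUBFAMILY_ORDER = ("PIP", "TIP", "NIP", "SIP", "XIP")

TOTAL_ROW = "TOTAL_MAPPED"


@dataclass
class CountTable:
    counts: pd.DataFrame          # genes x tissues, integer fragments
    eff_len: pd.Series            # per-gene effective length (bp)
    totals: pd.Series             # per-tissue library-wide mapped fragments

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("fragment counts must be nonnegative")
        if (self.eff_len <= 0).any():
            raise ValueError("effective lengths must be positive")
        if (self.totals <= 0).any():
            raise ValueError("library totals must be positive")
        family_sums = self.counts.sum(axis=0)
        if (self.totals < family_sums).any():
            raise ValueError(
                "library totals must be at least the family column sums"
            )


@dataclass
class ExpressionMatrix:
    fpkm: pd.DataFrame            # genes x tissues
    subfamily: pd.Series          # per-gene label
    expressed: pd.DataFrame       # genes x tissues booleans


def fpkm(count: float, eff_len: float, total_mapped: float) -> float:
    """Fragments per kilobase of model per million mapped fragments."""
    if eff_len <= 0:
        raise ValueError("effective length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped fragments must be positive")
    return count * 1e9 / (eff_len * total_mapped)


def call_expressed(count: int, min_fragments: int = 2) -> bool:
    """Expressed iff the mapped-fragment count is more than one."""
    if count < 0:
        raise ValueError("count must be >= 0")
    return count >= min_fragments


def expression_matrix(
    table: CountTable, subfamily: Mapping[str, str], *, min_fragments: int = 2
) -> ExpressionMatrix:
    values = table.counts.astype(float)
    f = values.mul(1e9).div(table.eff_len, axis=0).div(table.totals, axis=1)
    expressed = table.counts >= min_fragments
    labels = pd.Series({g: subfamily[g] for g in table.counts.index})
    return ExpressionMatrix(fpkm=f, subfamily=labels, expressed=expressed)


# ---------------------------------------------------------------------------
# summaries


def subfamily_shares(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per tissue and subfamily: total FPKM, member percent shares, and
    pairwise subfamily fold ratios.

    Returns a long-format frame with rows of kind ``total`` (one per
    tissue/subfamily), ``share`` (one per gene) and ``fold`` (one per
    ordered subfamily pair); shares over a zero subfamily total are NaN
    (undefined), as are folds with a zero denominator.
    """
    rows: List[Dict] = []
    for tissue in expr.fpkm.columns:
        col = expr.fpkm[tissue]
        totals = col.groupby(expr.subfamily).sum()
        for subfam, total in totals.items():
            rows.append(
                {"tissue": tissue, "kind": "total", "subfamily": subfam,
                 "gene": None, "value": total}
            )
        for gene, value in col.items():
            subfam = expr.subfamily[gene]
            total = totals[subfam]
            share = 100.0 * value / total if total > 0 else math.nan
            rows.append(
                {"tissue": tissue, "kind": "share", "subfamily": subfam,
                 "gene": gene, "value": share}
            )
        for sf_a in totals.index:
            for sf_b in totals.index:
                if sf_a == sf_b:
                    continue
                fold = (
                    totals[sf_a] / totals[sf_b] if totals[sf_b] > 0 else math.nan
                )
                rows.append(
                    {"tissue": tissue, "kind": "fold",
                     "subfamily": f"{sf_a}:{sf_b}", "gene": None, "value": fold}
                )
    return pd.DataFrame(rows, columns=["tissue", "kind", "subfamily", "gene", "value"])


def pair_divergence(
    gene_a: str,
    gene_b: str,
    expr: ExpressionMatrix,
    pseudocount: float = 1.0,
) -> Tuple[pd.Series, bool]:
    """Per-tissue log2 expression ratio of a duplicate pair.

    Returns (log2((a + pc) / (b + pc)) per tissue, preference-switch flag);
    the flag is set when the ratio changes sign across tissues, i.e. each
    duplicate dominates in a different tissue.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for g in (gene_a, gene_b):
        if g not in expr.fpkm.index:
            raise KeyError(f"gene {g!r} not in the expression matrix")
    ratios = np.log2(
        (expr.fpkm.loc[gene_a] + pseudocount)
        / (expr.fpkm.loc[gene_b] + pseudocount)
    )
    switch = bool((ratios > 0).any() and (ratios < 0).any())
    return ratios, switch


def heatmap_matrix(
    expr: ExpressionMatrix, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(FPKM + pseudocount) with rows ordered by subfamily then name."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    rank = {sf: i for i, sf in enumerate(SUBFAMILY_ORDER)}
    order = sorted(
        expr.fpkm.index,
        key=lambda g: (rank.get(expr.subfamily[g], len(rank)), g),
    )
    return np.log2(expr.fpkm.loc[order] + pseudocount)


# ---------------------------------------------------------------------------
# TSV round trip


def write_count_table(table: CountTable, path) -> None:
    tissues = list(table.counts.columns)
    df = table.counts.copy()
    df.insert(0, "length", table.eff_len)
    df.insert(0, "gene", table.counts.index)
    totals_row = {"gene": TOTAL_ROW, "length": 0}
    totals_row.update({t: int(table.totals[t]) for t in tissues})
    df = pd.concat([df, pd.DataFrame([totals_row])], ignore_index=True)
    write_tsv(df, path)


def read_count_table(path) -> CountTable:
    df = read_tsv(path)
    tissues = [c for c in df.columns if c not in ("gene", "length")]
    body = df[df["gene"] != TOTAL_ROW]
    totals_rows = df[df["gene"] == TOTAL_ROW]
    if totals_rows.empty:
        raise ValueError(f"{path}: missing {TOTAL_ROW} totals row")
    counts = body[tissues].astype(int)
    counts.index = pd.Index(body["gene"], name="gene")
    eff_len = pd.Series(
        body["length"].astype(int).values, index=counts.index, name="length"
    )
    totals = totals_rows.iloc[0][tissues].astype(int)
    return CountTable(counts=counts, eff_len=eff_len, totals=totals)
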