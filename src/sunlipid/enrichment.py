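"""Candidate-gene enrichment within significant LD blocks.

Genes overlapping significant haplotype blocks are intersected with a
curated pathway list (e.g. oil-metabolism genes) and tested for enrichment
with a one-sided Fisher exact test on the 2x2 classification
(in pathway x in blocks) over all annotated genes.
"""
from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import LDBlock

__all__ = ["genes_in_blocks", "fisher_enrichment"]


def genes_in_blocks(
    genes: pd.DataFrame, blocks: Sequence[LDBlock], flank: int = 0
) -> set:
    """Gene ids overlapping any block by >= 1 bp (1-based inclusive).

    ``genes`` needs columns gene_id, chrom, start, end. ``flank`` widens
    every block symmetrically before intersecting.
    """
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    hits: set = set()
    for blk in blocks:
        lo, hi = blk.start - flank, blk.end + flank
        mask = (
            (genes["chrom"] == blk.chrom)
            & (genes["start"] <= hi)
            & (genes["end"] >= lo)
        )
        hits.update(genes.loc[mask, "gene_id"])
    return hits


def fisher_enrichment(
    total: int, in_list: int, in_blocks: int, overlap: int
) -> tuple[float, float]:
    """Odds ratio and one-sided Fisher p for pathway/block overlap.

    2x2 table: a = overlap, b = in_blocks - overlap, c = in_list - overlap,
    d = total - a - b - c. Returns the sample odds ratio ad/bc (0 or inf
    when a margin is empty) and the one-sided (greater) hypergeometric p.
    """
    a = overlap
    b = in_blocks - overlap
    c = in_list - overlap
    d = total - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts: negative 2x2 cell")
    if a == 0:
        odds = 0.0
    elif b == 0 or c == 0:
        odds = math.inf
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
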