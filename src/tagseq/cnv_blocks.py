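"""Expression-derived relative copy-number signal in megabase blocks.

Genes are aggregated into fixed-size genomic blocks keyed by transcription
termination site (the anchor of the tag signal), block expression is summed
per sample, and each block is expressed as a log2 ratio against the mean of
a designated reference sample group.  A broad DNA amplification then shows
up as a contiguous run of elevated blocks in the affected samples.  This is
a qualitative readout — no segmentation, breakpoint calling, or calibrated
copy-number estimation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate_count import TranscriptModel

DEFAULT_BLOCK_SIZE = 1_000_000
DEFAULT_PSEUDOCOUNT = 1.0


class CnvError(ValueError):
    pass


def gene_tts(models: Sequence[TranscriptModel]) -> Dict[str, Tuple[str, int]]:
    """Representative TTS per gene: the 3'-most terminus among its
    transcripts (strand-aware), maximizing consistency with tag signal."""
    best: Dict[str, Tuple[str, str, int]] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = (m.reference, m.strand, m.tts)
            continue
        _, strand, tts = cur
        if strand != m.strand or cur[0] != m.reference:
            raise CnvError(f"gene {m.gene_id}: transcripts disagree on locus")
        further = m.tts > tts if m.strand == "+" else m.tts < tts
        if further:
            best[m.gene_id] = (m.reference, m.strand, m.tts)
    return {g: (ref, tts) for g, (ref, _, tts) in best.items()}


def assign_blocks(
    models: Sequence[TranscriptModel],
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> Dict[str, Tuple[str, int]]:
    """Map each gene to (chromosome, block index) with block = floor(TTS/size)."""
    if block_size <= 0:
        raise CnvError(f"block size must be positive, got {block_size}")
    return {
        gene: (ref, tts // block_size)
        for gene, (ref, tts) in gene_tts(models).items()
    }


@dataclass
class BlockMatrix:
    """Blocks x samples log2-ratio matrix with a no-data mask."""

    values: pd.DataFrame  # index: (chromosome, block index)
    no_data: pd.Series  # boolean per block
    membership: Dict[Tuple[str, int], List[str]]
    reference_samples: List[str]
    params: dict = field(default_factory=dict)

    def write(self, path: str, block_size: int = DEFAULT_BLOCK_SIZE) -> None:
        out = self.values.copy()
        out.insert(0, "chromosome", [b[0] for b in out.index])
        out.insert(1, "block_start", [b[1] * block_size for b in out.index])
        out.insert(2, "block_end", [(b[1] + 1) * block_size for b in out.index])
        out.insert(3, "no_data", self.no_data.to_numpy())
        out.to_csv(path, sep="\t", index=False)


def block_expression(
    expr: pd.DataFrame,
    blocks: Dict[str, Tuple[str, int]],
    reference_samples: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    order: str = "per_block",
) -> BlockMatrix:
    """Aggregate a genes x samples expression table into block log2 ratios.

    per_block (default): sum expression over the block's genes, then
        log2((sum + pseudocount) / (reference mean of sum + pseudocount)).
    per_gene: form each gene's log2 ratio against its reference mean first,
        then average the ratios within the block.

    Blocks with zero expression in every sample are flagged no-data.
    """
    if order not in ("per_block", "per_gene"):
        raise CnvError(f"unknown aggregation order {order!r}")
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise CnvError("reference sample set is empty")
    missing = [s for s in reference_samples if s not in expr.columns]
    if missing:
        raise CnvError(f"unknown reference samples: {missing}")
    genes = [g for g in expr.index if g in blocks]
    expr = expr.loc[genes]
    chroms = pd.Index([blocks[g][0] for g in genes], name="chromosome")
    idxs = pd.Index([blocks[g][1] for g in genes], name="block")
    keys = [chroms, idxs]

    membership: Dict[Tuple[str, int], List[str]] = {}
    for g in genes:
        membership.setdefault(blocks[g], []).append(g)

    if order == "per_block":
        sums = expr.groupby(keys).sum()
        ref_mean = sums[reference_samples].mean(axis=1)
        values = np.log2(sums.add(pseudocount, axis=0).div(
            ref_mean + pseudocount, axis=0))
        no_data = sums.sum(axis=1) == 0
    else:
        ref_mean_gene = expr[reference_samples].mean(axis=1)
        ratios = np.log2(expr.add(pseudocount, axis=0).div(
            ref_mean_gene + pseudocount, axis=0))
        values = ratios.groupby(keys).mean()
        no_data = expr.groupby(keys).sum().sum(axis=1) == 0

    values = values.sort_index()
    no_data = no_data.sort_index()
    return BlockMatrix(
        values=values,
        no_data=no_data,
        membership=membership,
        reference_samples=reference_samples,
        params={"pseudocount": pseudocount, "order": order},
    )
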