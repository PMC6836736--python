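"""Gene assignment with 3'-end > exon > intron priority, and count tables.

A tag read is expected at the 3' terminus of its source transcript, so when
an alignment touches more than one annotated feature the most likely origin
wins: a read overlapping the end region of *any* same-strand transcript is
"3' end" regardless of what else it touches; otherwise "exon" if it overlaps
any same-strand exon; otherwise "intron" if it falls within a same-strand
transcript body; otherwise intergenic.  Only sense-orientation overlaps are
considered.  Gene-level counts use only nonduplicate sense alignments, and
libraries with too few reads assigned to genes are dropped as failed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .dedup import (TagAlignment, estimate_nonduplicates, group_alignments)

DEFAULT_END_WINDOW = 500  # nt upstream of the TTS treated as "3' end"
DEFAULT_MIN_GENE_READS = 10_000


class AnnotationError(ValueError):
    pass


class AssignmentCategory(Enum):
    THREE_PRIME_END = "3p_end"
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"
    AMBIGUOUS_GENE = "ambiguous_gene"


@dataclass
class TranscriptModel:
    """Stranded exon structure with a distinguished 3' terminus.

    Exons are 0-based half-open genomic intervals, sorted by coordinate and
    nonoverlapping.  ``tts`` is the transcript's final base: the last base of
    the last exon on the + strand, the first base of the first exon on -.
    """

    transcript_id: str
    gene_id: str
    reference: str
    strand: str
    exons: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(
                    f"{self.transcript_id}: empty exon interval [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons at {s}")
            prev_end = e

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tts(self) -> int:
        if self.strand == "+":
            return self.exons[-1][1] - 1
        return self.exons[0][0]

    def end_window(self, window: int) -> Tuple[int, int]:
        """Genomic interval covering the ``window`` bases ending at the TTS,
        clipped to the transcript's genomic span."""
        lo, hi = self.span
        if self.strand == "+":
            return max(lo, self.tts - window + 1), self.tts + 1
        return self.tts, min(hi, self.tts + window)


def load_annotation(gtf_path: str) -> List[TranscriptModel]:
    """Build transcript models from a GTF file (1-based closed coordinates)."""
    db = gffutils.create_db(
        gtf_path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    grouped: Dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        try:
            tid = exon.attributes["transcript_id"][0]
            gid = exon.attributes["gene_id"][0]
        except KeyError as err:
            raise AnnotationError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} lacks {err} attribute"
            ) from None
        if exon.end < exon.start:
            raise AnnotationError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end}: end before start")
        rec = grouped.setdefault(
            tid, {"gene_id": gid, "reference": exon.seqid,
                  "strand": exon.strand, "exons": []})
        rec["exons"].append((exon.start - 1, exon.end))  # to 0-based half-open
    return [
        TranscriptModel(transcript_id=tid, gene_id=rec["gene_id"],
                        reference=rec["reference"], strand=rec["strand"],
                        exons=rec["exons"])
        for tid, rec in grouped.items()
    ]


class AnnotationIndex:
    """Interval indexes over 3'-end windows, exons, and transcript bodies."""

    def __init__(self, models: Sequence[TranscriptModel],
                 end_window: int = DEFAULT_END_WINDOW):
        self.end_window = end_window
        self.models = list(models)
        self._ends: Dict[tuple, IntervalTree] = {}
        self._exons: Dict[tuple, IntervalTree] = {}
        self._bodies: Dict[tuple, IntervalTree] = {}
        for m in models:
            key = (m.reference, m.strand)
            lo, hi = m.end_window(end_window)
            if hi > lo:
                self._ends.setdefault(key, IntervalTree()).addi(lo, hi, m.gene_id)
            for s, e in m.exons:
                self._exons.setdefault(key, IntervalTree()).addi(s, e, m.gene_id)
            s, e = m.span
            self._bodies.setdefault(key, IntervalTree()).addi(s, e, m.gene_id)

    def _hits(self, trees: Dict[tuple, IntervalTree], aln: TagAlignment) -> set:
        tree = trees.get((aln.reference, aln.strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(aln.start, max(aln.end, aln.start + 1))}


def categorize_alignment(
    aln: TagAlignment, index: AnnotationIndex
) -> Tuple[AssignmentCategory, Optional[str]]:
    """Assign one sense-strand alignment to a category and (maybe) a gene."""
    for trees, category in (
        (index._ends, AssignmentCategory.THREE_PRIME_END),
        (index._exons, AssignmentCategory.EXON),
        (index._bodies, AssignmentCategory.INTRON),
    ):
        genes = index._hits(trees, aln)
        if genes:
            if len(genes) > 1:
                return AssignmentCategory.AMBIGUOUS_GENE, None
            return category, next(iter(genes))
    return AssignmentCategory.INTERGENIC, None


@dataclass
class CountTable:
    """Genes x samples counts plus per-sample category tallies."""

    counts: pd.DataFrame
    tallies: pd.DataFrame  # categories x samples
    params: dict = field(default_factory=dict)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def gene_reads_per_sample(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def write(self, counts_path: str, sidecar_path: Optional[str] = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        if sidecar_path:
            payload = {"params": self.params,
                       "category_tallies": {
                           s: {c: float(self.tallies.loc[c, s])
                               for c in self.tallies.index}
                           for s in self.tallies.columns}}
            with open(sidecar_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def count_genes(
    alignments_per_sample: Dict[str, Iterable[TagAlignment]],
    models: Sequence[TranscriptModel],
    end_window: int = DEFAULT_END_WINDOW,
    count_mode: str = "classic",
    min_mapq: int = 10,
    umi_len: int = 5,
) -> CountTable:
    """Build a gene x sample count table.

    classic mode counts reads not flagged as duplicates (one unit each);
    corrected mode groups each sample's coordinate-sorted alignments by
    position and adds the group's collision-corrected nonduplicate estimate
    to the gene the group is assigned to, so counts are fractional.
    Category tallies cover every MAPQ-passing alignment (classic) or group
    (corrected), including intergenic and gene-ambiguous ones.
    """
    if count_mode not in ("classic", "corrected"):
        raise AnnotationError(f"unknown count mode {count_mode!r}")
    samples = list(alignments_per_sample)
    if len(set(samples)) != len(samples):
        raise AnnotationError("sample name collision")
    index = AnnotationIndex(models, end_window=end_window)
    gene_ids = sorted({m.gene_id for m in models})
    counts = pd.DataFrame(0.0, index=gene_ids, columns=samples)
    cats = [c.value for c in AssignmentCategory]
    tallies = pd.DataFrame(0.0, index=cats, columns=samples)

    cache: Dict[tuple, tuple] = {}  # alignment span -> (category, gene)

    def categorize_cached(aln: TagAlignment) -> tuple:
        key = (aln.reference, aln.strand, aln.start, aln.end)
        hit = cache.get(key)
        if hit is None:
            hit = categorize_alignment(aln, index)
            cache[key] = hit
        return hit

    for sample, alns in alignments_per_sample.items():
        gene_acc: Dict[str, float] = {}
        cat_acc: Dict[str, float] = {c: 0.0 for c in cats}
        if count_mode == "classic":
            for aln in alns:
                if aln.mapq < min_mapq or aln.duplicate:
                    continue
                category, gene = categorize_cached(aln)
                cat_acc[category.value] += 1
                if gene is not None:
                    gene_acc[gene] = gene_acc.get(gene, 0.0) + 1
        else:
            for group in group_alignments(alns, min_mapq=min_mapq,
                                          umi_len=umi_len):
                est = estimate_nonduplicates(group)
                rep = TagAlignment(
                    read_id="group", reference=group.key[0],
                    strand=group.key[1], start=group.key[2], mapq=255,
                    umi="A" * umi_len,
                    end=max(a.end for a in group.alignments),
                )
                category, gene = categorize_cached(rep)
                cat_acc[category.value] += est
                if gene is not None:
                    gene_acc[gene] = gene_acc.get(gene, 0.0) + est
        for gene, val in gene_acc.items():
            counts.loc[gene, sample] = val
        for cat, val in cat_acc.items():
            tallies.loc[cat, sample] = val

    return CountTable(
        counts=counts, tallies=tallies,
        params={"end_window": end_window, "count_mode": count_mode,
                "min_mapq": min_mapq},
    )


def filter_failed_libraries(
    table: CountTable,
    min_gene_reads: int = DEFAULT_MIN_GENE_READS,
) -> Tuple[CountTable, List[str]]:
    """Drop samples with fewer than ``min_gene_reads`` reads aligned to genes."""
    totals = table.gene_reads_per_sample()
    discarded = [s for s in table.samples if totals[s] < min_gene_reads]
    kept = [s for s in table.samples if s not in discarded]
    filtered = CountTable(
        counts=table.counts[kept],
        tallies=table.tallies[kept],
        params={**table.params, "min_gene_reads": min_gene_reads},
    )
    return filtered, discarded
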