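"""UMI-collision-corrected duplicate detection for 3'-tag sequencing.

In a 3'-tag library every read starts at a reproducible position near the
transcript's poly(A) site, so reads from *different* RNA molecules frequently
share a genome position by chance.  Unique molecular identifiers (UMIs)
separate these coincidental position duplicates from true PCR duplicates, but
when read density is high relative to the UMI space (n = 4^k for k-nt UMIs)
even distinct molecules collide on both position and UMI.

The corrected estimator implemented here treats each observed per-UMI read
count c as a prediction that any count above c + 1 at the same position is
PCR duplication, and averages those predictions over all n UMIs (zero-count
UMIs included, each voting for a cap of one read per UMI):

    estimate = (1/n) * sum_i sum_j min(c_j, c_i + 1)

When totals are small this reduces exactly to the traditional one-read-per-UMI
rule; when totals approach or exceed n it keeps counting molecules the
traditional rule would collapse.
"""

from __future__ import annotations

import sys
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

VALID_UMI_BASES = frozenset("ACGT")


class DedupError(ValueError):
    pass


def umi_space_size(umi_len: int) -> int:
    """Number of possible UMIs for a given tag length (4^umi_len)."""
    if umi_len < 0:
        raise DedupError(f"negative UMI length: {umi_len}")
    return 4 ** umi_len


@dataclass
class TagAlignment:
    """One aligned tag read.

    ``start`` is the soft-clip-adjusted 5'-most aligned base of the read on
    its own strand (0-based).  ``end`` is the exclusive end of the aligned
    reference span, used only for feature overlap; the duplicate grouping key
    is (reference, strand, start).
    """

    read_id: str
    reference: str
    strand: str  # "+" or "-"
    start: int
    mapq: int
    umi: str
    end: Optional[int] = None
    duplicate: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DedupError(f"bad strand {self.strand!r} for read {self.read_id}")
        if self.end is None:
            self.end = self.start + 1


@dataclass
class UmiCountVector:
    """Per-position read counts over the full UMI space.

    Only nonzero counts are stored; the remaining ``n - len(counts)`` UMIs
    implicitly have count zero.  Reads whose UMI contains a non-ACGT
    character are tallied in ``ambiguous_count`` and kept out of the vector.
    """

    key: tuple  # (reference, strand, start)
    n: int
    counts: Counter = field(default_factory=Counter)
    ambiguous_count: int = 0
    alignments: list = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values()) + self.ambiguous_count

    def add(self, aln: TagAlignment) -> None:
        if is_ambiguous_umi(aln.umi):
            self.ambiguous_count += 1
        else:
            self.counts[aln.umi] += 1
        self.alignments.append(aln)


def is_ambiguous_umi(umi: str) -> bool:
    return any(b not in VALID_UMI_BASES for b in umi)


def estimate_nonduplicates(v: UmiCountVector) -> float:
    """Collision-corrected estimate of nonduplicate reads in one group.

    Evaluates (1/n) * sum_i sum_j min(c_j, c_i + 1) over the full UMI space
    using the frequency-of-frequencies table, which reduces the naive O(n^2)
    double loop to O(d^2) for d distinct count values.  Exactness against the
    naive evaluation is asserted in the test suite.

    Ambiguous-UMI reads are outside the vector and each counts as one
    nonduplicate read of its own.
    """
    n = v.n
    if n < 1:
        raise DedupError("UMI space must contain at least one UMI")
    est = _estimate_from_counts(list(v.counts.values()), n)
    return est + v.ambiguous_count


def _estimate_from_counts(nonzero_counts: Sequence[int], n: int) -> float:
    if not nonzero_counts:
        return 0.0
    if len(nonzero_counts) > n:
        raise DedupError(f"{len(nonzero_counts)} distinct UMIs exceed UMI space n={n}")
    freq = Counter(nonzero_counts)
    n_zero = n - len(nonzero_counts)
    if n_zero:
        freq[0] = n_zero
    vals = np.array(sorted(freq), dtype=np.float64)
    mult = np.array([freq[int(t)] for t in sorted(freq)], dtype=np.float64)
    # prediction of UMI-count value t: sum_s f_s * min(s, t + 1)
    capped = np.minimum(vals[:, None], vals[None, :] + 1.0)  # [s, t]
    predictions = (mult[:, None] * capped).sum(axis=0)
    return float((mult * predictions).sum() / n)


def classic_nonduplicates(v: UmiCountVector) -> int:
    """Traditional one-read-per-UMI rule: number of UMIs observed at least once."""
    return sum(1 for c in v.counts.values() if c > 0) + v.ambiguous_count


def group_alignments(
    alignments: Iterable[TagAlignment],
    min_mapq: int = 10,
    umi_len: int = 5,
) -> Iterator[UmiCountVector]:
    """Group coordinate-sorted alignments by (reference, strand, 5' start).

    Alignments below ``min_mapq`` are discarded before grouping.  The input
    must be coordinate-sorted (nondecreasing start within each reference,
    no reference revisited); violations raise :class:`DedupError`.
    """
    n = umi_space_size(umi_len)
    seen_refs: set = set()
    current_ref: Optional[str] = None
    current_start = -1
    pending: dict = {}

    def flush() -> Iterator[UmiCountVector]:
        for key in sorted(pending):
            yield pending[key]
        pending.clear()

    for aln in alignments:
        if aln.mapq < min_mapq:
            continue
        if len(aln.umi) != umi_len:
            raise DedupError(
                f"UMI {aln.umi!r} of read {aln.read_id} does not match "
                f"configured length {umi_len}"
            )
        if aln.reference != current_ref:
            if aln.reference in seen_refs:
                raise DedupError(
                    f"input not coordinate-sorted: reference {aln.reference} revisited"
                )
            yield from flush()
            seen_refs.add(aln.reference)
            current_ref = aln.reference
            current_start = -1
        if aln.start < current_start:
            raise DedupError(
                f"input not coordinate-sorted: {aln.reference}:{aln.start} "
                f"after {current_start}"
            )
        if aln.start > current_start:
            yield from flush()
            current_start = aln.start
        key = (aln.reference, aln.strand, aln.start)
        if key not in pending:
            pending[key] = UmiCountVector(key=key, n=n)
        pending[key].add(aln)
    yield from flush()


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class GroupReport:
    reference: str
    strand: str
    start: int
    total: int
    classic: int
    corrected: float


def mark_group(v: UmiCountVector, mode: str) -> GroupReport:
    """Set duplicate flags on a group's alignments in place.

    classic mode: the first-seen read of each (position, UMI) stays unflagged.
    corrected mode: the number of unflagged reads equals the rounded
    collision-corrected estimate; after the classic one-per-UMI pass, extra
    reads are unflagged one UMI at a time in decreasing-count order (ties
    broken lexicographically by UMI), cycling until the target is reached.
    Ambiguous-UMI reads are never flagged.
    """
    if mode not in ("classic", "corrected"):
        raise DedupError(f"unknown duplicate-marking mode {mode!r}")
    classic = classic_nonduplicates(v)
    corrected = estimate_nonduplicates(v)

    per_umi_reads: dict = {}
    for aln in v.alignments:
        if is_ambiguous_umi(aln.umi):
            aln.duplicate = False
            continue
        per_umi_reads.setdefault(aln.umi, []).append(aln)

    keep_per_umi = {umi: min(len(reads), 1) for umi, reads in per_umi_reads.items()}
    if mode == "corrected":
        target = _round_half_up(corrected) - v.ambiguous_count
        extra = target - sum(keep_per_umi.values())
        order = sorted(per_umi_reads, key=lambda u: (-len(per_umi_reads[u]), u))
        while extra > 0:
            progressed = False
            for umi in order:
                if extra <= 0:
                    break
                if keep_per_umi[umi] < len(per_umi_reads[umi]):
                    keep_per_umi[umi] += 1
                    extra -= 1
                    progressed = True
            if not progressed:
                break
    for umi, reads in per_umi_reads.items():
        k = keep_per_umi[umi]
        for i, aln in enumerate(reads):
            aln.duplicate = i >= k
    ref, strand, start = v.key
    return GroupReport(ref, strand, start, v.total_reads, classic, corrected)


def mark_duplicates(
    alignments: Iterable[TagAlignment],
    mode: str = "corrected",
    min_mapq: int = 10,
    umi_len: int = 5,
) -> Iterator[tuple]:
    """Yield (group alignments, GroupReport) pairs with duplicate flags set."""
    for v in group_alignments(alignments, min_mapq=min_mapq, umi_len=umi_len):
        report = mark_group(v, mode)
        yield v.alignments, report


# ---------------------------------------------------------------------------
# SAM I/O


def five_prime_start(seg: pysam.AlignedSegment) -> int:
    """Soft-clip-adjusted 5'-most aligned base of a read on its own strand."""
    cigar = seg.cigartuples or []
    if seg.is_reverse:
        trail = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
        return seg.reference_end - 1 + trail
    lead = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
    return seg.reference_start - lead


def umi_from_name(name: str, delimiter: str = "_") -> tuple:
    """Split a read name of the form ``{id}{delimiter}{UMI}``."""
    base, _, umi = name.rpartition(delimiter)
    if not base:
        raise DedupError(f"read name {name!r} carries no {delimiter!r}-delimited UMI")
    return base, umi


def read_tag_alignments(
    path: str, umi_delimiter: str = "_"
) -> Iterator[TagAlignment]:
    """Stream mapped SAM/BAM records as :class:`TagAlignment` objects."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            base, umi = umi_from_name(seg.query_name, umi_delimiter)
            yield TagAlignment(
                read_id=base,
                reference=seg.reference_name,
                strand="-" if seg.is_reverse else "+",
                start=five_prime_start(seg),
                mapq=seg.mapping_quality,
                umi=umi,
                end=seg.reference_end,
                duplicate=seg.is_duplicate,
            )


def dedup_sam(
    in_path: str,
    out_path: str,
    mode: str = "corrected",
    min_mapq: int = 10,
    umi_len: int = 5,
    umi_delimiter: str = "_",
    report_path: Optional[str] = None,
) -> list:
    """Mark duplicates in a coordinate-sorted SAM/BAM file.

    Unflagged/flagged status is written as the standard 0x400 duplicate flag.
    Returns the per-group reports (and optionally writes them as TSV).
    """
    reports = []
    with pysam.AlignmentFile(in_path, check_sq=False) as fh:
        header = fh.header.to_dict()
        segments = [s for s in fh if not s.is_unmapped]

    def to_tag(seg: pysam.AlignedSegment) -> TagAlignment:
        base, umi = umi_from_name(seg.query_name, umi_delimiter)
        return TagAlignment(
            read_id=seg.query_name,
            reference=seg.reference_name,
            strand="-" if seg.is_reverse else "+",
            start=five_prime_start(seg),
            mapq=seg.mapping_quality,
            umi=umi,
            end=seg.reference_end,
        )

    tags = [to_tag(s) for s in segments]
    flag_by_read: dict = {}
    for group, report in mark_duplicates(tags, mode=mode, min_mapq=min_mapq,
                                         umi_len=umi_len):
        reports.append(report)
        for aln in group:
            flag_by_read[aln.read_id] = aln.duplicate

    mode_out = "wb" if out_path.endswith(".bam") else "wh"
    with pysam.AlignmentFile(out_path, mode_out, header=header) as out:
        for seg in segments:
            seg.is_duplicate = flag_by_read.get(seg.query_name, False)
            out.write(seg)

    if report_path:
        write_group_report(reports, report_path)
    return reports


def write_group_report(reports: Sequence[GroupReport], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reference\tstrand\tstart\ttotal\tclassic\tcorrected\n")
        for r in reports:
            fh.write(f"{r.reference}\t{r.strand}\t{r.start}\t{r.total}\t"
                     f"{r.classic}\t{r.corrected:.4f}\n")
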