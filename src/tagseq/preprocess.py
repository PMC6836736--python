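"""Raw tag-read preprocessing: UMI extraction, overhang removal, dimer filtering.

Each raw read begins with a 5-nt UMI followed by 3 nt deriving from the
template-switch oligonucleotide's G-overhang.  The UMI is moved into the
read name (``{id}{delimiter}{UMI}``), the overhang bases are discarded, and
the remainder is the cDNA insert.  Inserts shorter than 8 nt after optional
adapter trimming are treated as primer dimers: excluded from downstream
analysis but still counted toward the sequenced total.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, TextIO

import pysam

DEFAULT_UMI_LEN = 5
DEFAULT_DISCARD_LEN = 3  # G-overhang bases dropped after the UMI
DEFAULT_MIN_INSERT_LEN = 8
DEFAULT_DELIMITER = "_"


class PreprocessError(ValueError):
    pass


@dataclass
class TagRead:
    """A read after UMI extraction; the UMI lives in the read id suffix."""

    read_id: str
    insert_sequence: str
    insert_qualities: str
    umi: str
    is_dimer: bool

    def to_fastq(self) -> str:
        return (f"@{self.read_id}\n{self.insert_sequence}\n+\n"
                f"{self.insert_qualities}\n")


def extract_umi(
    name: str,
    sequence: str,
    qualities: str,
    umi_len: int = DEFAULT_UMI_LEN,
    discard_len: int = DEFAULT_DISCARD_LEN,
    min_insert_len: int = DEFAULT_MIN_INSERT_LEN,
    delimiter: str = DEFAULT_DELIMITER,
) -> TagRead:
    """Split a raw read into UMI / discarded overhang / insert.

    Reads shorter than ``umi_len + discard_len`` yield an empty insert and
    are flagged as dimers rather than rejected, so stream totals stay simple.
    """
    if len(sequence) != len(qualities):
        raise PreprocessError(
            f"record {name!r}: sequence length {len(sequence)} != "
            f"quality length {len(qualities)}"
        )
    umi = sequence[:umi_len]
    insert = sequence[umi_len + discard_len:]
    quals = qualities[umi_len + discard_len:]
    return TagRead(
        read_id=f"{name}{delimiter}{umi}",
        insert_sequence=insert,
        insert_qualities=quals,
        umi=umi,
        is_dimer=len(insert) < min_insert_len,
    )


def trim_adapter(read: TagRead, adapter: str, min_overlap: int = 3,
                 min_insert_len: int = DEFAULT_MIN_INSERT_LEN) -> TagRead:
    """Remove the longest insert suffix that exactly matches an adapter prefix.

    Overlaps below ``min_overlap`` are ignored; with no match the read is
    returned unchanged.  The dimer flag is re-evaluated after trimming.
    """
    if not adapter:
        raise PreprocessError("adapter sequence must be nonempty")
    insert = read.insert_sequence
    cut = None
    for k in range(min(len(insert), len(adapter)), min_overlap - 1, -1):
        if insert.endswith(adapter[:k]):
            cut = len(insert) - k
            break
    if cut is None:
        return read
    return TagRead(
        read_id=read.read_id,
        insert_sequence=insert[:cut],
        insert_qualities=read.insert_qualities[:cut],
        umi=read.umi,
        is_dimer=cut < min_insert_len,
    )


@dataclass
class PreprocessStats:
    total: int = 0
    kept: int = 0
    dimers: int = 0
    malformed: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def filter_dimers(
    reads: Iterable[TagRead],
    min_insert_len: int = DEFAULT_MIN_INSERT_LEN,
) -> tuple:
    """Partition reads into (kept list, dimer count, total count)."""
    kept = []
    dimers = 0
    total = 0
    for r in reads:
        total += 1
        if len(r.insert_sequence) < min_insert_len:
            dimers += 1
        else:
            kept.append(r)
    return kept, dimers, total


def _open_out(path: str) -> TextIO:
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def process_fastq(
    in_path: str,
    out_path: str,
    dimer_path: Optional[str] = None,
    umi_len: int = DEFAULT_UMI_LEN,
    discard_len: int = DEFAULT_DISCARD_LEN,
    min_insert_len: int = DEFAULT_MIN_INSERT_LEN,
    adapter: Optional[str] = None,
    min_overlap: int = 3,
    delimiter: str = DEFAULT_DELIMITER,
    stats_path: Optional[str] = None,
) -> PreprocessStats:
    """Preprocess a FASTQ file (gzip-transparent input) end to end."""
    stats = PreprocessStats()
    out = _open_out(out_path)
    dimer_out = _open_out(dimer_path) if dimer_path else None
    try:
        with pysam.FastxFile(in_path) as fh:
            for rec in fh:
                stats.total += 1
                try:
                    tag = extract_umi(
                        rec.name, rec.sequence, rec.quality or "",
                        umi_len=umi_len, discard_len=discard_len,
                        min_insert_len=min_insert_len, delimiter=delimiter,
                    )
                except PreprocessError:
                    stats.malformed += 1
                    continue
                if adapter:
                    tag = trim_adapter(tag, adapter, min_overlap=min_overlap,
                                       min_insert_len=min_insert_len)
                if tag.is_dimer:
                    stats.dimers += 1
                    if dimer_out:
                        dimer_out.write(tag.to_fastq())
                else:
                    stats.kept += 1
                    out.write(tag.to_fastq())
    finally:
        out.close()
        if dimer_out:
            dimer_out.close()
    if stats_path:
        stats.to_json(stats_path)
    return stats
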