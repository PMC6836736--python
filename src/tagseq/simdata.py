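"""Synthetic 3'-tag libraries with complete ground truth.

The generator emulates a spike-in dilution experiment: a pool of
polyadenylated transcripts at known concentrations spanning a configurable
dynamic range (the spike-in standard contains 92 transcripts over six orders
of magnitude), from which molecules are captured with some efficiency,
tagged with a random UMI, amplified by PCR, and sampled by the sequencer.
Every emitted read carries a recorded lineage (transcript, founder molecule,
UMI, fragment offset), so downstream estimates — nonduplicate counts, gene
counts, standard-curve statistics — can be scored against exact truth.

Read layout matches the tag chemistry consumed by :mod:`tagseq.preprocess`:
``UMI + GGG + insert``, where the three G bases mimic the template-switch
oligonucleotide's G-overhang.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pysam

BASES = np.array(list("ACGT"))
DEFAULT_CAPTURE_EFFICIENCY = 0.3  # observed fraction of molecules yielding a distinct read
DEFAULT_POLYA_LEN = 30
DEFAULT_FRAGMENT_WINDOW = 200  # 3'-proximal window holding fragment start sites
DEFAULT_INSERT_LEN = 40


class SimulationError(ValueError):
    pass


@dataclass
class SyntheticTranscript:
    """A synthetic polyadenylated transcript at known molar abundance."""

    id: str
    sequence: str
    molar_abundance: float

    def __post_init__(self) -> None:
        if len(self.sequence) < 150:
            raise SimulationError(f"{self.id}: transcript shorter than 150 nt")
        if self.molar_abundance <= 0:
            raise SimulationError(f"{self.id}: nonpositive abundance")


@dataclass
class ReadLineage:
    transcript_id: str
    founder_id: int
    umi: str
    offset: int  # fragment 5' start on the transcript (0-based)
    insert_len: int


@dataclass
class SimTruth:
    """Complete ground truth for one simulated library."""

    params: Dict
    captured: Dict[str, int]  # transcript -> founder-molecule count
    lineages: Dict[str, ReadLineage]  # read id -> lineage (non-dimer reads)
    dimer_reads: List[str] = field(default_factory=list)

    @property
    def n_founders(self) -> int:
        return sum(self.captured.values())

    def founder_counts_per_transcript(self) -> Dict[str, int]:
        """Distinct founder molecules actually represented among the reads."""
        seen: Dict[str, set] = {}
        for lin in self.lineages.values():
            seen.setdefault(lin.transcript_id, set()).add(lin.founder_id)
        return {t: len(s) for t, s in seen.items()}

    def to_json(self, path: str) -> None:
        payload = {
            "params": self.params,
            "captured": self.captured,
            "dimer_reads": self.dimer_reads,
            "lineages": {
                rid: [l.transcript_id, l.founder_id, l.umi, l.offset, l.insert_len]
                for rid, l in self.lineages.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        lineages = {
            rid: ReadLineage(t, f, u, o, il)
            for rid, (t, f, u, o, il) in payload["lineages"].items()
        }
        return cls(payload["params"], payload["captured"], lineages,
                   payload["dimer_reads"])


def make_transcriptome(
    n_transcripts: int,
    orders_of_magnitude: float,
    seed: int,
    min_len: int = 300,
    max_len: int = 1500,
    polya_len: int = DEFAULT_POLYA_LEN,
) -> List[SyntheticTranscript]:
    """Generate a synthetic transcriptome with log-uniformly spaced abundances.

    Abundances are placed at exact even spacing in log10, so the max/min
    ratio equals ``10 ** orders_of_magnitude``.  Deterministic given ``seed``.
    """
    if n_transcripts < 2:
        raise SimulationError(f"need at least 2 transcripts, got {n_transcripts}")
    if orders_of_magnitude < 0:
        raise SimulationError(f"negative dynamic range: {orders_of_magnitude}")
    rng = np.random.default_rng(seed)
    exponents = np.linspace(0.0, orders_of_magnitude, n_transcripts)
    out = []
    width = len(str(n_transcripts))
    for i, exp in enumerate(exponents):
        length = int(rng.integers(min_len, max_len + 1))
        body = "".join(rng.choice(BASES, size=length - polya_len))
        out.append(
            SyntheticTranscript(
                id=f"SYNT{i + 1:0{width}d}",
                sequence=body + "A" * polya_len,
                molar_abundance=float(10.0 ** exp),
            )
        )
    return out


def abundance_ref(transcripts: Sequence[SyntheticTranscript]) -> Dict[str, float]:
    return {t.id: t.molar_abundance for t in transcripts}


def write_fasta(transcripts: Sequence[SyntheticTranscript], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i:i + 70] + "\n")


def write_abundance_table(transcripts: Sequence[SyntheticTranscript],
                          path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\texpected_molecules\n")
        for t in transcripts:
            fh.write(f"{t.id}\t{t.molar_abundance:.6g}\n")


def write_gtf(transcripts: Sequence[SyntheticTranscript], path: str) -> None:
    """Annotation for the synthetic transcriptome: each transcript is a
    single-exon, forward-strand gene spanning its own reference sequence."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (f'gene_id "{t.id}.gene"; transcript_id "{t.id}.t1";')
            for feature in ("transcript", "exon"):
                fh.write(
                    f"{t.id}\ttagseq_sim\t{feature}\t1\t{len(t.sequence)}\t.\t+\t.\t{attrs}\n"
                )


def _int_to_umi(idx: np.ndarray, umi_len: int) -> List[str]:
    digits = np.empty((len(idx), umi_len), dtype=np.int64)
    rem = idx.copy()
    for pos in range(umi_len - 1, -1, -1):
        digits[:, pos] = rem % 4
        rem //= 4
    return ["".join(row) for row in BASES[digits]]


def _apply_errors(seqs: List[str], error_rate: float,
                  rng: np.random.Generator) -> List[str]:
    if error_rate <= 0:
        return seqs
    out = []
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype="S1").astype("U1")
        hits = rng.random(len(arr)) < error_rate
        if hits.any():
            # substitute with a uniformly chosen *different* base
            for i in np.nonzero(hits)[0]:
                choices = [b for b in "ACGT" if b != arr[i]]
                arr[i] = choices[rng.integers(0, 3)]
            out.append("".join(arr))
        else:
            out.append(s)
    return out


def simulate_library(
    transcripts: Sequence[SyntheticTranscript],
    total_molecules: int,
    n_reads: int,
    seed: int,
    capture_efficiency: float = DEFAULT_CAPTURE_EFFICIENCY,
    umi_len: int = 5,
    pcr_cycles: int = 0,
    pcr_efficiency: float = 1.0,
    error_rate: float = 0.0,
    dimer_fraction: float = 0.0,
    insert_len: int = DEFAULT_INSERT_LEN,
    fragment_window: int = DEFAULT_FRAGMENT_WINDOW,
    polya_len: int = DEFAULT_POLYA_LEN,
    with_replacement: bool = False,
    fastq_path: Optional[str] = None,
) -> tuple:
    """Simulate one tag library; returns (fastq records, SimTruth).

    The generative model: molecules are drawn multinomially by abundance;
    each is captured independently with ``capture_efficiency``; captured
    founders get an independent uniform UMI over 4^umi_len and one fragment
    position uniform over the 3'-proximal window (fixed through PCR, as in
    tag chemistry where the captured fragment is the poly(A)-adjacent one);
    each PCR cycle duplicates every library molecule independently with
    probability ``pcr_efficiency``; the sequencer samples ``n_reads`` from
    the final pool without replacement (a library aliquot) unless
    ``with_replacement`` is set.  Substitution errors are applied per base
    (UMI included) after lineages are recorded.

    fastq records are (read_id, sequence, quality) tuples; if ``fastq_path``
    is given they are also written as Phred+33 FASTQ.
    """
    if not 0 < capture_efficiency <= 1:
        raise SimulationError(f"capture efficiency {capture_efficiency} outside (0, 1]")
    if not 0 < pcr_efficiency <= 1:
        raise SimulationError(f"PCR efficiency {pcr_efficiency} outside (0, 1]")
    if not 0 <= error_rate < 1:
        raise SimulationError(f"error rate {error_rate} outside [0, 1)")
    if total_molecules <= 0 or n_reads <= 0:
        raise SimulationError("total_molecules and n_reads must be positive")

    rng = np.random.default_rng(seed)
    ids = [t.id for t in transcripts]
    abund = np.array([t.molar_abundance for t in transcripts], dtype=float)
    mol_counts = rng.multinomial(total_molecules, abund / abund.sum())
    captured = rng.binomial(mol_counts, capture_efficiency)
    n_founders = int(captured.sum())
    if n_founders == 0:
        raise SimulationError("no molecules captured; increase input or efficiency")

    founder_tidx = np.repeat(np.arange(len(ids)), captured)
    founder_umi_idx = rng.integers(0, 4 ** umi_len, size=n_founders)
    founder_umis = _int_to_umi(founder_umi_idx, umi_len)
    lengths = np.array([len(t.sequence) for t in transcripts])
    usable_end = lengths[founder_tidx] - polya_len
    win_lo = np.maximum(0, usable_end - fragment_window)
    founder_offsets = (win_lo + rng.random(n_founders)
                       * (usable_end - win_lo)).astype(np.int64)

    copies = np.ones(n_founders, dtype=np.int64)
    for _ in range(pcr_cycles):
        copies = copies + rng.binomial(copies, pcr_efficiency)
    pool = int(copies.sum())
    if not with_replacement and n_reads > pool:
        raise SimulationError(
            f"requested {n_reads} reads but the amplified pool holds only "
            f"{pool} molecules (shortfall {n_reads - pool})"
        )
    if with_replacement:
        sampled = rng.multinomial(n_reads, copies / pool)
    else:
        sampled = rng.multivariate_hypergeometric(copies, n_reads)
    read_founder = np.repeat(np.arange(n_founders), sampled)
    rng.shuffle(read_founder)

    n_dimers = int(round(dimer_fraction * n_reads))
    seqs: List[str] = []
    records = []
    lineages: Dict[str, ReadLineage] = {}
    dimer_reads: List[str] = []
    for ridx in range(n_reads):
        rid = f"read{ridx:08d}"
        if ridx < n_dimers:
            dimer_insert_len = int(rng.integers(0, 8))
            insert = "".join(rng.choice(BASES, size=dimer_insert_len))
            umi = "".join(rng.choice(BASES, size=umi_len))
            dimer_reads.append(rid)
        else:
            f = int(read_founder[ridx - n_dimers])
            tid = ids[founder_tidx[f]]
            off = int(founder_offsets[f])
            seq = transcripts[founder_tidx[f]].sequence
            insert = seq[off:off + insert_len]
            umi = founder_umis[f]
            lineages[rid] = ReadLineage(tid, f, umi, off, len(insert))
        seqs.append(umi + "GGG" + insert)
        records.append(rid)

    seqs = _apply_errors(seqs, error_rate, rng)
    fastq = [(rid, s, "I" * len(s)) for rid, s in zip(records, seqs)]

    truth = SimTruth(
        params={
            "seed": seed,
            "total_molecules": total_molecules,
            "capture_efficiency": capture_efficiency,
            "umi_len": umi_len,
            "pcr_cycles": pcr_cycles,
            "pcr_efficiency": pcr_efficiency,
            "n_reads": n_reads,
            "error_rate": error_rate,
            "dimer_fraction": dimer_fraction,
            "insert_len": insert_len,
            "fragment_window": fragment_window,
            "polya_len": polya_len,
            "with_replacement": with_replacement,
            "n_founders": n_founders,
            "pool_size": pool,
        },
        captured={tid: int(c) for tid, c in zip(ids, captured)},
        lineages=lineages,
        dimer_reads=dimer_reads,
    )
    if fastq_path:
        write_fastq(fastq, fastq_path)
    return fastq, truth


def write_fastq(records: Sequence[tuple], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_alignments(
    truth: SimTruth,
    transcripts: Sequence[SyntheticTranscript],
    sam_path: Optional[str] = None,
    umi_delimiter: str = "_",
    mapq: int = 60,
):
    """Emit idealized alignment records directly from lineage truth.

    Bypasses an external aligner: each non-dimer read aligns forward-strand
    at its recorded fragment offset on its source transcript with the given
    MAPQ.  Output is coordinate-sorted.  Returns a pysam header dict and the
    list of aligned segments; writes SAM if ``sam_path`` is given.
    """
    by_id = {t.id: t for t in transcripts}
    for lin in truth.lineages.values():
        if lin.transcript_id not in by_id:
            raise SimulationError(
                f"lineage references unknown transcript {lin.transcript_id}")
    order = {t.id: i for i, t in enumerate(transcripts)}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": t.id, "LN": len(t.sequence)} for t in transcripts],
    }
    items = sorted(truth.lineages.items(),
                   key=lambda kv: (order[kv[1].transcript_id], kv[1].offset))
    ah = pysam.AlignmentHeader.from_dict(header)
    segments = []
    for rid, lin in items:
        seg = pysam.AlignedSegment(ah)
        seg.query_name = f"{rid}{umi_delimiter}{lin.umi}"
        seg.flag = 0
        seg.reference_id = order[lin.transcript_id]
        seg.reference_start = lin.offset
        seg.mapping_quality = mapq
        seg.cigarstring = f"{lin.insert_len}M"
        seq = by_id[lin.transcript_id].sequence[lin.offset:lin.offset + lin.insert_len]
        seg.query_sequence = seq
        seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        segments.append(seg)
    if sam_path:
        with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
            for seg in segments:
                out.write(seg)
    return header, segments
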