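"""Generator ground truth: determinism, sampling moments, lineage integrity."""

import numpy as np
import pysam
import pytest

from tagseq import simdata
from tagseq.simdata import (
    SimulationError,
    make_transcriptome,
    simulate_alignments,
    simulate_library,
)


class TestTranscriptome:
    def test_span_and_count(self):
        ts = make_transcriptome(92, 6.0, seed=1)
        assert len(ts) == 92
        ab = [t.molar_abundance for t in ts]
        assert max(ab) / min(ab) == pytest.approx(1e6)

    def test_zero_span_gives_equal_abundances(self):
        ts = make_transcriptome(2, 0.0, seed=7)
        assert ts[0].molar_abundance == ts[1].molar_abundance

    def test_sequences_end_in_polya_and_are_long_enough(self):
        for t in make_transcriptome(5, 2.0, seed=3):
            assert len(t.sequence) >= 150
            assert t.sequence.endswith("A" * 20)
            assert set(t.sequence) <= set("ACGT")

    def test_deterministic_outputs(self, tmp_path):
        paths = []
        for run in (1, 2):
            ts = make_transcriptome(10, 3.0, seed=3)
            fa = tmp_path / f"run{run}.fa"
            tsv = tmp_path / f"run{run}.tsv"
            simdata.write_fasta(ts, str(fa))
            simdata.write_abundance_table(ts, str(tsv))
            paths.append((fa.read_bytes(), tsv.read_bytes()))
        assert paths[0] == paths[1]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SimulationError):
            make_transcriptome(1, 3.0, seed=1)
        with pytest.raises(SimulationError):
            make_transcriptome(5, -1.0, seed=1)


class TestLibrary:
    def test_no_amplification_reads_equal_founders(self, small_transcriptome):
        _, truth = simulate_library(
            small_transcriptome, total_molecules=2000, n_reads=1,
            seed=9, capture_efficiency=1.0, pcr_cycles=0)
        # re-run at full depth: pool == founders, so sample everything
        fastq, truth = simulate_library(
            small_transcriptome, total_molecules=2000,
            n_reads=truth.params["pool_size"], seed=9,
            capture_efficiency=1.0, pcr_cycles=0)
        assert truth.params["pool_size"] == truth.n_founders
        assert len(truth.lineages) == truth.n_founders
        founders_seen = {l.founder_id for l in truth.lineages.values()}
        assert len(founders_seen) == truth.n_founders
        keys = {(l.transcript_id, l.offset, l.umi) for l in truth.lineages.values()}
        distinct_founder_keys = len(keys)
        # distinct (position, UMI) reads equals captured molecules up to
        # exact key collisions between founders, which are possible but rare
        assert distinct_founder_keys <= truth.n_founders

    def test_umi_space_and_read_layout(self, small_transcriptome):
        fastq, truth = simulate_library(
            small_transcriptome, total_molecules=500, n_reads=50, seed=2,
            capture_efficiency=1.0, umi_len=5, pcr_cycles=0)
        assert truth.params["umi_len"] == 5
        assert 4 ** truth.params["umi_len"] == 1024
        for rid, seq, qual in fastq:
            lin = truth.lineages[rid]
            assert seq[:5] == lin.umi
            assert seq[5:8] == "GGG"
            assert len(seq) == len(qual)

    def test_deterministic_fastq(self, small_transcriptome, tmp_path):
        files = []
        for run in (1, 2):
            path = tmp_path / f"r{run}.fastq"
            simulate_library(small_transcriptome, total_molecules=1000,
                             n_reads=200, seed=5, pcr_cycles=2,
                             pcr_efficiency=0.8, error_rate=0.01,
                             fastq_path=str(path))
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_read_demand_beyond_pool_rejected(self, small_transcriptome):
        with pytest.raises(SimulationError, match="shortfall"):
            simulate_library(small_transcriptome, total_molecules=100,
                             n_reads=10_000, seed=1, capture_efficiency=0.5,
                             pcr_cycles=0)

    def test_capture_mean_matches_binomial(self, small_transcriptome):
        total, p, reps = 500, 0.3, 200
        captured = []
        for i in range(reps):
            _, truth = simulate_library(small_transcriptome,
                                        total_molecules=total, n_reads=1,
                                        seed=1000 + i, capture_efficiency=p,
                                        pcr_cycles=0)
            captured.append(truth.n_founders)
        se = np.sqrt(total * p * (1 - p) / reps)
        assert abs(np.mean(captured) - total * p) < 3 * se

    def test_pool_size_mean_matches_amplification(self, small_transcriptome):
        cycles, eff, reps = 3, 0.7, 60
        ratios = []
        for i in range(reps):
            _, truth = simulate_library(small_transcriptome,
                                        total_molecules=300, n_reads=1,
                                        seed=2000 + i, capture_efficiency=0.5,
                                        pcr_cycles=cycles, pcr_efficiency=eff)
            ratios.append(truth.params["pool_size"] / truth.n_founders)
        expected = (1 + eff) ** cycles
        se = np.std(ratios, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(ratios) - expected) < 4 * max(se, 1e-3)

    def test_nonduplicate_fraction_falls_with_input(self, small_transcriptome):
        fractions = []
        for total in (200_000, 20_000, 2_000):
            _, truth = simulate_library(
                small_transcriptome, total_molecules=total, n_reads=5_000,
                seed=77, capture_efficiency=0.3, pcr_cycles=6,
                pcr_efficiency=0.9)
            distinct = len({l.founder_id for l in truth.lineages.values()})
            fractions.append(distinct / truth.params["n_reads"])
        assert fractions == sorted(fractions, reverse=True)

    def test_dimer_injection(self, small_transcriptome):
        fastq, truth = simulate_library(
            small_transcriptome, total_molecules=2000, n_reads=200, seed=3,
            capture_efficiency=1.0, pcr_cycles=1, pcr_efficiency=1.0,
            dimer_fraction=0.1)
        assert len(truth.dimer_reads) == 20
        by_id = {rid: seq for rid, seq, _ in fastq}
        for rid in truth.dimer_reads:
            assert len(by_id[rid]) < 5 + 3 + 8


class TestAlignments:
    def test_round_trip_through_sam_reader(self, small_transcriptome, tmp_path):
        _, truth = simulate_library(small_transcriptome, total_molecules=1000,
                                    n_reads=300, seed=8, pcr_cycles=2,
                                    pcr_efficiency=0.9)
        sam = tmp_path / "sim.sam"
        simulate_alignments(truth, small_transcriptome, sam_path=str(sam))
        with pysam.AlignmentFile(str(sam)) as fh:
            segs = list(fh)
        assert len(segs) == len(truth.lineages)
        for seg in segs:
            rid, umi = seg.query_name.rsplit("_", 1)
            lin = truth.lineages[rid]
            assert seg.reference_name == lin.transcript_id
            assert seg.reference_start == lin.offset
            assert seg.mapping_quality == 60
            assert not seg.is_reverse
            assert umi == lin.umi

    def test_pcr_copies_share_alignment_key(self, small_transcriptome):
        _, truth = simulate_library(small_transcriptome, total_molecules=50,
                                    n_reads=400, seed=4,
                                    capture_efficiency=1.0, pcr_cycles=4,
                                    pcr_efficiency=0.9)
        _, segs = simulate_alignments(truth, small_transcriptome)
        key_by_founder = {}
        for seg in segs:
            rid = seg.query_name.rsplit("_", 1)[0]
            lin = truth.lineages[rid]
            key = (seg.reference_name, seg.is_reverse, seg.reference_start)
            key_by_founder.setdefault(lin.founder_id, set()).add(key)
        assert all(len(keys) == 1 for keys in key_by_founder.values())

    def test_unknown_transcript_in_lineage_rejected(self, small_transcriptome):
        _, truth = simulate_library(small_transcriptome, total_molecules=100,
                                    n_reads=20, seed=6, capture_efficiency=1.0)
        next(iter(truth.lineages.values())).transcript_id = "NOPE"
        with pytest.raises(SimulationError, match="unknown transcript"):
            simulate_alignments(truth, small_transcriptome)

    def test_truth_json_round_trip(self, small_transcriptome, tmp_path):
        _, truth = simulate_library(small_transcriptome, total_molecules=100,
                                    n_reads=30, seed=6, capture_efficiency=1.0)
        path = tmp_path / "truth.json"
        truth.to_json(str(path))
        back = simdata.SimTruth.from_json(str(path))
        assert back.captured == truth.captured
        assert back.lineages == truth.lineages
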