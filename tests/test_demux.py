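"""Barcode matcher semantics, trimming, stream partition and monotonicity."""

import numpy as np
import pytest

import aneupore.demux as dx
import aneupore.simulate as sim
from aneupore.simulate import SimRead, revcomp
from oracles import oracle_find_match


def mutate(seq: str, positions, alphabet="ACGT"):
    out = list(seq)
    for p in positions:
        out[p] = alphabet[(alphabet.index(out[p]) + 2) % 4]
    return "".join(out)


BC = "ATCGGTACCAGTTGACCTTGAGCA"  # 24 nt
INSERT100 = sim.make_toy_genome({"c": 1000}, seed=42).chromosomes["c"][:100]


class TestFindBarcodeMatch:
    def test_exact_prefix(self):
        read = BC + INSERT100
        m = dx.find_barcode_match(read, BC)
        assert m is not None
        assert (m.errors, m.start, m.stop) == (0, 0, 24)
        assert m.end == dx.FIVE_PRIME and m.strand == dx.FORWARD
        assert m.error_rate == 0.0

    def test_substitution_budget_is_floor_of_rate_times_span(self):
        # floor(0.20 * 24) = 4 errors allowed on a full-span match
        read4 = mutate(BC, [2, 7, 12, 17]) + INSERT100
        m = dx.find_barcode_match(read4, BC)
        assert m is not None and m.errors == 4
        assert m.error_rate == pytest.approx(4 / 24)
        read5 = mutate(BC, [2, 7, 12, 17, 22]) + INSERT100
        assert dx.find_barcode_match(read5, BC) is None

    def test_revcomp_at_three_prime_end(self):
        read = INSERT100 + revcomp(BC)
        m = dx.find_barcode_match(read, BC)
        assert m is not None
        assert m.end == dx.THREE_PRIME and m.strand == dx.REVCOMP
        assert (m.start, m.stop, m.errors) == (100, 124, 0)

    def test_search_flags_disable_ends_and_strands(self):
        read = INSERT100 + revcomp(BC)
        cfg = dx.DemuxConfig(search_both_ends=False)
        assert dx.find_barcode_match(read, BC, cfg) is None
        cfg = dx.DemuxConfig(search_reverse_complement=False)
        assert dx.find_barcode_match(read, BC, cfg) is None

    def test_outer_truncated_barcode_matches(self):
        # barcode hangs off the 5' end: only its last 21 bases are in the read
        read = BC[3:] + INSERT100
        m = dx.find_barcode_match(read, BC)
        assert m is not None
        assert m.errors == 0 and m.start == 0 and m.stop == 21

    def test_empty_and_short_reads_return_none(self):
        assert dx.find_barcode_match("", BC) is None
        assert dx.find_barcode_match("ACGT", BC) is None

    @pytest.mark.parametrize("n_instances", [200])
    def test_agrees_with_exhaustive_oracle(self, n_instances):
        """Spot check against the brute-force enumerator (full run in the
        acceptance suite)."""
        rng = np.random.default_rng(2024)
        bases = "ACGT"
        mismatch = 0
        for i in range(n_instances):
            m = int(rng.integers(18, 27))
            bc = "".join(bases[b] for b in rng.integers(0, 4, m))
            rlen = int(rng.integers(0, 201))
            read = "".join(bases[b] for b in rng.integers(0, 4, rlen))
            if rng.random() < 0.6 and rlen > 30:
                noisy = list(bc)
                for _ in range(int(rng.integers(0, 6))):
                    op = rng.random()
                    p = int(rng.integers(0, len(noisy)))
                    if op < 0.5:
                        noisy[p] = bases[int(rng.integers(0, 4))]
                    elif op < 0.75 and len(noisy) > 1:
                        del noisy[p]
                    else:
                        noisy.insert(p, bases[int(rng.integers(0, 4))])
                planted = "".join(noisy)
                if rng.random() < 0.5:
                    read = planted + read[len(planted):]
                else:
                    read = read[: max(0, rlen - len(planted))] + revcomp(planted)
            got = dx.find_barcode_match(read, bc)
            want = oracle_find_match(read, bc)
            got_t = None if got is None else (
                got.end, got.strand, got.start, got.stop, got.errors
            )
            if got_t != want:
                mismatch += 1
        assert mismatch == 0


@pytest.fixture(scope="module")
def bcs():
    return sim.make_barcode_set(3, seed=21)


class TestDemultiplexRead:
    def test_clean_read_assigned_and_trimmed(self, bcs):
        bc_id, bc_seq = bcs.entries[0]
        read = bc_seq + INSERT100 + revcomp(bc_seq)
        res = dx.demultiplex_read(read, bcs)
        assert res.status == dx.ASSIGNED
        assert res.barcode_id == bc_id
        assert res.trimmed_sequence == INSERT100

    def test_short_insert_is_too_short(self, bcs):
        bc_id, bc_seq = bcs.entries[1]
        read = bc_seq + INSERT100[:30] + revcomp(bc_seq)
        res = dx.demultiplex_read(read, bcs)
        assert res.status == dx.TOO_SHORT
        assert res.barcode_id == bc_id

    def test_equidistant_read_is_unassigned(self):
        # two barcodes differing at 4 positions; the read sits exactly between
        b1 = BC
        b2 = mutate(BC, [1, 6, 11, 16])
        read_bc = mutate(BC, [1, 6])  # 2 errors to each
        bcs = sim.BarcodeSet(entries=[("b1", b1), ("b2", b2)])
        res = dx.demultiplex_read(read_bc + INSERT100, bcs)
        assert res.status == dx.UNASSIGNED

    def test_five_prime_only_read_trims_one_end(self, bcs):
        bc_id, bc_seq = bcs.entries[2]
        read = bc_seq + INSERT100
        res = dx.demultiplex_read(read, bcs)
        assert res.status == dx.ASSIGNED
        assert res.trimmed_sequence == INSERT100


class TestDemultiplexStream:
    def test_empty_stream(self, barcodes):
        bins, summary = dx.demultiplex_stream([], barcodes)
        assert all(len(v) == 0 for v in bins.values())
        assert summary["n_reads"].sum() == 0

    def test_zero_noise_multiplex_fully_recovered(self, small_genome, diploid,
                                                  barcodes):
        samples, truths = [], []
        for i, (bc_id, bc_seq) in enumerate(barcodes.entries):
            cfg = sim.ReadSimConfig(n_reads=120, per_base_error=0.0, seed=30 + i)
            reads, truth = sim.simulate_sample(
                small_genome, diploid, (bc_id, bc_seq), cfg, sample_id=bc_id
            )
            samples.append(reads)
            truths.append(truth)
        pooled = sim.multiplex(samples, seed=31)
        bins, summary = dx.demultiplex_stream(pooled, barcodes)
        for bc_id, _ in barcodes.entries:
            assert {r.read_id.split("-")[0] for r in bins[bc_id]} == {bc_id}
            assert len(bins[bc_id]) == 120
        assert len(bins[dx.UNASSIGNED]) == 0

    def test_noisy_multiplex_no_cross_assignment(self, small_genome, diploid,
                                                 barcodes):
        """At 10% read error and barcode distance >= 8, reads land in their
        own bin or nowhere -- never in another sample's."""
        samples = []
        for i, entry in enumerate(barcodes.entries):
            cfg = sim.ReadSimConfig(n_reads=1000, per_base_error=0.10, seed=40 + i)
            reads, _ = sim.simulate_sample(
                small_genome, diploid, entry, cfg, sample_id=entry[0]
            )
            samples.append(reads)
        pooled = sim.multiplex(samples, seed=41)
        assert len(pooled) == 5000
        bins, summary = dx.demultiplex_stream(pooled, barcodes)
        n_assigned = 0
        for bc_id, _ in barcodes.entries:
            origins = {r.read_id.split("-")[0] for r in bins[bc_id]}
            assert origins <= {bc_id}, f"cross-assignment into {bc_id}"
            n_assigned += len(bins[bc_id])
        assert n_assigned / 5000 >= 0.9  # simulator's calibrated band
        # partition: every read in exactly one bin
        total = sum(len(v) for v in bins.values())
        assert total == 5000
        assert summary["n_reads"].sum() == 5000

    def test_partition_and_files(self, tmp_path, small_genome, diploid, barcodes):
        entry = barcodes.entries[0]
        cfg = sim.ReadSimConfig(n_reads=60, per_base_error=0.05, seed=50)
        reads, _ = sim.simulate_sample(small_genome, diploid, entry, cfg)
        bins, summary = dx.demultiplex_stream(reads, barcodes, out_dir=tmp_path)
        assert (tmp_path / f"{entry[0]}.fastq").exists()
        assert (tmp_path / "unassigned.fastq").exists()
        assert summary["n_reads"].sum() == 60


@pytest.fixture(scope="module")
def noisy_reads(small_genome, diploid):
    bset = sim.make_barcode_set(3, seed=60)
    cfg = sim.ReadSimConfig(n_reads=300, per_base_error=0.15, seed=61)
    reads, _ = sim.simulate_sample(small_genome, diploid, bset.entries[0], cfg)
    return bset, reads


class TestMonotonicity:
    def test_assigned_count_monotone_in_error_rate(self, noisy_reads):
        bcs, reads = noisy_reads
        counts = []
        for rate in (0.05, 0.10, 0.20, 0.30):
            cfg = dx.DemuxConfig(max_error_rate=rate)
            res = dx.demultiplex_reads(reads, bcs, cfg)
            counts.append(sum(r.status == dx.ASSIGNED for r in res))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_assigned_count_antitone_in_min_overlap(self, noisy_reads):
        bcs, reads = noisy_reads
        counts = []
        for overlap in (10, 16, 20, 24):
            cfg = dx.DemuxConfig(min_overlap=overlap)
            res = dx.demultiplex_reads(reads, bcs, cfg)
            counts.append(sum(r.status == dx.ASSIGNED for r in res))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestTrimmingSoundness:
    def test_zero_noise_trim_removes_all_barcode_bases(self, small_genome,
                                                       diploid, barcodes):
        entry = barcodes.entries[3]
        cfg = sim.ReadSimConfig(n_reads=100, per_base_error=0.0, seed=70)
        reads, truth = sim.simulate_sample(small_genome, diploid, entry, cfg)
        res = dx.demultiplex_reads(reads, barcodes)
        for r, (_, row) in zip(res, truth.iterrows()):
            assert r.status == dx.ASSIGNED
            chrom_seq = small_genome.chromosomes[row["chromosome"]]
            frag = chrom_seq[row["start"]: row["start"] + row["length"]]
            if row["strand"] == "-":
                frag = sim.revcomp(frag)
            assert r.trimmed_sequence == frag


class TestConfigValidation:
    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            dx.DemuxConfig(max_error_rate=0.0)

    def test_empty_barcode_set_rejected(self):
        with pytest.raises(ValueError):
            dx.demultiplex_reads(
                [SimRead("r", "ACGT" * 30, "I" * 120)],
                sim.BarcodeSet(entries=[]),
            )

    def test_window_length_rule(self):
        assert dx.DemuxConfig().window_len(24) == 29
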