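"""Synthetic-data generator: determinism, proportionality, error model."""

import math

import numpy as np
import pytest

import aneupore.simulate as sim
from aneupore.karyotype import Karyotype
from oracles import edit_distance


class TestToyGenome:
    def test_deterministic_for_fixed_seed(self):
        a = sim.make_toy_genome({"chrA": 10_000}, seed=1)
        b = sim.make_toy_genome({"chrA": 10_000}, seed=1)
        assert a.chromosomes == b.chromosomes
        assert len(a.chromosomes["chrA"]) == 10_000

    def test_different_seeds_differ(self):
        a = sim.make_toy_genome({"chrA": 10_000, "chrB": 10_000}, seed=1)
        b = sim.make_toy_genome({"chrA": 10_000, "chrB": 10_000}, seed=2)
        assert a.chromosomes["chrA"] != b.chromosomes["chrA"]

    def test_short_chromosome_rejected_by_name(self):
        with pytest.raises(ValueError, match="chrTiny"):
            sim.make_toy_genome({"chrA": 10_000, "chrTiny": 10}, seed=1)

    def test_mappable_len_cannot_exceed_sequence(self):
        with pytest.raises(ValueError):
            sim.ToyGenome(chromosomes={"c": "ACGT" * 300},
                          mappable_len={"c": 5000})

    def test_fasta_round_trip(self, tmp_path, small_genome):
        path = tmp_path / "g.fasta"
        small_genome.to_fasta(path)
        back = sim.ToyGenome.from_fasta(path)
        assert back.chromosomes == small_genome.chromosomes

    def test_default_genome_male_chry_expectation(self, default_genome):
        """A normal male's expected chrY share at 9,000 UA reads is ~41."""
        male = Karyotype.from_string("46,XY")
        counts = sim.expected_counts(default_genome, male, 9000)
        assert counts["chrY"] == pytest.approx(41.0, abs=0.2)
        # female: no chrY reads at all
        female = Karyotype.from_string("46,XX")
        assert sim.expected_counts(default_genome, female, 9000)["chrY"] == 0.0


class TestBarcodeSet:
    def test_single_barcode(self):
        bs = sim.make_barcode_set(1, seed=0)
        assert len(bs) == 1
        assert len(bs.entries[0][1]) == 24

    def test_pairwise_distance_floor_brute_force(self):
        """All 66 pairs of the 12-barcode set verified with a plain DP."""
        bs = sim.make_barcode_set(12, length=24, min_dist=8, seed=3)
        seqs = [s for _, s in bs.entries]
        assert len(seqs) == 12
        for i in range(12):
            for j in range(i + 1, 12):
                assert edit_distance(seqs[i], seqs[j]) >= 8

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            sim.make_barcode_set(0)

    def test_infeasible_combination_fails_explicitly(self):
        with pytest.raises(RuntimeError):
            sim.make_barcode_set(10, length=4, min_dist=4, seed=0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            sim.BarcodeSet(entries=[("b", "ACGT"), ("b", "TTTT")])

    def test_fasta_round_trip(self, tmp_path, barcodes):
        path = tmp_path / "bc.fasta"
        barcodes.to_fasta(path)
        assert sim.BarcodeSet.from_fasta(path).entries == barcodes.entries


class TestSimulateSample:
    def test_single_chromosome_sources_everything(self):
        g = sim.make_toy_genome({"solo": 20_000}, seed=1)
        kar = Karyotype(autosome_copies={"solo": 2}, x_copies=0, y_copies=0)
        cfg = sim.ReadSimConfig(n_reads=300, seed=2)
        _, truth = sim.simulate_sample(g, kar, None, cfg)
        assert (truth["chromosome"] == "solo").all()

    def test_source_fractions_track_copy_weighted_lengths(self):
        """Trisomic chromosome draws reads in proportion copy x mappable len."""
        g = sim.ToyGenome(
            chromosomes=sim.make_toy_genome(
                {"chrA": 5000, "chrB": 5000}, seed=4
            ).chromosomes,
            mappable_len={"chrA": 2000, "chrB": 2000},
        )
        kar = Karyotype(autosome_copies={"chrA": 2, "chrB": 3},
                        x_copies=0, y_copies=0)
        cfg = sim.ReadSimConfig(n_reads=10_000, seed=5)
        _, truth = sim.simulate_sample(g, kar, None, cfg)
        frac_b = (truth["chromosome"] == "chrB").mean()
        bound = 3 * math.sqrt(0.6 * 0.4 / 10_000)
        assert abs(frac_b - 0.6) <= bound

    def test_truth_table_is_exhaustive(self, small_genome, diploid, barcodes):
        cfg = sim.ReadSimConfig(n_reads=250, seed=6)
        reads, truth = sim.simulate_sample(
            small_genome, diploid, barcodes.entries[0], cfg, "sampleX"
        )
        assert len(reads) == len(truth) == 250
        assert truth["read_id"].is_unique
        assert set(truth["read_id"]) == {r.read_id for r in reads}
        assert (truth["sample_id"] == "sampleX").all()

    def test_zero_noise_read_is_exact_genome_substring(self, small_genome, diploid):
        cfg = sim.ReadSimConfig(
            n_reads=40, per_base_error=0.0, seed=7,
            barcode_placement="five_prime_only",
        )
        bc = ("B", "ACGTACGTACGTACGTACGTACGT")
        reads, truth = sim.simulate_sample(small_genome, diploid, bc, cfg)
        for read, (_, row) in zip(reads, truth.iterrows()):
            insert = read.sequence[len(bc[1]):]
            chrom_seq = small_genome.chromosomes[row["chromosome"]]
            frag = chrom_seq[row["start"]: row["start"] + len(insert)]
            if row["strand"] == "-":
                frag = sim.revcomp(frag)
            assert insert == frag

    def test_unknown_chromosome_rejected(self, small_genome):
        kar = Karyotype(autosome_copies={"chrZ": 3}, x_copies=0, y_copies=0)
        with pytest.raises(ValueError, match="chrZ"):
            sim.simulate_sample(
                small_genome, kar, None, sim.ReadSimConfig(n_reads=10, seed=1)
            )

    def test_byte_identical_fastq_for_fixed_seed(self, tmp_path, small_genome,
                                                 diploid, barcodes):
        cfg = sim.ReadSimConfig(n_reads=120, seed=8)
        paths = []
        for tag in ("a", "b"):
            reads, _ = sim.simulate_sample(
                small_genome, diploid, barcodes.entries[1], cfg
            )
            p = tmp_path / f"{tag}.fastq"
            sim.write_fastq(reads, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_error_rate_is_calibrated(self, small_genome, diploid):
        """Realized edit distance to the clean molecule tracks the configured rate."""
        import edlib

        cfg = sim.ReadSimConfig(n_reads=60, per_base_error=0.10, seed=9,
                                barcode_placement="five_prime_only")
        bc = ("B", "TTGGCCAATTGGCCAATTGGCCAA")
        noisy, truth = sim.simulate_sample(small_genome, diploid, bc, cfg)
        rates = []
        for read, (_, row) in zip(noisy, truth.iterrows()):
            chrom_seq = small_genome.chromosomes[row["chromosome"]]
            frag = chrom_seq[row["start"]: row["start"] + row["length"]]
            if row["strand"] == "-":
                frag = sim.revcomp(frag)
            clean = bc[1] + frag
            d = edlib.align(read.sequence, clean, mode="NW")["editDistance"]
            rates.append(d / len(clean))
        mean_rate = sum(rates) / len(rates)
        assert 0.06 <= mean_rate <= 0.13

    def test_read_lengths_respect_law(self, small_genome, diploid):
        cfg = sim.ReadSimConfig(n_reads=600, per_base_error=0.0, seed=10,
                                barcode_placement="five_prime_only")
        reads, _ = sim.simulate_sample(small_genome, diploid, None, cfg)
        lens = np.array([len(r.sequence) for r in reads])
        assert lens.min() >= 400 and lens.max() <= 2000
        assert ((lens >= 450) & (lens <= 1100)).mean() > 0.6

    def test_quality_char_matches_rate(self):
        assert sim.ReadSimConfig(per_base_error=0.1).quality_char == chr(33 + 10)
        assert sim.ReadSimConfig(per_base_error=0.0).quality_char == chr(33 + 40)


class TestMultiplex:
    def test_single_sample_preserved(self, small_genome, diploid):
        reads, _ = sim.simulate_sample(
            small_genome, diploid, None, sim.ReadSimConfig(n_reads=50, seed=1)
        )
        out = sim.multiplex([reads], seed=3)
        assert sorted(r.read_id for r in out) == sorted(r.read_id for r in reads)

    def test_conservation_across_samples(self, small_genome, diploid):
        samples = []
        for i in range(5):
            reads, _ = sim.simulate_sample(
                small_genome, diploid, None,
                sim.ReadSimConfig(n_reads=100, seed=i), sample_id=f"s{i}"
            )
            samples.append(reads)
        out = sim.multiplex(samples, seed=4)
        assert len(out) == 500
        assert sorted(r.read_id for r in out) == sorted(
            r.read_id for s in samples for r in s
        )

    def test_deterministic_interleave(self, small_genome, diploid):
        reads, _ = sim.simulate_sample(
            small_genome, diploid, None, sim.ReadSimConfig(n_reads=80, seed=1)
        )
        a = sim.multiplex([reads[:40], reads[40:]], seed=5)
        b = sim.multiplex([reads[:40], reads[40:]], seed=5)
        assert [r.read_id for r in a] == [r.read_id for r in b]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sim.multiplex([], seed=0)


class TestFastqIO:
    def test_round_trip(self, tmp_path, small_genome, diploid):
        reads, _ = sim.simulate_sample(
            small_genome, diploid, None, sim.ReadSimConfig(n_reads=30, seed=2)
        )
        p = tmp_path / "r.fastq"
        sim.write_fastq(reads, p)
        assert sim.read_fastq(p) == reads

    def test_malformed_record_names_index(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@ok\nACGT\n+\nIIII\n@broken\nACGT\n+\nIII\n")
        with pytest.raises(ValueError, match="index 1"):
            sim.read_fastq(p)
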