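"""Synthetic-data generator: determinism, error model, mixtures, spiking."""

import numpy as np
import pytest

from strainscope.consensus import qc_cascade
from strainscope.ingest import build_pileups, naive_map
from strainscope.msa import SpeciesAlignment
from strainscope.phylogeny import snv_distance
from strainscope.simulate import (
    SimConfig,
    make_marker_db,
    mix_strains,
    mutate_strain,
    simulate_reads,
    spike_background,
    write_fastq,
    read_fastq,
)

SMALL = SimConfig(seed=3, n_markers=6, coverage=6.0, read_length=100,
                  marker_length_range=(400, 500))


class TestMakeMarkerDb:
    def test_deterministic_under_seed(self, tmp_path):
        db1, _ = make_marker_db(SMALL)
        db2, _ = make_marker_db(SMALL)
        assert {m.marker_id: m.sequence for m in db1} == {
            m.marker_id: m.sequence for m in db2
        }

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            make_marker_db(SimConfig(n_markers=0))

    def test_base_composition_uniform(self):
        cfg = SimConfig(seed=9, n_markers=100, marker_length_range=(9000, 11000))
        db, _ = make_marker_db(cfg)
        seq = "".join(m.sequence for m in db)
        assert len(seq) > 900_000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.49 <= gc <= 0.51  # binomial CI at ~1e6 nt


class TestMutateStrain:
    def test_zero_rate_identity(self):
        db, truth = make_marker_db(SMALL)
        strain, planted = mutate_strain(truth.strains["base"], 0.0, seed=1)
        assert strain == truth.strains["base"]
        assert all(not v for v in planted.values())

    def test_planted_count_near_rate(self):
        db, truth = make_marker_db(
            SimConfig(seed=4, n_markers=20, marker_length_range=(900, 1100))
        )
        rate = 0.01
        _, planted = mutate_strain(truth.strains["base"], rate, seed=2)
        L = sum(len(s) for s in truth.strains["base"].values())
        count = sum(len(v) for v in planted.values())
        sigma = np.sqrt(rate * (1 - rate) * L)
        assert abs(count - rate * L) <= 3 * sigma

    def test_snv_distance_equals_planted_fraction(self):
        """Cross-module: planted substitutions / length == SNV rate exactly."""
        db, truth = make_marker_db(SMALL)
        strain, planted = mutate_strain(truth.strains["base"], 0.005, seed=5)
        base_cat = "".join(truth.strains["base"][m] for m in sorted(strain))
        strain_cat = "".join(strain[m] for m in sorted(strain))
        d = snv_distance(SpeciesAlignment("s__sim", {"base": base_cat, "mut": strain_cat}))
        expected = sum(len(v) for v in planted.values()) / len(base_cat)
        assert d[("base", "mut")] == expected


class TestSimulateReads:
    def test_zero_error_reads_are_exact_substrings(self):
        cfg = SimConfig(seed=6, n_markers=3, coverage=3.0, error_rate=0.0,
                        marker_length_range=(300, 400), read_length=80)
        db, truth = make_marker_db(cfg)
        reads, truth = simulate_reads(truth.strains["base"], cfg, seed=7,
                                      strain_name="base", truth=truth)
        comp = str.maketrans("ACGT", "TGCA")
        for read in reads:
            strain, mid, start, strand = truth.read_sources[read.name]
            ref = truth.strains["base"][mid][start : start + cfg.read_length]
            if strand == "-":
                ref = ref.translate(comp)[::-1]
            assert read.sequence == ref

    def test_error_fraction_and_quality_model(self):
        cfg = SimConfig(seed=8, n_markers=10, coverage=10.0)
        db, truth = make_marker_db(cfg)
        reads, truth = simulate_reads(truth.strains["base"], cfg, seed=9,
                                      strain_name="base", truth=truth)
        comp = str.maketrans("ACGT", "TGCA")
        mismatches = total = 0
        for read in reads:
            _, mid, start, strand = truth.read_sources[read.name]
            ref = truth.strains["base"][mid][start : start + cfg.read_length]
            if strand == "-":
                ref = ref.translate(comp)[::-1]
            for a, b, q in zip(read.sequence, ref, read.qualities):
                total += 1
                if a != b:
                    mismatches += 1
                    assert q == cfg.q_error
                else:
                    assert q == cfg.q_correct
        sigma = np.sqrt(cfg.error_rate * total)
        assert abs(mismatches - cfg.error_rate * total) <= 3 * sigma

    def test_mean_depth_near_coverage(self):
        cfg = SimConfig(seed=10, n_markers=10, coverage=8.0)
        db, truth = make_marker_db(cfg)
        reads, _ = simulate_reads(truth.strains["base"], cfg, seed=11)
        total_nt = sum(len(r.sequence) for r in reads)
        marker_nt = sum(m.length for m in db)
        assert total_nt / marker_nt == pytest.approx(cfg.coverage, rel=0.10)

    def test_fastq_round_trip_and_determinism(self, tmp_path):
        db, truth = make_marker_db(SMALL)
        reads, _ = simulate_reads(truth.strains["base"], SMALL, seed=12)
        write_fastq(reads, tmp_path / "a.fastq")
        reads2, _ = simulate_reads(truth.strains["base"], SMALL, seed=12)
        write_fastq(reads2, tmp_path / "b.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
        back = read_fastq(tmp_path / "a.fastq")
        assert [(r.name, r.sequence, r.qualities) for r in back] == [
            (r.name, r.sequence, r.qualities) for r in reads
        ]


class TestMixAndSpike:
    def test_degenerate_ratio_is_single_strain(self):
        db, truth = make_marker_db(SMALL)
        s2, _ = mutate_strain(truth.strains["base"], 0.01, seed=13)
        reads, t = mix_strains([truth.strains["base"], s2], [1.0, 0.0], SMALL, seed=14)
        assert all(t.read_sources[r.name][0] == "strain0" for r in reads)

    def test_nine_to_one_ratio(self):
        cfg = SimConfig(seed=15, n_markers=10, coverage=20.0)
        db, truth = make_marker_db(cfg)
        s2, _ = mutate_strain(truth.strains["base"], 0.01, seed=16)
        reads, t = mix_strains([truth.strains["base"], s2], [0.9, 0.1], cfg, seed=17)
        n0 = sum(t.read_sources[r.name][0] == "strain0" for r in reads)
        p_hat = n0 / len(reads)
        sigma = np.sqrt(0.9 * 0.1 / len(reads))
        assert abs(p_hat - 0.9) <= 4 * sigma

    def test_ratios_must_sum_to_one(self):
        db, truth = make_marker_db(SMALL)
        with pytest.raises(ValueError, match="sum to 1"):
            mix_strains([truth.strains["base"]], [0.5], SMALL, seed=18)

    def test_background_shares_no_seed_kmer(self):
        """Exhaustive 15-mer intersection between background and markers is empty."""
        from strainscope.simulate import _background_genome, _db_kmers, SEED_K

        db, _ = make_marker_db(SMALL)
        forbidden = _db_kmers(db)
        rng = np.random.default_rng(19)
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(3):
            g = _background_genome(rng, 3000, forbidden)
            kmers = {g[i : i + SEED_K] for i in range(len(g) - SEED_K + 1)}
            rc_kmers = {k.translate(comp)[::-1] for k in kmers}
            assert not (kmers | rc_kmers) & forbidden

    def test_background_only_sample_reports_species_absent(self):
        db, truth = make_marker_db(SMALL)
        target, _ = simulate_reads(truth.strains["base"], SMALL, seed=21)
        # keep only the background portion by spiking an empty target list
        # with a fixed absolute count via ratio on a single dummy read
        combined = spike_background(target[:30], db, SMALL, seed=22,
                                    background_ratio=10.0, n_genomes=4,
                                    genome_length=5000)
        bg_only = [r for r in combined if r.name.startswith("background")]
        assert len(bg_only) == 300
        piles = build_pileups(naive_map(bg_only, db), db)
        profile = qc_cascade(piles, "s__sim", "s1", markers_in_db=len(db))
        assert profile is None  # species gate reports absence

    def test_spiked_sample_consensus_still_accurate(self):
        cfg = SimConfig(seed=23, n_markers=6, coverage=6.0,
                        marker_length_range=(400, 500))
        db, truth = make_marker_db(cfg)
        target, _ = simulate_reads(truth.strains["base"], cfg, seed=24)
        combined = spike_background(target, db, cfg, seed=25,
                                    background_ratio=5.0, genome_length=5000)
        piles = build_pileups(naive_map(combined, db), db)
        profile = qc_cascade(piles, "s__sim", "s1", markers_in_db=len(db))
        assert profile is not None
        errors = compared = 0
        for mid, cm in profile.markers.items():
            ref = truth.strains["base"][mid][50:-50]
            for a, b in zip(cm.sequence, ref):
                if a != "N":
                    compared += 1
                    errors += a != b
        assert compared > 1000
        assert errors / compared < 0.002


class TestEndToEndOracle:
    def test_zero_error_pipeline_recovers_strain_exactly(self):
        cfg = SimConfig(seed=26, n_markers=5, coverage=15.0, error_rate=0.0,
                        marker_length_range=(400, 500), read_length=100)
        db, truth = make_marker_db(cfg)
        strain, _ = mutate_strain(truth.strains["base"], 0.005, seed=27)
        reads, _ = simulate_reads(strain, cfg, seed=28)
        piles = build_pileups(naive_map(reads, db), db)
        profile = qc_cascade(piles, "s__sim", "s1", markers_in_db=len(db))
        assert profile is not None
        for mid, cm in profile.markers.items():
            ref = strain[mid][50:-50]
            called = [(a, b) for a, b in zip(cm.sequence, ref) if a != "N"]
            assert all(a == b for a, b in called)
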