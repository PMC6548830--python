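import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybscan import (
    ConfigError,
    LayoutError,
    OriginState,
    SPECIES_A,
    SimulationConfig,
    simulate_cohort,
    simulate_hybrid,
    simulate_parents,
    simulate_reads,
)
from hybscan.datatypes import N_CODE
from hybscan.simulate import simulate_read_counts


class TestConfigValidation:
    def test_probs_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(genome_length=1000, n_groups=0, origin_state_probs={"CC": 0.5})

    def test_divergence_bounds(self):
        with pytest.raises(ConfigError):
            SimulationConfig(genome_length=1000, n_groups=0, divergence=0.8)

    def test_depth_positive(self):
        with pytest.raises(ConfigError):
            SimulationConfig(genome_length=1000, n_groups=0, depth=0.0)

    def test_copy_numbers_integral(self):
        with pytest.raises(ConfigError):
            SimulationConfig(genome_length=1000, n_groups=0, cnv_specs=(("g1", 1.5),))

    def test_unknown_state_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(genome_length=1000, n_groups=0, origin_state_probs={"XX": 1.0})

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(genome_length=5000, n_groups=2, seed=9, cnv_specs=(("g0001", 3),))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestSimulateParents:
    def test_zero_divergence_identity(self):
        cfg = SimulationConfig(genome_length=20_000, n_groups=5, divergence=0.0, seed=1)
        pa, pb, _ = simulate_parents(cfg)
        assert np.array_equal(pa.chroms["chr1"], pb.chroms["chr1"])

    def test_divergence_within_binomial_bounds(self):
        cfg = SimulationConfig(genome_length=100_000, n_groups=0, divergence=0.10, seed=2)
        pa, pb, _ = simulate_parents(cfg)
        observed = float((pa.chroms["chr1"] != pb.chroms["chr1"]).mean())
        sd = np.sqrt(0.10 * 0.90 / 100_000)
        assert abs(observed - 0.10) < 3 * sd

    def test_orf_count_and_layout(self):
        cfg = SimulationConfig(genome_length=1_000_000, n_groups=200, orf_length_range=(500, 1500), seed=3)
        _, _, ann = simulate_parents(cfg)
        orfs = ann[ann["species"] == SPECIES_A].sort_values("start")
        assert len(orfs) == 200
        # non-overlapping
        assert (orfs["start"].to_numpy()[1:] >= orfs["end"].to_numpy()[:-1]).all()
        assert (orfs["length"] == orfs["end"] - orfs["start"]).all()

    def test_shared_coordinates_across_species(self):
        cfg = SimulationConfig(genome_length=50_000, n_groups=10, seed=4)
        _, _, ann = simulate_parents(cfg)
        by_species = {sp: sub.set_index("group_id")[["start", "end"]] for sp, sub in ann.groupby("species")}
        a, b = by_species.values()
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_impossible_layout_raises(self):
        cfg = SimulationConfig(genome_length=5_000, n_groups=100, orf_length_range=(500, 1500), seed=5)
        with pytest.raises(LayoutError):
            simulate_parents(cfg)


class TestSimulateHybrid:
    def test_all_cc_identical_to_parent_a(self):
        cfg = SimulationConfig(genome_length=30_000, n_groups=10, origin_state_probs={"CC": 1.0}, seed=6)
        pa, pb, ann = simulate_parents(cfg)
        hybrids, truth = simulate_hybrid((pa, pb), ann, cfg)
        strain = hybrids[0].strain
        assert np.array_equal(hybrids[0].consensus.chroms["chr1"], pa.chroms["chr1"])
        assert truth.foreign_fraction[strain] == 0.0

    def test_all_pp_foreign_fraction_one(self):
        cfg = SimulationConfig(
            genome_length=30_000, n_groups=5, origin_state_probs={"PP": 1.0},
            foreign_block_mode="contiguous", seed=7,
        )
        pa, pb, ann = simulate_parents(cfg)
        hybrids, truth = simulate_hybrid((pa, pb), ann, cfg)
        assert truth.foreign_fraction[hybrids[0].strain] == pytest.approx(1.0)
        assert np.array_equal(hybrids[0].consensus.chroms["chr1"], pb.chroms["chr1"])

    def test_blocks_tile_genome(self, small_config):
        pa, pb, ann = simulate_parents(small_config)
        hybrids, truth = simulate_hybrid((pa, pb), ann, small_config)
        blocks = truth.blocks[hybrids[0].strain].sort_values("start")
        assert blocks["start"].iloc[0] == 0
        assert blocks["end"].iloc[-1] == small_config.genome_length
        assert (blocks["start"].to_numpy()[1:] == blocks["end"].to_numpy()[:-1]).all()

    def test_foreign_fraction_matches_blocks(self, small_config):
        pa, pb, ann = simulate_parents(small_config)
        hybrids, truth = simulate_hybrid((pa, pb), ann, small_config)
        blocks = truth.blocks[hybrids[0].strain]
        lens = blocks["end"] - blocks["start"]
        expected = (
            lens[blocks["origin"] == "PP"].sum() + 0.5 * lens[blocks["origin"] == "CP"].sum()
        ) / small_config.genome_length
        assert truth.foreign_fraction[hybrids[0].strain] == pytest.approx(expected, abs=1e-9)

    def test_contiguous_mode_hits_target_fraction_on_average(self):
        # mean over 20 seeds of the realized foreign fraction ~ P(PP) = 0.037
        fractions = []
        for seed in range(20):
            cfg = SimulationConfig(
                genome_length=1_000_000, n_groups=0, origin_state_probs={"CC": 0.963, "PP": 0.037},
                foreign_block_mode="contiguous", mean_block_length=10_000, seed=seed,
            )
            pa, pb, ann = simulate_parents(cfg)
            hybrids, truth = simulate_hybrid((pa, pb), ann, cfg)
            fractions.append(truth.foreign_fraction[hybrids[0].strain])
        assert abs(np.mean(fractions) - 0.037) < 0.01

    def test_cp_consensus_masks_divergent_sites(self):
        cfg = SimulationConfig(genome_length=20_000, n_groups=3, origin_state_probs={"CP": 1.0}, seed=8)
        pa, pb, ann = simulate_parents(cfg)
        hybrids, _ = simulate_hybrid((pa, pb), ann, cfg)
        con = hybrids[0].consensus.chroms["chr1"]
        a, b = pa.chroms["chr1"], pb.chroms["chr1"]
        orf = ann[ann["species"] == SPECIES_A].iloc[0]
        seg = slice(int(orf["start"]), int(orf["end"]))
        diff = a[seg] != b[seg]
        assert (con[seg][diff] == N_CODE).all()
        assert np.array_equal(con[seg][~diff], a[seg][~diff])


class TestSimulateReadCounts:
    def test_poisson_mean_cc(self):
        # depth 20, 1000 bp ORF, 250 bp reads, CC, m=0 -> mean 80 to A, 0 to B
        cfg = SimulationConfig(
            genome_length=200_000, n_groups=100, orf_length_range=(1000, 1000),
            origin_state_probs={"CC": 1.0}, depth=20.0, seed=9,
        )
        pa, pb, ann, hybrids, tables, _, _ = simulate_cohort(cfg)
        counts = tables[hybrids[0].strain].counts
        a = counts[counts["species"] == SPECIES_A]["count"]
        b = counts[counts["species"] != SPECIES_A]["count"]
        assert b.sum() == 0
        assert abs(a.mean() - 80) < 3 * np.sqrt(80 / len(a))

    def test_misassignment_rate(self):
        cfg = SimulationConfig(
            genome_length=400_000, n_groups=200, orf_length_range=(1000, 1000),
            origin_state_probs={"PP": 1.0}, depth=20.0, misassign_rate=0.05, seed=10,
        )
        pa, pb, ann, hybrids, tables, _, _ = simulate_cohort(cfg)
        counts = tables[hybrids[0].strain].counts
        to_a = counts[counts["species"] == SPECIES_A]["count"].sum()
        total = counts["count"].sum()
        assert to_a / total == pytest.approx(0.05, abs=0.01)

    def test_cnv_depth_mean(self):
        cfg = SimulationConfig(
            genome_length=60_000, n_groups=10, orf_length_range=(1000, 1000),
            depth=20.0, cnv_specs=(("g0001", 15),), seed=11,
        )
        pa, pb, ann, hybrids, _, profiles, _ = simulate_cohort(cfg)
        orf = ann[(ann["group_id"] == "g0001") & (ann["species"] == SPECIES_A)].iloc[0]
        gene_depth = profiles[hybrids[0].strain].depths["chr1"][orf["start"]: orf["end"]]
        sd = np.sqrt(300 / len(gene_depth))
        assert abs(gene_depth.mean() - 300) < 3 * sd

    def test_count_conservation_chi_square(self):
        # per-ORF counts are Poisson at their stated means (GOF across 100 ORFs)
        cfg = SimulationConfig(
            genome_length=300_000, n_groups=100, orf_length_range=(800, 1600),
            origin_state_probs={"CC": 1.0}, depth=20.0, seed=12,
        )
        pa, pb, ann, hybrids, tables, _, _ = simulate_cohort(cfg)
        counts = tables[hybrids[0].strain].counts
        orfs = ann[ann["species"] == SPECIES_A].set_index("group_id")
        sub = counts[counts["species"] == SPECIES_A].set_index("group_id")
        lam = cfg.depth * orfs["length"] / cfg.read_length
        statistic = (((sub["count"] - lam) ** 2) / lam).sum()
        assert stats.chi2.sf(statistic, df=100) > 0.01


class TestReads:
    def test_read_lengths_and_alphabet(self, small_config):
        pa, pb, ann = simulate_parents(small_config)
        hybrids, _ = simulate_hybrid((pa, pb), ann, small_config)
        reads = simulate_reads(hybrids[0], (pa, pb), ann, small_config)
        assert reads
        assert all(len(seq) == small_config.read_length for _, seq in reads)
        assert set("".join(seq for _, seq in reads[:50])) <= set("ACGT")

    def test_read_names_encode_position(self, small_config):
        pa, pb, ann = simulate_parents(small_config)
        hybrids, _ = simulate_hybrid((pa, pb), ann, small_config)
        name, seq = simulate_reads(hybrids[0], (pa, pb), ann, small_config)[0]
        strain, chrom, start, hap, _ = name.split("|")
        hap_genomes = hybrids[0].haplotypes(pa, pb)
        source = hap_genomes[0 if hap == "hap1" else 1]
        segment = source.chroms[chrom][int(start): int(start) + len(seq)]
        assert segment.tobytes().decode() == seq


class TestReproducibility:
    def test_identical_seed_identical_outputs(self, small_config):
        out1 = simulate_cohort(small_config)
        out2 = simulate_cohort(small_config)
        assert np.array_equal(out1[0].chroms["chr1"], out2[0].chroms["chr1"])
        assert np.array_equal(out1[1].chroms["chr1"], out2[1].chroms["chr1"])
        pd.testing.assert_frame_equal(out1[2], out2[2])
        s = out1[3][0].strain
        pd.testing.assert_frame_equal(out1[4][s].counts, out2[4][s].counts)
        assert np.array_equal(out1[5][s].depths["chr1"], out2[5][s].depths["chr1"])

    def test_different_seed_differs(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        g1 = simulate_cohort(small_config)[0].chroms["chr1"]
        g2 = simulate_cohort(other)[0].chroms["chr1"]
        assert not np.array_equal(g1, g2)
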