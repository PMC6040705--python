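"""The generator must be deterministic, log every injection, and plant
exactly the structures the downstream stages assume."""

import numpy as np
import pytest

from wgs_bakeoff.masks import revcomp
from wgs_bakeoff.synth import (DEFAULT_CAUSAL_PATTERN, SimulationConfig,
                               make_reference, simulate_annotation_table,
                               simulate_center_callsets, simulate_cn_profile,
                               simulate_read_pairs)


class TestConfig:
    def test_validation_rejects_bad_geometry(self):
        with pytest.raises(ValueError, match="geometry"):
            SimulationConfig(insert_size_mean=100).validate()
        with pytest.raises(ValueError, match="genome_length"):
            SimulationConfig(genome_length=1000).validate()
        with pytest.raises(ValueError, match="outside"):
            SimulationConfig(base_error_rate=1.5).validate()
        with pytest.raises(ValueError, match="out of bounds"):
            SimulationConfig(planted_sds=[("chr1", 0, 10**9, 4.0)]).validate()


class TestReference:
    def test_deterministic_and_sized(self):
        cfg = SimulationConfig(genome_length=50_000, seed=1)
        ref1, _ = make_reference(cfg)
        ref2, _ = make_reference(cfg)
        assert list(ref1) == ["chr1"]
        assert len(ref1["chr1"]) == 50_000
        assert ref1 == ref2

    def test_planted_duplicate_occurs_twice(self, reference):
        ref, truth = reference
        (chrom, ivs), = truth.duplications.intervals.items()
        s, e = ivs[0]
        segment = ref[chrom][s:e]
        assert ref[chrom].count(segment) >= 2

    def test_homopolymer_truth_interval(self):
        cfg = SimulationConfig(genome_length=50_000, seed=2)
        ref, truth = make_reference(cfg, homopolymer_length=10)
        (chrom, ivs), = truth.homopolymers.intervals.items()
        s, e = ivs[0]
        assert e - s == 10
        assert ref[chrom][s:e] == "A" * 10
        # maximal run: flanks differ
        assert ref[chrom][s - 1] != "A" and ref[chrom][e] != "A"

    def test_too_short_for_features(self):
        with pytest.raises(ValueError, match="too short"):
            # 500 bp per chromosome cannot host a 300 bp duplicate twice
            make_reference(SimulationConfig(genome_length=1_500,
                                            n_chromosomes=3, seed=0))


class TestReads:
    def test_pair_count_matches_coverage(self, read_sim, small_config):
        pairs, _ = read_sim
        cfg = small_config
        expected = cfg.coverage * cfg.genome_length / (2 * cfg.read_length)
        assert abs(len(pairs) - expected) / expected < 0.01

    def test_zero_noise_reads_are_reference_substrings(self):
        cfg = SimulationConfig(genome_length=20_000, seed=5, coverage=2.0,
                               base_error_rate=0.0, adapter_rate=0.0,
                               n_rate=0.0, low_quality_rate=0.0)
        ref, _ = make_reference(cfg)
        pairs, _ = simulate_read_pairs(ref, cfg)
        genome = ref["chr1"]
        rc = revcomp(genome)
        for p in pairs[:200]:
            assert p.seq1 in genome or p.seq1 in rc
            assert p.seq2 in genome or p.seq2 in rc

    def test_adapter_injection_rate(self):
        cfg = SimulationConfig(genome_length=60_000, seed=6, coverage=20.0,
                               adapter_rate=0.006)
        ref, _ = make_reference(cfg)
        pairs, log = simulate_read_pairs(ref, cfg)
        n = len(pairs)
        frac = len(log.adapter_pairs) / n
        se = np.sqrt(0.006 * 0.994 / n)
        assert abs(frac - 0.006) < 4 * se

    def test_deterministic_fastq(self, small_config, reference):
        p1, _ = simulate_read_pairs(reference[0], small_config)
        p2, _ = simulate_read_pairs(reference[0], small_config)
        assert p1[:50] == p2[:50] and p1[-1] == p2[-1]


class TestCallsets:
    def test_zero_noise_replicates_identical(self, reference, design):
        cfg = SimulationConfig(genome_length=50_000, seed=3,
                               n_variant_sites=300, mendel_error_rate=0.0,
                               per_center_discordance=0.0)
        sim = simulate_center_callsets(reference[0], design, cfg)
        assert sim.corruption_log.empty
        for rep in sim.replicates:
            assert [r.genotypes for r in rep.records] == \
                   [r.genotypes for r in sim.truth.records]

    def test_trio_brute_force_mendel_clean(self, reference, design):
        cfg = SimulationConfig(genome_length=50_000, seed=4,
                               n_variant_sites=500, mendel_error_rate=0.0)
        sim = simulate_center_callsets(reference[0], design, cfg,
                                       plant_causal=False)
        child, father, mother = design.trio
        ci, fi, mi = (sim.truth.sample_index(s) for s in design.trio)
        violations = 0
        for rec in sim.truth.records:
            c, f, m = rec.genotypes[ci], rec.genotypes[fi], rec.genotypes[mi]
            ok = False  # brute force over ordered parental assignments
            for a, b in (c, c[::-1]):
                if a in f and b in m:
                    ok = True
            violations += not ok
        assert violations == 0

    def test_corruption_log_reconciles_exactly(self, callset_sim):
        sim = callset_sim
        samples = sim.truth.samples
        observed = set()
        for ci, rep in enumerate(sim.replicates):
            truth_by_key = sim.truth.by_key()
            for rec in rep.records:
                t = truth_by_key.get(rec.key())
                assert t is not None
                for si, s in enumerate(samples):
                    if rec.genotypes[si] != t.genotypes[si]:
                        observed.add((f"center{ci + 1}", rec.pos, s))
        logged = {(r.center, r.pos, r.sample)
                  for r in sim.corruption_log.itertuples()}
        assert observed == logged

    def test_discordance_rate_recovered(self, callset_sim, small_config):
        sim = callset_sim
        n_slots = len(sim.truth) * len(sim.truth.samples)
        for center, rate in (("center2", 0.01), ("center3", 0.02)):
            n_corr = (sim.corruption_log["center"] == center).sum()
            se = np.sqrt(rate * (1 - rate) / n_slots)
            assert abs(n_corr / n_slots - rate) < 3 * se + 1 / n_slots

    def test_planted_causal_column(self, callset_sim, design):
        sim = callset_sim
        rec = next(r for r in sim.truth.records if r.pos == sim.causal_pos)
        assert len(rec.alts[0]) == len(rec.ref) + 1  # single-base insertion
        for s, gt in DEFAULT_CAUSAL_PATTERN.items():
            assert sim.truth.genotype(rec, s) == tuple(sorted(gt))

    def test_array_is_truth_subset(self, callset_sim):
        sim = callset_sim
        by_key = sim.truth.by_key()
        for row in sim.array.itertuples(index=False):
            key = next(k for k in by_key
                       if k.pos == row.pos and k.chrom == row.chrom)
            rec = by_key[key]
            for si, s in enumerate(sim.truth.samples):
                gt = rec.genotypes[si]
                assert getattr(row, s) == f"{gt[0]}/{gt[1]}"


class TestCnProfile:
    def test_dispersion_zero_exact_baseline(self):
        df = simulate_cn_profile(30_000, ["s1"], {}, coverage=30.0,
                                 dispersion=0.0, seed=1)
        assert np.allclose(df["depth"], 30.0)

    def test_planted_cn4_doubles_depth(self):
        planted = {"s1": [("chr1", 10_000, 20_000, 4.0)]}
        df = simulate_cn_profile(30_000, ["s1"], planted, coverage=30.0,
                                 dispersion=0.0, seed=1)
        inside = df[(df.start >= 10_000) & (df.end <= 20_000)]
        outside = df[(df.start < 10_000) | (df.end > 20_000)]
        assert np.allclose(inside["depth"], 60.0)
        assert np.allclose(outside["depth"], 30.0)

    def test_normalized_mean_near_two_without_sds(self):
        from wgs_bakeoff.cnv import compute_cn
        df = simulate_cn_profile(100_000, ["s1"], {}, dispersion=0.15, seed=2)
        profile = compute_cn(df)
        assert profile.mean_cn == pytest.approx(2.0)
        assert abs(float(profile.windows["cn"].mean()) - 2.0) < 0.05


class TestAnnotation:
    def test_causal_row_is_rare_lof(self, annotation, callset_sim):
        row = annotation[annotation["pos"] == callset_sim.causal_pos].iloc[0]
        assert row["lof_confidence"] == "high"
        assert np.isnan(row["maf_1000g"]) and np.isnan(row["maf_exac"])
        assert row["maf_gnomad"] < 0.01
        assert row["gene"] == "FTCD"

    def test_lof_fraction_binomial(self, annotation, small_config):
        bg = annotation[annotation["gene"] != "FTCD"]
        n = len(bg)
        frac = (bg["lof_confidence"] == "high").mean()
        p = small_config.lof_fraction
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_zero_lof_fraction_leaves_only_causal(self, reference, design):
        cfg = SimulationConfig(genome_length=50_000, seed=9,
                               n_variant_sites=200, lof_fraction=0.0)
        sim = simulate_center_callsets(reference[0], design, cfg)
        ann = simulate_annotation_table(sim.truth, design, cfg, sim.causal_pos)
        high = ann[ann["lof_confidence"] == "high"]
        assert len(high) == 1 and high.iloc[0]["pos"] == sim.causal_pos

    def test_deterministic(self, callset_sim, design, small_config):
        a1 = simulate_annotation_table(callset_sim.truth, design, small_config,
                                       callset_sim.causal_pos)
        a2 = simulate_annotation_table(callset_sim.truth, design, small_config,
                                       callset_sim.causal_pos)
        assert a1.equals(a2)
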