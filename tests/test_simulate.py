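import numpy as np
import pytest

from regulocus.errors import ConfigError, InvalidAlphabetError, ViewpointResolutionError
from regulocus.fragmap import digest, find_motif_positions
from regulocus.genomeio import write_fasta
from regulocus.intervals import GenomicInterval
from regulocus.simulate import (
    SimConfig,
    decay_weights,
    expected_4c_lambda,
    fragment_map_for,
    make_genome,
    make_locus,
    simulate_4c,
    simulate_enhancer_signal,
    simulate_nucleus_matrix,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        SimConfig()

    def test_bad_motif_rejected(self):
        with pytest.raises(InvalidAlphabetError):
            SimConfig(cutter_motif="GAXC")

    def test_unsorted_tads_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(tad_boundaries=(500_000, 200_000))

    def test_se_spanning_tad_boundary_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(se_interval=GenomicInterval("chrS", 440_000, 460_000))

    def test_accessibility_effect_below_one_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(accessibility_effect=0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"decay_exponent": 0},
            {"dispersion": 0},
            {"loop_enrichment": -1},
            {"genome_length": 0},
        ],
    )
    def test_invalid_numerics_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)


class TestMakeGenome:
    def test_deterministic_fasta(self, tmp_path, small_config):
        seq1, pos1 = make_genome(small_config)
        seq2, pos2 = make_genome(small_config)
        assert seq1 == seq2
        assert np.array_equal(pos1, pos2)
        paths = []
        for i, seq in enumerate((seq1, seq2)):
            path = tmp_path / f"g{i}.fa"
            write_fasta(path, {"chrS": seq})
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_planted_positions_match_exhaustive_scan(self, small_config, small_genome):
        sequence, positions = small_genome
        found = find_motif_positions(sequence, small_config.cutter_motif)
        assert set(found.tolist()) == set(positions.tolist())

    def test_mean_spacing_near_target(self, small_config, small_genome):
        _, positions = small_genome
        spacing = np.diff(positions)
        assert spacing.mean() == pytest.approx(
            small_config.motif_spacing_mean, rel=0.15
        )

    def test_zero_motifs_single_fragment(self):
        config = SimConfig(
            genome_length=600_000,
            tad_boundaries=(),
            motif_spacing_mean=1e12,
            seed=2,
        )
        sequence, positions = make_genome(config)
        assert len(positions) == 0
        fmap = digest(sequence, config.cutter_motif)
        assert len(fmap) == 1
        assert (fmap[0].start, fmap[0].end) == (0, config.genome_length)

    def test_self_overlapping_motif_still_exact(self):
        config = SimConfig(
            genome_length=20_000,
            cutter_motif="AAAA",
            tad_boundaries=(),
            se_interval=GenomicInterval("chrS", 5_000, 15_000),
            motif_spacing_mean=300,
            seed=5,
        )
        sequence, positions = make_genome(config)
        found = find_motif_positions(sequence, "AAAA")
        assert set(found.tolist()) == set(positions.tolist())


class TestSimulate4C:
    def test_lambda_matches_closed_form(self, small_config, small_fragmap, small_locus):
        config = small_config
        viewpoint = small_locus.viewpoint_for("gene1")
        lam = expected_4c_lambda(config, small_fragmap, viewpoint, "B")
        # independent evaluation of N * w_i / sum(w) with w from the stated
        # formula (alpha=1 default, d0=1000, beta on A only)
        from regulocus.fragmap import locate_viewpoint

        vp_idx = locate_viewpoint(small_fragmap, viewpoint)
        mids = small_fragmap.midpoints.astype(float)
        w = (np.abs(mids - mids[vp_idx]) + config.decay_offset) ** (
            -config.decay_exponent
        )
        w[vp_idx] = 0.0
        expected = config.read_depth * w / w.sum()
        np.testing.assert_allclose(lam, expected, rtol=1e-12)

    def test_lambda_sums_to_depth(self, small_config, small_fragmap, small_locus):
        for condition in ("A", "B"):
            lam = expected_4c_lambda(
                small_config,
                small_fragmap,
                small_locus.viewpoint_for("gene1"),
                condition,
            )
            assert lam.sum() == pytest.approx(small_config.read_depth, rel=1e-9)

    def test_loop_enrichment_applied_to_se_only(
        self, small_config, small_fragmap, small_locus
    ):
        config = small_config
        viewpoint = small_locus.viewpoint_for("gene1")
        w_a = decay_weights(config, small_fragmap, viewpoint, "A")
        w_b = decay_weights(config, small_fragmap, viewpoint, "B")
        mids = small_fragmap.midpoints
        in_se = (mids >= config.se_interval.start) & (mids < config.se_interval.end)
        ratio = w_a[in_se] / w_b[in_se]
        np.testing.assert_allclose(ratio, 1.0 + config.loop_enrichment, rtol=1e-12)
        out_se = ~in_se
        out_se[small_fragmap.fragment_at(viewpoint.midpoint)] = False
        np.testing.assert_allclose(w_a[out_se], w_b[out_se], rtol=1e-12)

    def test_viewpoint_fragment_gets_zero(
        self, small_config, small_fragmap, small_locus
    ):
        viewpoint = small_locus.viewpoint_for("gene1")
        lam = expected_4c_lambda(small_config, small_fragmap, viewpoint, "A")
        from regulocus.fragmap import locate_viewpoint

        assert lam[locate_viewpoint(small_fragmap, viewpoint)] == 0.0

    def test_straddling_viewpoint_rejected(self, small_config, small_fragmap):
        cut = int(small_fragmap.starts[10])
        viewpoint = GenomicInterval(small_fragmap.chrom, cut - 5, cut + 5)
        with pytest.raises(ViewpointResolutionError):
            simulate_4c(small_config, small_fragmap, viewpoint, "A")

    def test_poisson_limit_variance(self):
        """dispersion -> infinity: sampled variance approaches lambda."""
        config = SimConfig(
            genome_length=20_000,
            tad_boundaries=(),
            se_interval=GenomicInterval("chrS", 5_000, 15_000),
            motif_spacing_mean=1000,
            read_depth=50_000,
            dispersion=1e9,
            seed=3,
        )
        _, positions = make_genome(config)
        fmap = fragment_map_for(config, positions)
        viewpoint = GenomicInterval("chrS", int(fmap.starts[1]), int(fmap.starts[1]) + 1)
        lam = expected_4c_lambda(config, fmap, viewpoint, "B")
        target = int(np.argmax(lam * (lam < lam.max())))  # a well-populated fragment
        rng = np.random.default_rng(99)
        draws = np.array(
            [
                simulate_4c(config, fmap, viewpoint, "B", rng).values[target]
                for _ in range(10_000)
            ]
        )
        assert draws.mean() == pytest.approx(lam[target], rel=0.05)
        assert draws.var() == pytest.approx(lam[target], rel=0.1)

    def test_overdispersion_above_poisson(self):
        config = SimConfig(
            genome_length=20_000,
            tad_boundaries=(),
            se_interval=GenomicInterval("chrS", 5_000, 15_000),
            motif_spacing_mean=1000,
            read_depth=50_000,
            dispersion=2.0,
            seed=3,
        )
        _, positions = make_genome(config)
        fmap = fragment_map_for(config, positions)
        viewpoint = GenomicInterval("chrS", int(fmap.starts[1]), int(fmap.starts[1]) + 1)
        lam = expected_4c_lambda(config, fmap, viewpoint, "B")
        target = int(np.argmax(lam * (lam < lam.max())))
        rng = np.random.default_rng(7)
        draws = np.array(
            [
                simulate_4c(config, fmap, viewpoint, "B", rng).values[target]
                for _ in range(4000)
            ]
        )
        mu = lam[target]
        expected_var = mu + mu**2 / config.dispersion
        assert draws.var() == pytest.approx(expected_var, rel=0.15)
        assert draws.var() > 1.5 * mu

    def test_null_se_sign_fraction_near_half(
        self, small_config, small_fragmap, small_locus
    ):
        """beta = 0: condition A beats B on ~50% of enhancer-region
        fragments (aggregated over pairs for a tight estimate)."""
        config = SimConfig(
            **{
                **{f: getattr(small_config, f) for f in (
                    "genome_length", "tad_boundaries", "se_interval",
                    "n_genes", "n_nuclei_per_class", "read_depth", "seed",
                )},
                "loop_enrichment": 0.0,
            }
        )
        viewpoint = small_locus.viewpoint_for("gene1")
        mids = small_fragmap.midpoints
        in_se = (mids >= config.se_interval.start) & (mids < config.se_interval.end)
        rng = np.random.default_rng(123)
        wins = trials = 0
        for _ in range(30):
            a = simulate_4c(config, small_fragmap, viewpoint, "A", rng).values
            b = simulate_4c(config, small_fragmap, viewpoint, "B", rng).values
            diff = a[in_se] - b[in_se]
            wins += int(np.sum(diff > 0))
            trials += int(np.sum(diff != 0))
        assert wins / trials == pytest.approx(0.5, abs=0.03)


class TestEnhancerSignal:
    def test_seven_planted_peaks(self):
        peaks, planted = simulate_enhancer_signal(SimConfig(seed=1))
        assert int(planted.sum()) == 7

    def test_planted_inside_se_with_small_gaps(self):
        config = SimConfig(seed=1)
        peaks, planted = simulate_enhancer_signal(config)
        cluster = [p for p, flag in zip(peaks, planted) if flag]
        for p in cluster:
            assert config.se_interval.contains_interval(p.interval)
        starts = [p.interval.start for p in cluster]
        ends = [p.interval.end for p in cluster]
        gaps = [s - e for s, e in zip(starts[1:], ends[:-1])]
        assert all(0 < g < 12_500 for g in gaps)

    def test_planted_signal_dominates(self):
        peaks, planted = simulate_enhancer_signal(SimConfig(seed=2))
        background = [p.signal for p, flag in zip(peaks, planted) if not flag]
        cluster = [p.signal for p, flag in zip(peaks, planted) if flag]
        assert min(cluster) >= 10 * np.mean(background)
        assert sum(cluster) > max(background)

    def test_sorted_non_overlapping_pairwise(self):
        peaks, _ = simulate_enhancer_signal(SimConfig(seed=3))
        starts = [p.interval.start for p in peaks]
        assert starts == sorted(starts)
        for i in range(len(peaks)):  # O(n^2) overlap oracle
            for j in range(i + 1, len(peaks)):
                assert not peaks[i].interval.overlaps(peaks[j].interval)

    def test_at_least_30_background(self):
        peaks, planted = simulate_enhancer_signal(SimConfig(seed=1))
        assert int((~planted).sum()) >= 30

    def test_se_too_short_rejected(self):
        config = SimConfig(
            genome_length=100_000,
            tad_boundaries=(),
            se_interval=GenomicInterval("chrS", 50_000, 51_000),
            peak_width=500,
            seed=1,
        )
        with pytest.raises(ConfigError):
            simulate_enhancer_signal(config)

    def test_deterministic(self):
        a_peaks, a_flags = simulate_enhancer_signal(SimConfig(seed=6))
        b_peaks, b_flags = simulate_enhancer_signal(SimConfig(seed=6))
        assert np.array_equal(a_flags, b_flags)
        assert [(p.interval.start, p.signal) for p in a_peaks] == [
            (p.interval.start, p.signal) for p in b_peaks
        ]


class TestNucleusMatrix:
    def test_default_class_sizes_sum(self):
        table = simulate_nucleus_matrix(SimConfig(seed=1))
        assert len(table) == 867  # 64 + 59 + 249 + 495
        assert table["true_label"].value_counts().to_dict() == {
            "gene4": 495,
            "gene3": 249,
            "gene2": 59,
            "gene1": 64,
        }

    def test_qc_fail_fraction_planted(self):
        from regulocus.nucleus import qc_filter

        config = SimConfig(seed=21, qc_fail_fraction=0.1)
        table = simulate_nucleus_matrix(config)
        _, tally = qc_filter(table)
        kept, _ = qc_filter(table)
        fail_fraction = 1 - len(kept) / len(table)
        assert fail_fraction == pytest.approx(0.1, abs=0.03)

    def test_class_size_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            simulate_nucleus_matrix(SimConfig(n_nuclei_per_class=(5, 5, 5)))

    def test_deterministic(self):
        a = simulate_nucleus_matrix(SimConfig(seed=4))
        b = simulate_nucleus_matrix(SimConfig(seed=4))
        assert a.equals(b)


def test_locus_model_geometry(small_config, small_locus):
    assert small_locus.tad_region.contains_interval(small_locus.se_region)
    for name, gene in small_locus.genes:
        assert small_locus.tad_region.contains_interval(gene)
    tads = small_locus.tads
    assert tads[0].start == 0
    assert tads[-1].end == small_config.genome_length
    for left, right in zip(tads[:-1], tads[1:]):
        assert left.end == right.start
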