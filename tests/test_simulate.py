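"""Synthetic scenario generator: exact truths, determinism, thinning."""

import numpy as np
import pytest

from coversize import (
    CoverageTrack,
    GenomeSizeModel,
    InputError,
    SyntheticScenario,
    alignments_to_coverage,
    simulate_alignments,
    simulate_depth_scenario,
    thin_track,
)


REPEAT = SyntheticScenario(
    nuclear_length=1_000,
    base_depth=10,
    repeat_blocks=((600, 100, 3),),
    noise="none",
    n_single_copy_buscos=4,
    busco_length=100,
    seed=1,
)


class TestDepthScenario:
    def test_repeat_block_depth_and_truth(self):
        data = simulate_depth_scenario(REPEAT)
        nuc = data.track["nuc"]
        assert set(nuc[:600]) == {10}
        assert set(nuc[600:700]) == {30}
        assert set(nuc[700:]) == {10}
        assert data.truth["true_genome_size"] == 1_200

    def test_busco_regions_avoid_repeats(self):
        data = simulate_depth_scenario(REPEAT)
        for region in data.regions:
            assert region.end <= 600 or region.start >= 700

    def test_estimate_recovers_truth_exactly(self):
        data = simulate_depth_scenario(REPEAT)
        res = GenomeSizeModel(data.track, data.regions, mode="median").fit()
        assert res.genome_size_bp == 1_200.0
        assert res.total_aligned_bases == 900 * 10 + 100 * 30

    def test_contamination_never_enters_track(self):
        with_contam = SyntheticScenario(**{**REPEAT.__dict__, "contaminant_bases": 10**6})
        assert simulate_depth_scenario(with_contam).track == simulate_depth_scenario(REPEAT).track

    def test_reproducible_under_seed(self):
        noisy = SyntheticScenario(
            nuclear_length=5_000, base_depth=15, noise="poisson",
            n_single_copy_buscos=3, busco_length=200, seed=42,
        )
        a, b = simulate_depth_scenario(noisy), simulate_depth_scenario(noisy)
        assert a.track == b.track
        assert [(r.start, r.end) for r in a.regions] == [(r.start, r.end) for r in b.regions]

    def test_organelle_sequence_and_exclusion_list(self):
        scenario = SyntheticScenario(
            nuclear_length=1_000, base_depth=10, organelle=(50, 10),
            noise="none", n_single_copy_buscos=2, busco_length=100, seed=0,
        )
        data = simulate_depth_scenario(scenario)
        assert set(data.track["pt"]) == {100}
        assert data.excluded_ids == {"pt"}
        assert data.truth["true_genome_size"] == 1_000  # nuclear-only truth

    def test_impossible_busco_placement_rejected(self):
        bad = SyntheticScenario(
            nuclear_length=500, base_depth=5, n_single_copy_buscos=10,
            busco_length=100, seed=0,
        )
        with pytest.raises(InputError, match="cannot place"):
            simulate_depth_scenario(bad)

    @pytest.mark.parametrize(
        "blocks", [(( 100, 100, 3), (150, 100, 2)), ((900, 200, 2),)]
    )
    def test_invalid_repeat_blocks_rejected(self, blocks):
        with pytest.raises(InputError):
            SyntheticScenario(nuclear_length=1_000, base_depth=10, repeat_blocks=blocks)

    def test_poisson_recovery_across_seeds(self):
        """Median estimates on noisy repeat scenarios recover truth closely."""
        errors = []
        for seed in range(10):
            scenario = SyntheticScenario(
                nuclear_length=100_000, base_depth=20,
                repeat_blocks=((60_000, 5_000, 3),), noise="poisson",
                n_single_copy_buscos=20, busco_length=1_000, seed=seed,
            )
            data = simulate_depth_scenario(scenario)
            res = GenomeSizeModel(data.track, data.regions, mode="median").fit()
            errors.append(abs(res.genome_size_bp - scenario.true_genome_size) / scenario.true_genome_size)
        assert max(errors) < 0.03


class TestAlignmentSimulation:
    def test_tiling_reproduces_unit_depth(self):
        scenario = SyntheticScenario(
            nuclear_length=100, base_depth=1, noise="none",
            n_single_copy_buscos=1, busco_length=20, seed=0,
        )
        sam, lengths = simulate_alignments(scenario, read_length=5)
        reads = [l for l in sam.splitlines() if not l.startswith("@")]
        assert len(reads) == 20
        track = alignments_to_coverage(sam, lengths)
        assert set(track["nuc"]) == {1}

    def test_coverage_matches_expected_track_with_repeat(self):
        sam, lengths = simulate_alignments(REPEAT, read_length=50)
        track = alignments_to_coverage(sam, lengths)
        expected = simulate_depth_scenario(REPEAT).truth["expected_depths"]["nuc"]
        assert np.array_equal(track["nuc"], expected)

    def test_doubling_reads_doubles_track(self):
        scenario = SyntheticScenario(
            nuclear_length=200, base_depth=2, noise="none",
            n_single_copy_buscos=1, busco_length=50, seed=0,
        )
        sam, lengths = simulate_alignments(scenario, read_length=20)
        header = [l for l in sam.splitlines() if l.startswith("@")]
        reads = [l for l in sam.splitlines() if not l.startswith("@")]
        doubled = "\n".join(header + reads + reads) + "\n"
        track = alignments_to_coverage(sam, lengths)
        track2 = alignments_to_coverage(doubled, lengths)
        assert np.array_equal(track2["nuc"], 2 * track["nuc"])

    def test_read_longer_than_sequence_rejected(self):
        scenario = SyntheticScenario(
            nuclear_length=100, base_depth=1, noise="none",
            n_single_copy_buscos=1, busco_length=20, seed=0,
        )
        with pytest.raises(InputError):
            simulate_alignments(scenario, read_length=200)

    def test_noisy_scenario_rejected(self):
        noisy = SyntheticScenario(
            nuclear_length=100, base_depth=1, noise="poisson",
            n_single_copy_buscos=1, busco_length=20, seed=0,
        )
        with pytest.raises(InputError):
            simulate_alignments(noisy)


class TestThinning:
    def test_fraction_one_is_identity(self, uniform_track):
        assert thin_track(uniform_track, 1.0, seed=5) == uniform_track

    def test_fraction_zero_zeroes(self, uniform_track):
        assert thin_track(uniform_track, 0.0, seed=5).total_bases() == 0

    def test_half_fraction_within_binomial_moments(self):
        track = CoverageTrack({"a": np.full(1_000, 40, dtype=np.int64)})
        thinned = thin_track(track, 0.5, seed=3)
        # total ~ Binomial(40000, 0.5): sd = sqrt(40000 * 0.25) = 100
        assert abs(thinned.total_bases() - 20_000) <= 300

    def test_expectation_preserved_across_seeds(self):
        track = CoverageTrack({"a": np.full(500, 20, dtype=np.int64)})
        totals = [thin_track(track, 0.3, seed=s).total_bases() for s in range(200)]
        expected = 0.3 * track.total_bases()
        assert np.mean(totals) == pytest.approx(expected, rel=0.01)

    def test_deterministic_under_seed(self, uniform_track):
        assert thin_track(uniform_track, 0.4, seed=8) == thin_track(uniform_track, 0.4, seed=8)

    def test_out_of_range_fraction_rejected(self, uniform_track):
        with pytest.raises(InputError):
            thin_track(uniform_track, 1.5)
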