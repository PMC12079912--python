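"""The N = L / C estimate, the model/results interface, and saturation."""

import numpy as np
import pytest

from coversize import (
    CoverageTrack,
    EstimationError,
    GenomeSizeModel,
    InputError,
    Region,
    RegionSet,
    estimate_genome_size,
    saturation_analysis,
    total_aligned_bases,
)


class TestTotalAlignedBases:
    TRACK = CoverageTrack({"a": [10] * 10, "pt": [100] * 5})

    def test_restricted_to_included(self):
        assert total_aligned_bases(self.TRACK, {"a"}) == 100

    def test_all_sequences(self):
        assert total_aligned_bases(self.TRACK, {"a", "pt"}) == 600

    def test_all_zero_track(self):
        assert total_aligned_bases(CoverageTrack({"a": [0, 0]}), {"a"}) == 0

    def test_empty_included_rejected(self):
        with pytest.raises(EstimationError):
            total_aligned_bases(self.TRACK, set())

    def test_unknown_sequence_rejected(self):
        with pytest.raises(InputError):
            total_aligned_bases(self.TRACK, {"a", "zz"})


class TestEstimate:
    def test_uniform_track_recovers_assembly_length(self):
        track = CoverageTrack({"a": [10] * 10})
        rs = RegionSet([Region("a", 0, 10)])
        result = estimate_genome_size(track, rs, mode="mean", blacklist_enabled=False)
        assert (result.genome_size_bp, result.total_aligned_bases, result.average_coverage) == (10.0, 100, 10.0)

    def test_collapsed_repeat_recovers_true_size(self):
        depths = np.concatenate([np.full(5, 10), np.full(5, 20)])
        track = CoverageTrack({"a": depths})
        rs = RegionSet([Region("a", 0, 5)])
        result = estimate_genome_size(track, rs, mode="mean", blacklist_enabled=False)
        assert (result.average_coverage, result.total_aligned_bases, result.genome_size_bp) == (10.0, 150, 15.0)

    def test_organelle_blacklisted_by_default(self, organelle_track, nuc_regions):
        result = estimate_genome_size(organelle_track, nuc_regions, mode="mean")
        assert result.blacklisted == {"pt"}
        assert (result.average_coverage, result.total_aligned_bases, result.genome_size_bp) == (10.0, 1000, 100.0)

    def test_invariant_n_times_c_equals_l(self, organelle_track, nuc_regions):
        r = estimate_genome_size(organelle_track, nuc_regions, mode="mean")
        assert r.genome_size_bp * r.average_coverage == pytest.approx(
            r.total_aligned_bases, rel=1e-9
        )

    def test_user_exclusion_equivalent_to_blacklist_here(self, organelle_track, nuc_regions):
        auto = estimate_genome_size(organelle_track, nuc_regions, mode="mean")
        manual = estimate_genome_size(
            organelle_track, nuc_regions, mode="mean", blacklist_enabled=False, excluded={"pt"}
        )
        assert manual.genome_size_bp == auto.genome_size_bp == 100.0
        assert manual.excluded == {"pt"}

    def test_scale_invariance(self, organelle_track, nuc_regions):
        for mode in ("mean", "median"):
            base = estimate_genome_size(organelle_track, nuc_regions, mode=mode)
            scaled = estimate_genome_size(organelle_track.scaled(7), nuc_regions, mode=mode)
            assert scaled.genome_size_bp == pytest.approx(base.genome_size_bp, rel=1e-9)
            assert scaled.total_aligned_bases == 7 * base.total_aligned_bases
            assert scaled.average_coverage == 7 * base.average_coverage

    def test_zero_coverage_in_regions_is_error(self):
        track = CoverageTrack({"a": [0] * 10, "b": [5] * 10})
        rs = RegionSet([Region("a", 0, 10)])
        with pytest.raises(EstimationError, match="zero coverage"):
            estimate_genome_size(track, rs, blacklist_enabled=False)

    def test_regions_only_on_blacklisted_sequence_is_error(self, organelle_track):
        rs = RegionSet([Region("pt", 0, 10)])
        with pytest.raises(EstimationError, match="no reference regions"):
            estimate_genome_size(organelle_track, rs, mode="mean")


class TestModelInterface:
    def test_fit_matches_function_pipeline(self, organelle_track, nuc_regions):
        res = GenomeSizeModel(organelle_track, nuc_regions, mode="mean").fit()
        direct = estimate_genome_size(organelle_track, nuc_regions, mode="mean")
        assert res.genome_size_bp == direct.genome_size_bp
        assert res.blacklisted == direct.blacklisted

    def test_model_merges_regions_on_construction(self, organelle_track):
        overlapping = RegionSet([Region("nuc", 0, 60), Region("nuc", 40, 100)])
        model = GenomeSizeModel(organelle_track, overlapping, mode="mean")
        assert model.regions.total_positions() == 100
        assert model.fit().genome_size_bp == 100.0

    def test_summary_reports_headline_numbers(self, organelle_track, nuc_regions):
        text = GenomeSizeModel(organelle_track, nuc_regions, mode="mean").fit().summary()
        assert "100 bp" in text
        assert "pt" in text

    def test_from_files(self, tmp_path):
        cov = tmp_path / "c.tsv"
        cov.write_text("".join(f"nuc\t{i}\t10\n" for i in range(1, 101)))
        busco = tmp_path / "b.tsv"
        busco.write_text("B1\tComplete\tnuc\t1\t50\n")
        res = GenomeSizeModel.from_files(coverage=cov, busco=busco, mode="mean").fit()
        assert res.genome_size_bp == 100.0


class TestSaturation:
    def setup_method(self):
        self.track = CoverageTrack({"nuc": np.full(5_000, 40, dtype=np.int64)})
        self.regions = RegionSet([Region("nuc", 0, 2_000)])

    def test_fraction_one_row_bitwise_equals_full_estimate(self):
        full = estimate_genome_size(self.track, self.regions, mode="median")
        rows, _ = saturation_analysis(
            self.track, self.regions, mode="median", fractions=[1.0, 0.5], seed=7
        )
        assert rows[0].estimate_bp == full.genome_size_bp
        assert rows[0].sampled_bases == full.total_aligned_bases
        assert rows[0].within_tolerance

    def test_half_fraction_within_tolerance(self):
        rows, minimum = saturation_analysis(
            self.track, self.regions, mode="median", fractions=[1.0, 0.5], seed=7
        )
        assert rows[1].within_tolerance
        assert minimum == rows[1].sampled_bases

    def test_degenerate_fraction_flagged_not_fatal(self):
        shallow = CoverageTrack({"nuc": np.full(2_000, 5, dtype=np.int64)})
        rows, minimum = saturation_analysis(
            shallow, RegionSet([Region("nuc", 0, 1_000)]), mode="median",
            fractions=[1.0, 0.001], seed=3,
        )
        bad = rows[1]
        assert bad.estimate_bp is None or not bad.within_tolerance
        assert minimum is None or minimum > bad.sampled_bases

    def test_rows_independently_reproducible(self):
        rows_a, _ = saturation_analysis(
            self.track, self.regions, fractions=[1.0, 0.5, 0.1], seed=9
        )
        rows_b, _ = saturation_analysis(
            self.track, self.regions, fractions=[1.0, 0.5, 0.1], seed=9
        )
        assert [(r.sampled_bases, r.estimate_bp) for r in rows_a] == [
            (r.sampled_bases, r.estimate_bp) for r in rows_b
        ]

    def test_missing_full_fraction_rejected(self):
        with pytest.raises(InputError):
            saturation_analysis(self.track, self.regions, fractions=[0.5])

    def test_results_saturation_wrapper(self):
        model = GenomeSizeModel(self.track, self.regions, mode="median", blacklist=False)
        rows, _ = model.fit().saturation(fractions=[1.0, 0.5], seed=7)
        assert rows[0].estimate_bp == model.fit().genome_size_bp
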