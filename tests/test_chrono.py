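"""Substage binning, range-through assignment and per-bin summaries."""

import numpy as np
import pytest

from fossilcomp.chrono import (
    BinSeries,
    assign_occurrences,
    bin_assignment_mapping,
    make_substage_bins,
    mean_ccm2_series,
    species_incidence,
    taxic_diversity_series,
)
from fossilcomp.errors import BinLookupError, TableValidationError
from fossilcomp.io import default_stage_boundaries
from tests.test_ccm import make_specimen


class TestMakeSubstageBins:
    def test_midpoint_split_of_tithonian(self):
        bins = make_substage_bins([("Tithonian", 150.8, 145.5)])
        assert [b.label for b in bins.bins] == ["early Tithonian", "late Tithonian"]
        assert bins.bins[0].start_ma == 150.8
        assert bins.bins[0].end_ma == pytest.approx(148.15)
        assert bins.bins[1].start_ma == pytest.approx(148.15)
        assert bins.bins[1].end_ma == 145.5

    def test_zero_duration_stage_rejected(self):
        with pytest.raises(TableValidationError, match="duration"):
            make_substage_bins([("Aptian", 125.0, 125.0)])

    def test_gap_between_stages_rejected(self):
        with pytest.raises(TableValidationError, match="gap or overlap"):
            make_substage_bins([("Tithonian", 150.8, 145.5), ("Berriasian", 145.0, 140.2)])

    def test_packaged_timescale_spans_study_interval(self):
        """The shipped stage table runs Tithonian 150.8 Ma to Maastrichtian 65.5 Ma."""
        bins = make_substage_bins(default_stage_boundaries())
        assert len(bins) == 26
        assert bins.bins[0].start_ma == 150.8
        assert bins.bins[-1].end_ma == 65.5

    def test_boundary_age_belongs_to_younger_bin(self, three_stage_boundaries):
        bins = make_substage_bins(three_stage_boundaries)
        assert bins.bins[bins.bin_of_age(145.5)].label == "early Berriasian"


class TestAssignOccurrences:
    def test_stage_only_date_ranges_through_both_substages(self, three_stage_boundaries):
        bins = make_substage_bins(three_stage_boundaries)
        rec = make_specimen("s1", set(), age_earliest="Tithonian", age_latest="Tithonian")
        inc = assign_occurrences([rec], bins)
        assert list(inc.columns[inc.loc["s1"]]) == ["early Tithonian", "late Tithonian"]

    def test_exact_substage_occupies_one_bin(self, three_stage_boundaries):
        bins = make_substage_bins(three_stage_boundaries)
        rec = make_specimen("s1", set(), age_earliest="late Berriasian", age_latest="late Berriasian")
        inc = assign_occurrences([rec], bins)
        assert inc.loc["s1"].sum() == 1

    def test_uncertain_range_fills_every_intervening_bin(self, three_stage_boundaries):
        """A taxon ranged over several stages is present in all spanned substages."""
        bins = make_substage_bins(three_stage_boundaries)
        rec = make_specimen("s1", set(), age_earliest="Tithonian", age_latest="early Valanginian")
        inc = assign_occurrences([rec], bins)
        assert inc.loc["s1"].sum() == 5  # 2 + 2 + 1 substages

    def test_reversed_age_range_rejected(self, three_stage_boundaries):
        bins = make_substage_bins(three_stage_boundaries)
        rec = make_specimen("s1", set(), age_earliest="Valanginian", age_latest="Tithonian")
        with pytest.raises(TableValidationError, match="younger"):
            assign_occurrences([rec], bins)

    def test_unknown_substage_is_a_lookup_error(self, three_stage_boundaries):
        bins = make_substage_bins(three_stage_boundaries)
        rec = make_specimen("s1", set(), age_earliest="Aptian", age_latest="Aptian")
        with pytest.raises(BinLookupError, match="Aptian"):
            assign_occurrences([rec], bins)

    def test_widening_range_never_removes_bins(self, three_stage_boundaries):
        bins = make_substage_bins(three_stage_boundaries)
        narrow = assign_occurrences(
            [make_specimen("s1", set(), age_earliest="Berriasian", age_latest="Berriasian")], bins
        )
        wide = assign_occurrences(
            [make_specimen("s1", set(), age_earliest="Tithonian", age_latest="Valanginian")], bins
        )
        assert (wide.loc["s1"] | narrow.loc["s1"]).equals(wide.loc["s1"])


class TestSeries:
    def _bins(self, boundaries):
        return make_substage_bins(boundaries)

    def test_single_species_bin_mean_equals_species_score(self, three_stage_boundaries):
        bins = self._bins(three_stage_boundaries)
        rec = make_specimen("s1", set(), age_earliest="early Tithonian", age_latest="early Tithonian")
        inc = assign_occurrences([rec], bins)
        series = mean_ccm2_series({("sp", "early Tithonian"): 75.72}, bins, inc)
        assert series.value[0] == pytest.approx(75.72)
        assert np.isnan(series.std_dev[0])
        assert series.n[0] == 1

    def test_two_species_mean_and_sd(self, three_stage_boundaries):
        bins = self._bins(three_stage_boundaries)
        recs = [
            make_specimen("s1", set(), age_earliest="early Tithonian", age_latest="early Tithonian"),
            make_specimen("s2", set(), species="B", age_earliest="early Tithonian",
                          age_latest="early Tithonian"),
        ]
        inc = assign_occurrences(recs, bins)
        series = mean_ccm2_series(
            {("A", "early Tithonian"): 10.0, ("B", "early Tithonian"): 30.0}, bins, inc
        )
        assert series.value[0] == 20.0
        assert series.std_dev[0] == pytest.approx(np.std([10.0, 30.0], ddof=1))
        assert series.n[0] == 2
        assert np.isnan(series.value[1])  # empty bin stays missing

    def test_mean_bounded_by_member_scores(self, three_stage_boundaries):
        bins = self._bins(three_stage_boundaries)
        recs = [make_specimen("s1", set(), age_earliest="early Tithonian",
                              age_latest="early Tithonian")]
        inc = assign_occurrences(recs, bins)
        scores = {("A", "early Tithonian"): 12.5, ("B", "early Tithonian"): 80.0}
        series = mean_ccm2_series(scores, bins, inc)
        assert 12.5 <= series.value[0] <= 80.0

    def test_taxic_diversity_counts_range_through_species(self, three_stage_boundaries):
        bins = self._bins(three_stage_boundaries)
        recs = [
            make_specimen("s1", set(), species="A", age_earliest="Tithonian",
                          age_latest="early Berriasian"),
            make_specimen("s2", set(), species="B", age_earliest="late Berriasian",
                          age_latest="late Berriasian"),
        ]
        inc = assign_occurrences(recs, bins)
        series = taxic_diversity_series(species_incidence(recs, inc), bins)
        assert list(series.value) == [1, 1, 1, 1, 0, 0]
        # a species contributes once to every bin its range intersects
        assert species_incidence(recs, inc).loc["A"].sum() == 3

    def test_no_occurrences_gives_all_zero_diversity(self, three_stage_boundaries):
        bins = self._bins(three_stage_boundaries)
        inc = assign_occurrences([], bins)
        series = taxic_diversity_series(species_incidence([], inc), bins)
        assert list(series.value) == [0.0] * 6

    def test_bin_assignment_mapping_lists_occupied_bins(self, three_stage_boundaries):
        bins = self._bins(three_stage_boundaries)
        rec = make_specimen("s1", set(), age_earliest="Tithonian", age_latest="Tithonian")
        mapping = bin_assignment_mapping(assign_occurrences([rec], bins))
        assert mapping == {"s1": ["early Tithonian", "late Tithonian"]}

    def test_bin_series_length_mismatch_rejected(self):
        with pytest.raises(TableValidationError, match="equal length"):
            BinSeries(["a", "b"], np.array([1.0]), None, np.array([1]))
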