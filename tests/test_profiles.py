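"""Occupancy and positioning statistics, summaries and flank alignment."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucprofile import (
    DyadTrack,
    ElementInsert,
    NoSignalError,
    Orientation,
    Site,
    assemble_construct,
    align_flanking_profiles,
    build_dyad_track,
    estimate_array_coverage,
    normalize_occupancy,
    occupancy_from_dyads,
    positioning_at_element,
    positioning_scores,
    ratio_to_control,
    region_total_occupancy,
    synthetic_element,
)
from nucprofile.constructs import Interval
from nucprofile.profiles import OccupancyProfile

from conftest import oracle_occupancy, oracle_positioning


def track_from_dyads(dyads, ref_len):
    return build_dyad_track(np.asarray(dyads, dtype=np.int64), ref_len)


# ---------------------------------------------------------------------------
# Occupancy


def test_single_dyad_paints_one_footprint():
    occ = occupancy_from_dyads(track_from_dyads([100], 300))
    assert (occ.values[27:174] == 1).all()
    assert occ.values[26] == 0 and occ.values[174] == 0
    assert occ.values.sum() == 147


def test_occupancy_is_additive():
    occ = occupancy_from_dyads(track_from_dyads([100, 100], 300))
    assert (occ.values[27:174] == 2).all()
    assert occ.values.sum() == 2 * 147


def test_footprints_truncate_at_reference_ends():
    occ = occupancy_from_dyads(track_from_dyads([0], 300))
    assert occ.values.sum() == 74  # only [0, 73] is on-reference


def test_occupancy_matches_naive_oracle():
    rng = np.random.default_rng(11)
    for _ in range(10):
        ref_len = int(rng.integers(150, 600))
        dyads = rng.integers(0, ref_len, size=int(rng.integers(0, 400)))
        occ = occupancy_from_dyads(track_from_dyads(dyads, ref_len))
        np.testing.assert_array_equal(occ.values, oracle_occupancy(dyads, ref_len))


# ---------------------------------------------------------------------------
# Normalization


def test_normalize_max_sets_peak_to_one():
    occ = occupancy_from_dyads(track_from_dyads([100, 150, 150], 400))
    norm = normalize_occupancy(occ, "max")
    assert norm.values.max() == 1.0
    assert norm.normalized and norm.normalization_method.startswith("max")


def test_normalize_constant_profile_gives_all_ones():
    profile = OccupancyProfile("ref", np.full(50, 3.0))
    for method in ("max", "mean"):
        assert (normalize_occupancy(profile, method).values == 1.0).all()


def test_normalize_is_idempotent_for_max():
    occ = occupancy_from_dyads(track_from_dyads([10, 200, 321], 500))
    once = normalize_occupancy(occ, "max")
    twice = normalize_occupancy(once, "max")
    np.testing.assert_array_equal(once.values, twice.values)


def test_normalize_rejects_all_zero_profile():
    with pytest.raises(NoSignalError, match="no signal"):
        normalize_occupancy(OccupancyProfile("ref", np.zeros(100)))


def test_normalize_over_window():
    occ = OccupancyProfile("ref", np.array([1.0, 2.0, 4.0, 8.0]))
    norm = normalize_occupancy(occ, "max", window=Interval(0, 2))
    np.testing.assert_array_equal(norm.values, [0.5, 1.0, 2.0, 4.0])


# ---------------------------------------------------------------------------
# Positioning


def test_all_dyads_at_one_position_score_exactly_one():
    track = track_from_dyads([500] * 1000, 1000)
    profile = positioning_scores(track)
    assert profile.scores[500] == 1.0


def test_uniform_track_interior_score_is_21_over_301():
    ref_len = 800
    track = DyadTrack("ref", np.ones(ref_len, dtype=np.int64))
    profile = positioning_scores(track)
    interior = profile.scores[150:ref_len - 150]
    assert (interior == 21 / 301).all()


def test_empty_track_scores_zero_everywhere():
    profile = positioning_scores(track_from_dyads([], 400))
    assert (profile.scores == 0).all()


def test_positioning_matches_naive_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        ref_len = int(rng.integers(350, 700))
        dyads = rng.integers(0, ref_len, size=int(rng.integers(1, 500)))
        profile = positioning_scores(track_from_dyads(dyads, ref_len))
        np.testing.assert_array_equal(
            profile.scores, oracle_positioning(dyads, ref_len)
        )


@given(st.lists(st.integers(0, 499), min_size=0, max_size=300))
@settings(max_examples=25)
def test_positioning_scores_bounded_in_unit_interval(dyads):
    profile = positioning_scores(track_from_dyads(dyads, 500))
    assert (profile.scores >= 0).all() and (profile.scores <= 1).all()


def test_inner_window_may_not_exceed_outer():
    with pytest.raises(ValueError):
        positioning_scores(track_from_dyads([5], 50), inner_half=20, outer_half=10)


# ---------------------------------------------------------------------------
# Region summaries


def test_region_total_is_additive_over_disjoint_intervals():
    occ = occupancy_from_dyads(track_from_dyads([100, 180, 260], 500))
    whole = region_total_occupancy(occ, Interval(50, 350))
    parts = (region_total_occupancy(occ, Interval(50, 200))
             + region_total_occupancy(occ, Interval(200, 350)))
    assert whole == parts


def test_region_total_zero_region_and_empty_interval():
    occ = occupancy_from_dyads(track_from_dyads([10], 500))
    assert region_total_occupancy(occ, Interval(300, 400)) == 0.0
    with pytest.warns(UserWarning, match="empty interval"):
        assert region_total_occupancy(occ, Interval(50, 50)) == 0.0


def test_constant_unit_profile_over_90bp_region_totals_90():
    profile = OccupancyProfile("ref", np.ones(400))
    assert region_total_occupancy(profile, Interval(100, 190)) == 90.0


def test_ratio_to_control():
    assert ratio_to_control(62.7, 62.7) == 1.0
    assert ratio_to_control(0.0, 5.0) == 0.0
    total, control = 8.14, 62.74
    assert ratio_to_control(total, control) * control == pytest.approx(total)
    with pytest.raises(ValueError):
        ratio_to_control(1.0, 0.0)


# ---------------------------------------------------------------------------
# Flank alignment


def test_flank_offsets_hug_the_removed_interval():
    profile = OccupancyProfile("ref", np.arange(10, dtype=float))
    out = align_flanking_profiles({"x": profile}, {"x": Interval(4, 7)})["x"]
    assert list(out["offset"]) == [-4, -3, -2, -1, 1, 2, 3]
    assert list(out["value"]) == [0.0, 1.0, 2.0, 3.0, 7.0, 8.0, 9.0]


def test_zero_length_removal_recenters_only():
    profile = OccupancyProfile("ref", np.arange(6, dtype=float))
    out = align_flanking_profiles({"x": profile}, {"x": Interval(3, 3)})["x"]
    assert list(out["offset"]) == [-3, -2, -1, 1, 2, 3]
    assert list(out["value"]) == [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]


def test_flank_alignment_never_changes_values():
    rng = np.random.default_rng(3)
    values = rng.random(200)
    profile = OccupancyProfile("ref", values)
    out = align_flanking_profiles({"x": profile}, {"x": Interval(60, 140)})["x"]
    np.testing.assert_array_equal(
        out["value"].to_numpy(), np.concatenate([values[:60], values[140:]])
    )


def test_constructs_with_different_inserts_share_flank_axes():
    """Two constructs differing only by the removed block are directly
    comparable: equal flank dyads give identical flank tables."""
    rng = np.random.default_rng(5)
    flank_left = rng.random(300)
    flank_right = rng.random(300)
    short = OccupancyProfile("a", np.concatenate([flank_left, np.zeros(90), flank_right]))
    long = OccupancyProfile("b", np.concatenate([flank_left, np.zeros(230), flank_right]))
    out = align_flanking_profiles(
        {"a": short, "b": long},
        {"a": Interval(300, 390), "b": Interval(300, 530)},
    )
    assert out["a"].equals(out["b"])


def test_non_contiguous_removal_rejected():
    profile = OccupancyProfile("ref", np.zeros(100))
    with pytest.raises(ValueError, match="non-contiguous"):
        align_flanking_profiles(
            {"x": profile}, {"x": [Interval(10, 20), Interval(30, 40)]}
        )


# ---------------------------------------------------------------------------
# Positioning at elements


@pytest.fixture(scope="module")
def trifonov_construct(backbone):
    el = synthetic_element("Trifonov", 166)
    return assemble_construct(
        "tri",
        backbone,
        [
            ElementInsert(el, Site.UPSTREAM_HINDIII, Orientation.FORWARD),
            ElementInsert(el, Site.DOWNSTREAM_NHEI, Orientation.FORWARD),
        ],
    )


def test_odd_length_element_reports_single_center(backbone):
    el = synthetic_element("601", 147)
    spec = assemble_construct(
        "one601", backbone, [ElementInsert(el, Site.UPSTREAM_HINDIII, Orientation.FORWARD)]
    )
    track = track_from_dyads([spec.element_intervals["601"].interval.start + 73] * 50,
                             len(spec))
    pairs = positioning_at_element(positioning_scores(track), spec, "601")
    assert len(pairs) == 1
    assert pairs[0][1] == 1.0


def test_even_length_element_reports_both_flanking_positions(trifonov_construct):
    spec = trifonov_construct
    track = track_from_dyads([10], len(spec))
    profile = positioning_scores(track)
    pairs = positioning_at_element(profile, spec, "Trifonov")
    # two placements x two center-flanking positions, adjacent and ordered
    assert len(pairs) == 4
    positions = [p for p, _ in pairs]
    assert positions[1] == positions[0] + 1
    assert positions[3] == positions[2] + 1
    assert positions[0] < 0 < positions[2]


def test_element_scores_cross_check_against_profile(trifonov_construct):
    spec = trifonov_construct
    rng = np.random.default_rng(9)
    track = track_from_dyads(rng.integers(0, len(spec), 2000), len(spec))
    profile = positioning_scores(track)
    for report_pos, score in positioning_at_element(profile, spec, "Trifonov"):
        internal = report_pos + spec.enhancer_center
        assert score == profile.scores[internal]


def test_unknown_element_rejected(control_construct):
    profile = positioning_scores(track_from_dyads([5], len(control_construct)))
    with pytest.raises(KeyError, match="not annotated"):
        positioning_at_element(profile, control_construct, "601")


def test_profile_table_carries_both_coordinate_systems(control_construct):
    from nucprofile import profile_table

    track = track_from_dyads([100], len(control_construct))
    occ = occupancy_from_dyads(track)
    table = profile_table(control_construct, occ.values, column="occupancy")
    assert list(table.columns) == ["position", "report_position", "occupancy"]
    center = control_construct.enhancer_center
    assert table.loc[table["position"] == center, "report_position"].item() == 0
    assert table["occupancy"].sum() == occ.values.sum()
    with pytest.raises(ValueError, match="length"):
        profile_table(control_construct, occ.values[:-1])


# ---------------------------------------------------------------------------
# Coverage estimate


def test_coverage_zero_pairs_gives_zero_range():
    est = estimate_array_coverage(0, 147.0, 3000)
    assert est.coverage_low == est.coverage_high == 0.0


def test_coverage_degenerate_copy_range():
    est = estimate_array_coverage(1000, 147.0, 3000, copies_low=100, copies_high=100)
    assert est.coverage_low == est.coverage_high


def test_coverage_is_linear_in_mapped_pairs():
    a = estimate_array_coverage(1000, 147.0, 3000)
    b = estimate_array_coverage(2000, 147.0, 3000)
    assert b.coverage_low == 2 * a.coverage_low
    assert b.coverage_high == 2 * a.coverage_high
    assert a.coverage_low <= a.coverage_high


def test_coverage_rejects_zero_probe_length():
    with pytest.raises(ValueError, match="probe_length"):
        estimate_array_coverage(1000, 147.0, 0)
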