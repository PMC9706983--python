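"""The synthetic array generator: mixture model, fragment law, writers."""

import numpy as np
import pytest
from scipy import stats

from nucprofile import (
    DepletionZone,
    FilterPolicy,
    FragmentLengthLaw,
    PositionedSite,
    SimulationParams,
    dyads_to_fragments,
    filter_by_length,
    fragment_dyad,
    preset_experiment,
    read_fragments,
    simulate_dyads,
    write_dataset,
)
from nucprofile.constructs import Interval


@pytest.fixture(scope="module")
def control_params(control_construct):
    def make(**kw):
        kw.setdefault("construct", control_construct)
        kw.setdefault("n_fragments", 1000)
        kw.setdefault("seed", 42)
        return SimulationParams(**kw)

    return make


# ---------------------------------------------------------------------------
# Dyad mixture


def test_degenerate_site_puts_every_dyad_at_the_site(control_params):
    params = control_params(
        sites=(PositionedSite(700, 1.0, 0.0),), background_weight=0.0
    )
    dyads = simulate_dyads(params)
    assert (dyads == 700).all() and dyads.size == 1000


def test_zero_factor_zone_excludes_dyads(control_params):
    params = control_params(
        zones=(DepletionZone(Interval(100, 200), 0.0),), n_fragments=5000
    )
    dyads = simulate_dyads(params)
    assert not ((dyads >= 100) & (dyads < 200)).any()


def test_all_zero_weights_rejected(control_construct):
    with pytest.raises(ValueError, match="positive"):
        SimulationParams(control_construct, background_weight=0.0)


def test_mixture_fractions_and_background_law(control_params, control_construct):
    """50/50 site/background mixture at n=100,000: the site fraction sits
    within 3 binomial standard errors of 0.5, and the background positions
    fit the zone-modulated uniform law (chi-square, alpha=0.01)."""
    n = 100_000
    ref_len = len(control_construct)
    zone = DepletionZone(Interval(400, 900), 0.25)
    params = control_params(
        sites=(PositionedSite(1500, 1.0, 0.0),),
        zones=(zone,),
        background_weight=1.0,
        n_fragments=n,
    )
    dyads = simulate_dyads(params)
    at_site = int((dyads == 1500).sum())
    se = np.sqrt(n * 0.25)
    assert abs(at_site - n / 2) <= 3 * se

    background = dyads[dyads != 1500]
    edges = [0, 400, 900, ref_len]
    observed, _ = np.histogram(background, bins=edges)
    density = np.ones(ref_len)
    density[400:900] = 0.25
    expected = np.array([
        density[a:b].sum() for a, b in zip(edges[:-1], edges[1:])
    ])
    expected = expected / expected.sum() * background.size
    _, pvalue = stats.chisquare(observed, expected)
    assert pvalue > 0.01


def test_simulation_is_deterministic_per_seed(control_params):
    params = control_params(sites=(PositionedSite(800, 0.5, 5.0),))
    a, b = simulate_dyads(params), simulate_dyads(params)
    np.testing.assert_array_equal(a, b)
    other = simulate_dyads(control_params(
        sites=(PositionedSite(800, 0.5, 5.0),), seed=43
    ))
    assert not np.array_equal(a, other)


# ---------------------------------------------------------------------------
# Fragment construction


def test_fixed_147_length_round_trip(control_params):
    params = control_params(length_law=FragmentLengthLaw.constant(147))
    frags, _ = dyads_to_fragments(np.array([100]), params)
    assert (frags[0].start, frags[0].end) == (27, 174)
    assert fragment_dyad(frags[0]) == 100


@pytest.mark.parametrize("length", range(130, 211))
def test_fragment_construction_inverts_dyad_for_all_lengths(control_params, length):
    params = control_params(length_law=FragmentLengthLaw.constant(length))
    frags, _ = dyads_to_fragments(np.array([500]), params)
    assert frags[0].length == length
    assert fragment_dyad(frags[0]) == 500


def test_edge_fragments_discarded_and_counted(control_params):
    params = control_params(length_law=FragmentLengthLaw.constant(147))
    frags, discarded = dyads_to_fragments(np.array([0, 50, 500]), params)
    assert discarded == 2  # dyads 0 and 50 spill off the left end
    assert len(frags) == 1


def test_retention_fraction_matches_length_law_mass(control_params):
    """Simulated fragments survive the 136-158 bp filter at the law's own
    mass on that window, within 3 binomial standard errors (n=10,000)."""
    law = FragmentLengthLaw.truncated_normal()
    params = control_params(n_fragments=10_000, length_law=law)
    dyads = simulate_dyads(params)
    frags, _ = dyads_to_fragments(dyads, params)
    retained, _ = filter_by_length(frags, FilterPolicy())
    p = law.mass(136, 158)
    n = len(frags)
    se = np.sqrt(n * p * (1 - p))
    assert abs(len(retained) - n * p) <= 3 * se


def test_length_law_mass_and_mean():
    law = FragmentLengthLaw.truncated_normal(mean=147, sd=6, low=130, high=210)
    assert law.mass(130, 210) == pytest.approx(1.0)
    # closed form: (Phi(11.5/6) - Phi(-11.5/6)) / (Phi(63.5/6) - Phi(-17.5/6))
    assert law.mass(136, 158) == pytest.approx(0.9464, abs=0.001)
    assert law.mean == pytest.approx(147, abs=0.2)


# ---------------------------------------------------------------------------
# Dataset writer


def test_write_dataset_round_trips_and_is_byte_identical(tmp_path, control_params):
    params = control_params(n_fragments=500)
    dyads = simulate_dyads(params)
    frags, _ = dyads_to_fragments(dyads, params)
    p1 = write_dataset(params.construct, frags, tmp_path / "a", params=params)
    p2 = write_dataset(params.construct, frags, tmp_path / "b", params=params)
    for key in ("fasta", "bed", "sam"):
        assert p1[key].read_bytes() == p2[key].read_bytes()

    from_sam, _ = read_fragments(p1["sam"])
    from_bed, _ = read_fragments(p1["bed"])
    key = lambda f: (f.reference_id, f.start, f.end)
    assert sorted(map(key, from_sam)) == sorted(map(key, from_bed)) == sorted(map(key, frags))


def test_sam_template_length_magnitude(tmp_path, control_params):
    import pysam

    params = control_params(length_law=FragmentLengthLaw.constant(147))
    frags, _ = dyads_to_fragments(np.array([100]), params)
    paths = write_dataset(params.construct, frags, tmp_path / "one")
    with pysam.AlignmentFile(str(paths["sam"])) as af:
        tlens = {abs(r.template_length) for r in af}
    assert tlens == {147}


def test_zero_fragments_writes_valid_empty_dataset(tmp_path, control_params):
    params = control_params(n_fragments=0)
    paths = write_dataset(params.construct, [], tmp_path / "zero", params=params)
    assert paths["bed"].read_text() == ""
    frags, report = read_fragments(paths["sam"])
    assert frags == [] and report.total_pairs == 0


# ---------------------------------------------------------------------------
# Presets


def test_control_preset_has_no_sites_or_zones():
    params = preset_experiment("control", n_fragments=10, seed=0)
    assert params.sites == () and params.zones == ()


def test_repelling_preset_zone_covers_the_enhancer():
    params = preset_experiment("repelling_PRS_like", n_fragments=10, seed=0)
    (zone,) = params.zones
    enh = params.construct.enhancer_interval
    assert zone.interval.start <= enh.start and enh.end <= zone.interval.end
    assert zone.factor == 0.01


def test_unknown_preset_rejected():
    with pytest.raises(ValueError, match="unknown preset"):
        preset_experiment("nope", 10, 0)


def test_positioning_preset_recovers_element_centers_end_to_end():
    """Running the positioning preset through fragments, filtering and the
    positioning statistic puts the profile argmax at each element center."""
    from nucprofile import build_dyad_track, positioning_scores

    params = preset_experiment("positioning_601_like", n_fragments=30_000, seed=5)
    dyads = simulate_dyads(params)
    frags, _ = dyads_to_fragments(dyads, params)
    retained, _ = filter_by_length(frags)
    track = build_dyad_track(retained, len(params.construct))
    scores = positioning_scores(track).scores
    for site in params.sites:
        lo, hi = site.dyad_position - 200, site.dyad_position + 201
        local_argmax = lo + int(np.argmax(scores[lo:hi]))
        assert abs(local_argmax - site.dyad_position) <= 2
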