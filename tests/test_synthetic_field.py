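"""Tests for the synthetic field-operation generator."""

import math

import numpy as np
import pandas as pd
import pytest

from baitline import monitoring as mon
from baitline import synthetic_field as sf
from baitline.synthetic_field import Block, Population


def _population(coords, species="possum"):
    df = pd.DataFrame(
        [
            {"id": f"{species}-{i}", "species": species, "x": x, "y": y, "alive": True}
            for i, (x, y) in enumerate(coords)
        ],
        columns=["id", "species", "x", "y", "alive"],
    )
    return Population(animals=df)


# ---------------------------------------------------------------------------
# block geometry
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "area_ha,fps,expected_km",
    [(100.0, 100.0, 10.0), (100.0, 180.0, 100e4 / 180 / 1000), (10.0, 100.0, 1.0)],
)
def test_block_total_line_length(area_ha, fps, expected_km):
    block = sf.build_block(sf.SimConfig(area_ha=area_ha, fps_m=fps))
    assert block.total_line_length_km == pytest.approx(expected_km, rel=1e-9)
    assert block.area_ha == pytest.approx(area_ha)


@pytest.mark.parametrize("area_ha,fps", [(37.0, 90.0), (523.0, 180.0), (5.0, 150.0)])
def test_block_strip_tiling_conserves_area(area_ha, fps):
    """n lines x fps-wide strips tile the block: length * fps = area."""
    block = sf.build_block(sf.SimConfig(area_ha=area_ha, fps_m=fps))
    assert block.n_lines * block.fps_m == pytest.approx(block.width_m)
    assert block.total_line_length_km * 1000 * fps == pytest.approx(area_ha * 1e4)
    lines = block.flight_lines
    assert len(lines) == block.n_lines
    # parallel lines exactly fps apart
    xs = [seg[0][0] for seg in lines]
    assert np.allclose(np.diff(xs), fps)


@pytest.mark.parametrize("kwargs", [
    {"area_ha": -1.0}, {"fps_m": 0.0}, {"skip_fraction": 1.0},
    {"kill_prob": {"possum": 1.2}}, {"detection_mode": "magic"},
    {"nights_chewcard": 0},
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(sf.InvalidConfigError):
        sf.SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# flight simulation
# ---------------------------------------------------------------------------


def test_flight_fix_spacing_and_count():
    block = Block(name="b", width_m=100.0, length_m=1000.0, fps_m=100.0)
    (track,) = sf.simulate_flight(block, speed_kmh=110, fix_interval_s=2,
                                  jitter_sd_m=0.0, seed=0)
    # 110 km/h * 2 s = 61.1 m between fixes -> ~16 intervals over 1 km
    assert 16 <= len(track.fixes) <= 17
    # jitter 0: every fix exactly on the line x = 50
    assert np.allclose(track.fixes[:, 0], 50.0)
    assert (np.diff(track.times) > np.timedelta64(0, "ms")).all()


def test_flight_jitter_rms_matches_noise_model():
    # long single line -> ~10,000 fixes; RMS perpendicular offset ~ sd
    block = Block(name="b", width_m=100.0, length_m=555_000.0, fps_m=100.0)
    (track,) = sf.simulate_flight(block, speed_kmh=100, fix_interval_s=2,
                                  jitter_sd_m=5.0, seed=3)
    assert len(track.fixes) > 9_000
    rms = math.sqrt(np.mean((track.fixes[:, 0] - 50.0) ** 2))
    assert rms == pytest.approx(5.0, rel=0.05)


# ---------------------------------------------------------------------------
# population and control
# ---------------------------------------------------------------------------


def test_population_poisson_mean_matches_density():
    cfg = sf.SimConfig(area_ha=100.0, species_densities={"possum": 2.0})
    block = sf.build_block(cfg)
    counts = [
        len(sf.simulate_population(block, cfg, seed=s).animals) for s in range(300)
    ]
    # Poisson(200): SE of the mean over 300 draws is ~0.8
    assert np.mean(counts) == pytest.approx(200.0, abs=3.0)


def test_population_zero_density_empty_and_determinism():
    cfg = sf.SimConfig(area_ha=50.0, species_densities={"possum": 0.0})
    block = sf.build_block(cfg)
    assert len(sf.simulate_population(block, cfg, seed=1).animals) == 0
    cfg2 = sf.SimConfig(area_ha=50.0)
    p1 = sf.simulate_population(block, cfg2, seed=11).animals
    p2 = sf.simulate_population(block, cfg2, seed=11).animals
    pd.testing.assert_frame_equal(p1, p2)


def test_apply_control_extremes_and_input_unchanged():
    pop = _population([(i * 10.0, 0.0) for i in range(20)])
    all_dead = sf.apply_control(pop, {"possum": 1.0}, seed=0)
    assert not all_dead.animals["alive"].any()
    none_dead = sf.apply_control(pop, {"possum": 0.0}, seed=0)
    assert none_dead.animals["alive"].all()
    assert pop.animals["alive"].all()  # input untouched


def test_apply_control_binomial_survival_rate():
    pop = _population([(float(i), 0.0) for i in range(10_000)])
    survivors = sf.apply_control(pop, {"possum": 0.95}, seed=2).animals["alive"].sum()
    # Binomial(10000, 0.05): 99% bounds ~ 500 +- 2.58 * 21.8
    assert 443 <= survivors <= 557


def test_apply_control_unknown_species_errors():
    pop = _population([(0.0, 0.0)])
    with pytest.raises(KeyError):
        sf.apply_control(pop, {"stoat": 0.5}, seed=0)


# ---------------------------------------------------------------------------
# chewcard survey
# ---------------------------------------------------------------------------


def test_chewcards_all_clear_when_no_animals():
    cfg = sf.SimConfig(area_ha=60.0, species_densities={"possum": 0.0})
    block = sf.build_block(cfg)
    pop = sf.simulate_population(block, cfg, seed=0)
    recs = sf.simulate_chewcard_survey(pop, block, cfg, "pre", seed=0)
    assert recs and not any(r.species_flags["possum"] for r in recs)


def test_chewcards_saturate_under_high_hazard():
    # theta * D >= 5 over six nights: interference probability ~ 1
    cfg = sf.SimConfig(
        area_ha=60.0,
        species_densities={"possum": 10.0},
        detection_mode="hazard",
        detection_params=sf.DetectionParams(theta=2.0, home_range_radius_m=60.0),
    )
    block = sf.build_block(cfg)
    pop = sf.simulate_population(block, cfg, seed=4)
    recs = sf.simulate_chewcard_survey(pop, block, cfg, "pre", seed=4)
    frac = np.mean([r.species_flags["possum"] for r in recs])
    assert frac > 0.99


def test_transform_linear_half_probability_gives_45_degree_index():
    """One animal exactly at each card with c*D = pi/4 -> p = 1/2 per night;
    the mean single-night line tCCI sits at 45 degrees."""
    cfg = sf.SimConfig(
        area_ha=240.0,
        species_densities={"possum": 1.0},
        detection_mode="transform_linear",
        nights_chewcard=1,
        detection_params=sf.DetectionParams(
            c=(math.pi / 4.0) / (1.0 / (math.pi * 20.0 ** 2 / 1e4)),
            home_range_radius_m=20.0,
        ),
    )
    block = sf.build_block(cfg)
    layout = sf._chewcard_layout(block, cfg)
    coords = [(x, y) for _, pts in layout for x, y in pts]
    pop = _population(coords)
    recs = sf.simulate_chewcard_survey(pop, block, cfg, "pre", seed=9)
    tccis = [li.tcci for li in mon.line_indices(recs, "possum", "pre")]
    se = np.std(tccis, ddof=1) / math.sqrt(len(tccis))
    assert np.mean(tccis) == pytest.approx(45.0, abs=max(3 * se, 1.0))


def test_detection_probability_monotone_in_density():
    for mode in ("hazard", "transform_linear"):
        cfg = sf.SimConfig(detection_mode=mode)
        d = np.linspace(0.0, 30.0, 50)
        p = sf._night_probability(d, cfg)
        assert (np.diff(p) >= -1e-12).all()
        assert p[0] == 0.0


# ---------------------------------------------------------------------------
# trap survey
# ---------------------------------------------------------------------------


def test_trap_survey_default_design_all_empty_without_animals():
    cfg = sf.SimConfig(area_ha=60.0, species_densities={"possum": 0.0},
                       nontarget_event_prob=0.0)
    block = sf.build_block(cfg)
    pop = sf.simulate_population(block, cfg, seed=0)
    recs = sf.simulate_trap_survey(pop, block, cfg, seed=0)
    assert len(recs) == 8 * 10 * 3
    assert all(r.outcome == "empty" for r in recs)


def test_trap_survey_zero_capture_probability():
    cfg = sf.SimConfig(area_ha=60.0, per_animal_capture_prob=0.0,
                       nontarget_event_prob=0.0)
    block = sf.build_block(cfg)
    pop = sf.simulate_population(block, cfg, seed=1)
    recs = sf.simulate_trap_survey(pop, block, cfg, seed=1)
    assert all(r.outcome == "empty" for r in recs)


def test_trap_survey_certain_capture_on_constructed_layout():
    """Five possums, each placed exactly on a distinct trap, capture
    probability 1, one night: exactly those five traps record captures."""
    cfg = sf.SimConfig(
        area_ha=60.0, per_animal_capture_prob=1.0, nontarget_event_prob=0.0,
        trap_nights=1,
        detection_params=sf.DetectionParams(home_range_radius_m=8.0),
    )
    block = sf.build_block(cfg)
    xs = (np.arange(cfg.trap_lines) + 0.5) * block.width_m / cfg.trap_lines
    extent = (cfg.traps_per_line - 1) * cfg.trap_spacing_m
    y0 = (block.length_m - extent) / 2.0
    coords = [(xs[i], y0 + 2 * i * cfg.trap_spacing_m) for i in range(5)]
    pop = _population(coords)
    recs = sf.simulate_trap_survey(pop, block, cfg, seed=0)
    captures = [r for r in recs if r.outcome == "possum_capture"]
    assert len(captures) == 5
    assert sorted({r.line_id for r in captures}) == [f"T{i + 1:02d}" for i in range(5)]


# ---------------------------------------------------------------------------
# ground baiting
# ---------------------------------------------------------------------------


def _straight_track(length_m=1000.0):
    from baitline.trackwork import FlightTrack

    fixes = np.column_stack([np.zeros(101), np.linspace(0, length_m, 101)])
    return FlightTrack(line_id="L01", fixes=fixes)


def test_ground_baiting_plot_count_and_constant_timing():
    cfg = sf.SimConfig(gps_noise_sd_m=0.0, per_plot_time_min=(1.2, 0.0))
    events = sf.simulate_ground_baiting([_straight_track()], cfg, seed=0)
    assert len(events) == 50  # 1 km / 20 m
    assert np.allclose([ev.x for ev in events], 0.0)
    elapsed = (events[-1].timestamp - events[0].timestamp).total_seconds() / 60.0
    assert elapsed == pytest.approx(49 * 1.2)
    times = [ev.timestamp for ev in events]
    assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))


def test_ground_baiting_skip_fraction_expected_plots():
    cfg = sf.SimConfig(skip_fraction=0.09, gps_noise_sd_m=0.0)
    counts = [
        len(sf.simulate_ground_baiting([_straight_track()], cfg, seed=s))
        for s in range(400)
    ]
    # one contiguous skipped segment of 90 m drops 4-5 of 50 plots
    assert np.mean(counts) == pytest.approx(45.5, abs=0.5)


# ---------------------------------------------------------------------------
# full pipeline determinism
# ---------------------------------------------------------------------------


def test_run_operation_is_deterministic():
    cfg = sf.SimConfig(area_ha=40.0)
    a = sf.run_operation(cfg, seed=13)
    b = sf.run_operation(cfg, seed=13)
    flags_a = [r.species_flags for r in a["chewcards"]]
    flags_b = [r.species_flags for r in b["chewcards"]]
    assert flags_a == flags_b
    assert [r.outcome for r in a["traps"]] == [r.outcome for r in b["traps"]]
    assert [(e.x, e.y, e.timestamp) for e in a["bait_events"]] == [
        (e.x, e.y, e.timestamp) for e in b["bait_events"]
    ]
    c = sf.run_operation(cfg, seed=14)
    assert [r.outcome for r in a["traps"]] != [r.outcome for r in c["traps"]] or (
        flags_a != [r.species_flags for r in c["chewcards"]]
    )
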