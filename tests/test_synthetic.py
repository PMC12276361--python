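"""Generator statistics: class mixture, track lengths, switching, damage."""

import numpy as np
import pytest

from chromodyn import (
    SimulationConfig,
    RectROI,
    amplitude_factor_for_jump_ratio,
    jump_summary,
    simulate_damage_experiment,
    simulate_fbm_track,
    simulate_hybrid_track,
    simulate_population,
    yuen_welch,
)
from chromodyn.synthetic import sample_track_length


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(class_fractions=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(noise_sigma=-1)
    with pytest.raises(ValueError):
        SimulationConfig(track_survival_p=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(mobile_D=0.01)  # violates 10x separability


def test_effective_diffusion_calibration():
    """Default immobile parameters give the calibrated effective D."""
    cfg = SimulationConfig()
    assert cfg.immobile_effective_D == pytest.approx(0.0078, rel=0.01)
    assert cfg.mean_track_length == pytest.approx(17.0)


def test_fbm_track_basic_properties(sim_config):
    traj = simulate_fbm_track(30, sim_config, seed=1)
    assert traj.n_points == 31
    assert traj.x[0] != traj.x[1] or traj.y[0] != traj.y[1]
    with pytest.raises(ValueError):
        simulate_fbm_track(0, sim_config)


def test_zero_coefficient_track_is_static():
    cfg = SimulationConfig(noise_sigma=0.0)
    traj = simulate_fbm_track(20, cfg, A=0.0, seed=2)
    assert np.all(traj.x == traj.x[0]) and np.all(traj.y == traj.y[0])


def test_hybrid_degenerate_rates_rejected(sim_config):
    from dataclasses import replace

    for rates in [(0.0, 0.5), (0.5, 1.0)]:
        cfg = replace(sim_config, hybrid_switch_rates=rates)
        with pytest.raises(ValueError):
            simulate_hybrid_track(50, cfg)


@pytest.mark.parametrize("rates, occupancy", [
    ((0.05, 0.05), 0.5),        # symmetric -> 50/50
    ((0.02, 0.10), 1.0 / 6.0),  # stationary p12/(p12+p21)
])
def test_hybrid_stationary_occupancy(rates, occupancy):
    from dataclasses import replace

    cfg = replace(SimulationConfig(), hybrid_switch_rates=rates)
    _, states = simulate_hybrid_track(20_000, cfg, seed=8)
    # effective sample size accounts for chain autocorrelation
    n_eff = 20_000 * (rates[0] + rates[1]) / 2.0
    se = np.sqrt(occupancy * (1 - occupancy) / n_eff)
    assert states.mean() == pytest.approx(occupancy, abs=3.5 * se)


def test_hybrid_tracks_always_switch(sim_config):
    for seed in range(20):
        _, states = simulate_hybrid_track(4, sim_config, seed=seed)
        assert len(np.unique(states)) == 2


def test_population_degenerate_mixture():
    cfg = SimulationConfig(class_fractions=(1.0, 0.0, 0.0), n_tracks=50, seed=3)
    coll = simulate_population(cfg)
    assert set(coll.labels) == {"immobile"}


def test_population_mean_track_length():
    """Geometric attrition gives mean length 17 +- 0.5 at survival 15/16."""
    cfg = SimulationConfig(seed=12)
    rng = np.random.default_rng(12)
    lengths = [sample_track_length(cfg, rng) for _ in range(10_000)]
    assert np.mean(lengths) == pytest.approx(17.0, abs=0.5)


def test_population_fractions_within_multinomial_ci():
    cfg = SimulationConfig(n_tracks=1000, seed=4)
    coll = simulate_population(cfg)
    counts = {lab: coll.labels.count(lab) for lab in ("immobile", "hybrid", "mobile")}
    for lab, p in zip(("immobile", "hybrid", "mobile"), cfg.class_fractions):
        se = np.sqrt(p * (1 - p) / cfg.n_tracks)
        assert counts[lab] / cfg.n_tracks == pytest.approx(p, abs=2.807 * se)


def test_population_reproducible_and_sized():
    cfg = SimulationConfig(n_tracks=200, seed=5)
    a = simulate_population(cfg)
    b = simulate_population(cfg)
    assert len(a) == 200 and len(a) == len(a.labels)
    for ta, tb in zip(a.tracks, b.tracks):
        assert np.array_equal(ta.x, tb.x) and np.array_equal(ta.y, tb.y)
    assert a.labels == b.labels


def test_damage_requires_roi():
    cfg = SimulationConfig(n_tracks=10, damage_effect=1.5, seed=6)
    with pytest.raises(ValueError):
        simulate_population(cfg)
    with pytest.raises(ValueError):
        simulate_damage_experiment(
            SimulationConfig(n_tracks=10, seed=6),
            jump_ratio_profile={"before": 1.0, "1min": 1.5})


def test_amplitude_factor_closed_form():
    """Without localization noise the amplitude factor equals the ratio;
    with noise it must exceed it to overcome the noise floor."""
    from dataclasses import replace

    cfg = SimulationConfig()
    noiseless = replace(cfg, noise_sigma=0.0)
    assert amplitude_factor_for_jump_ratio(1.5, noiseless) == pytest.approx(1.5)
    assert amplitude_factor_for_jump_ratio(1.5, cfg) > 1.5
    with pytest.raises(ValueError):
        amplitude_factor_for_jump_ratio(0.1, cfg)  # below the noise floor


def _immobile_jumps(coll, region):
    tracks = [t for t, lab, reg in zip(coll.tracks, coll.labels, coll.region_labels)
              if lab == "immobile" and reg == region and t.n_points >= 5]
    return jump_summary(tracks)


def test_damage_experiment_scales_only_inside_roi():
    roi = RectROI(center=(3.0, 5.0), width=3.0, height=10.0)
    cfg = SimulationConfig(n_tracks=3000, roi=roi, seed=7)
    out = simulate_damage_experiment(
        cfg, jump_ratio_profile={"before": 1.0, "1min": 1.5})
    before_in = _immobile_jumps(out["before"], "inside")
    after_in = _immobile_jumps(out["1min"], "inside")
    before_out = _immobile_jumps(out["before"], "outside")
    after_out = _immobile_jumps(out["1min"], "outside")
    ratio = after_in.mean() / before_in.mean()
    assert ratio == pytest.approx(1.5, abs=0.1)
    # outside tracks identically distributed -> no significant difference
    assert yuen_welch(before_out, after_out).p_value > 0.05


def test_null_damage_profile_is_null():
    roi = RectROI(center=(3.0, 5.0), width=3.0, height=10.0)
    cfg = SimulationConfig(n_tracks=2000, roi=roi, seed=9)
    out = simulate_damage_experiment(
        cfg, jump_ratio_profile={"before": 1.0, "after": 1.0})
    a = _immobile_jumps(out["before"], "inside")
    b = _immobile_jumps(out["after"], "inside")
    assert yuen_welch(a, b).p_value > 0.05
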