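"""Synthetic experiment generator: determinism, recovery, fixtures."""

import numpy as np
import pytest

from sebupen.chem import ph_of_weak_base
from sebupen.pipeline import run_ph_method, run_optical_method
from sebupen.synthetic import (
    SimulationConfig,
    make_fixture_tables,
    render_tube_image,
    simulate_reaction,
)


def noiseless(conc=1.0, seed=0, **kw):
    return SimulationConfig(
        concentration_pct=conc, noise_sd_ph=0.0, noise_sd_height_mm=0.0,
        seed=seed, **kw,
    )


def test_determinism_same_seed_identical_streams():
    a = simulate_reaction(SimulationConfig(seed=5))
    b = simulate_reaction(SimulationConfig(seed=5))
    np.testing.assert_array_equal(a.ph.ph, b.ph.ph)
    np.testing.assert_array_equal(
        a.heights.replicates[2].penetration_mm,
        b.heights.replicates[2].penetration_mm,
    )
    c = simulate_reaction(SimulationConfig(seed=6))
    assert not np.array_equal(a.ph.ph, c.ph.ph)


def test_initial_ph_matches_equilibrium():
    cfg = noiseless(conc=1.5)
    res = simulate_reaction(cfg)
    cb0 = cfg.initial_amine_mass_g / (cfg.amine.molar_mass * cfg.Vr_dm3)
    assert res.truth.ph_clean[0] == pytest.approx(
        ph_of_weak_base(cb0, cfg.amine.constants), rel=1e-12
    )
    assert res.ph.ph[0] == res.truth.ph_clean[0]


def test_truth_invariants():
    res = simulate_reaction(SimulationConfig(seed=2))
    cfg = SimulationConfig(seed=2)
    assert np.all(np.diff(res.truth.m_zp_g) >= 0)
    assert res.truth.m_zp_g[-1] <= (
        cfg.effective_reacted_fraction * cfg.initial_amine_mass_g + 1e-15
    )
    assert np.all(res.truth.increase_mm >= 0)
    assert res.truth.turbidity[0] == 0.0


def test_low_concentration_ph_plateaus_before_end():
    """At low concentration the reactable amine is nearly exhausted well
    before the end of observation: the pH trajectory is fast at first and
    flattens toward a plateau set by the unreactable remainder."""
    cfg = noiseless(conc=0.5)
    res = simulate_reaction(cfg)
    ph = res.truth.ph_clean
    early_drop = ph[0] - ph[60]
    late_drop = ph[180] - ph[-1]
    assert late_drop < 0.2 * early_drop
    # the reacted-mass ceiling is effectively reached before duration end
    m_max = cfg.effective_reacted_fraction * cfg.initial_amine_mass_g
    assert res.truth.m_zp_g[-1] > 0.99 * m_max


def test_plug_reduces_reacted_ceiling():
    below = simulate_reaction(noiseless(conc=2.0))
    above = simulate_reaction(noiseless(conc=2.5))
    frac_below = below.truth.m_zp_g[-1] / (2.0 / 100 * 3.0)
    frac_above = above.truth.m_zp_g[-1] / (2.5 / 100 * 3.0)
    assert frac_above < frac_below


def test_ph_method_recovers_truth_on_noiseless_runs():
    """20 seeded random configs: the pH pipeline inverts the generator to
    relative 1e-9."""
    rng = np.random.default_rng(7)
    for i in range(20):
        cfg = noiseless(
            conc=float(rng.uniform(0.5, 2.5)),
            seed=int(rng.integers(0, 2**31)),
            rate_k=float(rng.uniform(0.005, 0.05)),
            max_reacted_fraction=float(rng.uniform(0.3, 0.95)),
        )
        res = simulate_reaction(cfg)
        vol = run_ph_method(
            res.ph, amine=cfg.amine, sebum=cfg.sebum, Vr_dm3=cfg.Vr_dm3
        )
        true = res.truth.reacted_volume_mm3
        assert vol.reacted_mm3[0] == 0.0
        mask = true > 0
        rel = np.abs(vol.reacted_mm3[mask] - true[mask]) / true[mask]
        assert rel.max() < 1e-9


def test_ph_method_noise_stays_within_ten_percent():
    """With 0.01 pH instrument noise the median absolute volume error is
    below 10% of the final true volume."""
    errors = []
    for seed in range(10):
        cfg = SimulationConfig(
            concentration_pct=1.0, noise_sd_ph=0.01, seed=seed
        )
        res = simulate_reaction(cfg)
        vol = run_ph_method(
            res.ph, amine=cfg.amine, sebum=cfg.sebum, Vr_dm3=cfg.Vr_dm3
        )
        err = np.median(
            np.abs(vol.reacted_mm3 - res.truth.reacted_volume_mm3)
        )
        errors.append(err / res.truth.reacted_volume_mm3[-1])
    assert np.median(errors) < 0.10


def test_optical_method_recovers_truth_heights(geometry):
    cfg = noiseless(conc=1.5, seed=4)
    res = simulate_reaction(cfg)
    vol = run_optical_method(res.heights, geometry)
    np.testing.assert_allclose(
        vol.penetrated_mm3, res.truth.reacted_volume_mm3, rtol=1e-9, atol=1e-9
    )


def test_rendered_image_round_trip_matches_calibration(geometry, calibration):
    from sebupen.optical import LayerHeights, measure_layer_heights

    img = render_tube_image(
        LayerHeights(3.0, 5.0), geometry, calibration, noise_sd=5.0, seed=9
    )
    h = measure_layer_heights(img)
    assert h.penetration_depth_mm == pytest.approx(3.0, abs=0.02)
    assert h.increase_height_mm == pytest.approx(5.0, abs=0.02)
    again = render_tube_image(
        LayerHeights(3.0, 5.0), geometry, calibration, noise_sd=5.0, seed=9
    )
    np.testing.assert_array_equal(img.pixels, again.pixels)


def test_render_respects_frame_limit(geometry, calibration):
    from sebupen.optical import LayerHeights

    with pytest.raises(ValueError, match="frame"):
        render_tube_image(
            LayerHeights(30.0, 30.0), geometry, calibration,
            frame_height_mm=10.0,
        )


def test_fixture_tables_match_published_values():
    tables = make_fixture_tables()
    screen = tables["alcoholamine_screen"]
    assert screen.loc["penetrated_mm3", "AMPD"] == 397.0
    assert screen.loc["increased_mm3", "TIPA"] == 521.0
    turbidity = tables["turbidity"]
    assert turbidity.loc[4, 0.5] == 0.532
    assert list(turbidity.loc[4]) == [0.532, 0.430, 0.351, 0.178]
    comparison = tables["method_comparison"]
    assert comparison.loc["optical_penetrated_mm3", 2.5] == 310.00
    assert comparison.loc["optical_sd_mm3", 2.5] == 52.91
    assert comparison.loc["ph_reacted_mm3", 0.5] == 115.10
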