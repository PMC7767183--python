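"""Synthetic experiments with known ground truth, plus packaged tables.

The generator simulates a 0.5-2.5% w/w alcoholamine solution (~3 cm^3)
over a ~20 mm sebum column in a 16 mm tube.  Reacted amine mass follows a
first-order approach to a ceiling,

    m_zp(t) = m_max (1 - exp(-k t)),   m_max = f_max * m_z0,

the simplest trajectory with the observed fast-then-stabilising shape; it
is a test harness, not a kinetic claim.  The remaining-amine concentration
gives the clean pH through the weak-base equilibrium; the reacted mass
gives the true reacted sebum volume through the neutralisation
stoichiometry, hence the penetration height; the increase height adds the
water-binding swell of the soap layer.  Turbidity rises in time and falls
with concentration (a denser product layer retains particles).  Above
``plug_threshold_pct`` the reactable fraction is cut down, emulating the
rigid product plug at high concentration.  Every output stream draws from
its own child of the master seed, so outputs are reproducible
bit-for-bit and adding one stream never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional

import numpy as np
import pandas as pd

from .chem import AlcoholamineSpec, ph_of_weak_base
from .constants import DM3_PER_CM3
from .density import PycnometerMeasurement
from .optical import LayerHeights, PixelCalibration, TubeGeometry, TubeImage
from .pipeline import (
    HeightSeries,
    HeightSeriesSet,
    PHSeries,
    TurbiditySeries,
)
from .stoichiometry import (
    SebumComposition,
    reacted_acid_mass,
    reacted_sebum_mass,
    reacted_sebum_volume,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationResult",
    "simulate_reaction",
    "render_tube_image",
    "make_fixture_tables",
    "table2_turbidity_series",
    "table3_volume_series",
    "synth_pycnometer",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated run.

    Defaults emulate the in-vitro setup: 3 cm^3 of solution (density ~1,
    so 3 g), four replicate tubes, 240 one-minute pH samples, +/-0.01 pH
    instrument noise.  ``rate_k`` = 0.025 /min puts most of the reaction
    in the first hour; ``max_reacted_fraction`` = 0.95 reproduces the
    observed ~0.6-0.8 unit pH drop; above ``plug_threshold_pct`` the
    reactable fraction is multiplied by ``plug_reduction`` to emulate the
    product plug.
    """

    concentration_pct: float = 1.0  # % w/w
    Vr_cm3: float = 3.0
    amine: AlcoholamineSpec = field(default_factory=AlcoholamineSpec)
    sebum: SebumComposition = field(default_factory=SebumComposition)
    geometry: TubeGeometry = field(default_factory=TubeGeometry)
    calibration: PixelCalibration = field(default_factory=PixelCalibration)
    rate_k: float = 0.025  # per minute
    max_reacted_fraction: float = 0.95
    plug_threshold_pct: float = 2.0
    plug_reduction: float = 0.4
    water_binding_factor: float = 1.8  # observed layer volume / reacted volume
    swell_mm: float = 0.2  # slow water-binding swell added to the increase
    noise_sd_ph: float = 0.01
    noise_sd_height_mm: float = 0.05
    duration_min: float = 240.0
    dt_min: float = 1.0
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rate_k > 0:
            raise ValueError("rate_k must be positive")
        if not 0 < self.max_reacted_fraction <= 1:
            raise ValueError("max_reacted_fraction must lie in (0, 1]")
        if self.water_binding_factor < 1:
            raise ValueError("water_binding_factor must be >= 1")
        if not self.concentration_pct > 0:
            raise ValueError("concentration_pct must be positive")

    @property
    def Vr_dm3(self) -> float:
        return self.Vr_cm3 * DM3_PER_CM3

    @property
    def solution_mass_g(self) -> float:
        # solution density taken as 1 g/cm^3 (dilute aqueous)
        return self.Vr_cm3

    @property
    def initial_amine_mass_g(self) -> float:
        return self.concentration_pct / 100.0 * self.solution_mass_g

    @property
    def effective_reacted_fraction(self) -> float:
        if self.concentration_pct > self.plug_threshold_pct:
            return self.max_reacted_fraction * self.plug_reduction
        return self.max_reacted_fraction


@dataclass
class SimulationTruth:
    """Noise-free ground truth of a simulated run."""

    times_min: np.ndarray
    m_zp_g: np.ndarray  # reacted amine mass, non-decreasing
    reacted_volume_mm3: np.ndarray
    penetration_mm: np.ndarray
    increase_mm: np.ndarray
    ph_clean: np.ndarray
    turbidity_times_h: np.ndarray
    turbidity: np.ndarray


class SimulationResult(NamedTuple):
    ph: PHSeries
    heights: HeightSeriesSet
    turbidity: TurbiditySeries
    truth: SimulationTruth


def _label(concentration_pct: float) -> str:
    return f"{concentration_pct:g}%"


def simulate_reaction(config: SimulationConfig) -> SimulationResult:
    """Simulate one run; all streams derive from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    rng_ph, rng_h, _rng_img, _rng_turb = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    t = np.arange(0.0, config.duration_min + config.dt_min / 2, config.dt_min)
    m_z0 = config.initial_amine_mass_g
    m_max = config.effective_reacted_fraction * m_z0
    m_zp = m_max * (1.0 - np.exp(-config.rate_k * t))

    M = config.amine.molar_mass
    Cb = (m_z0 - m_zp) / (M * config.Vr_dm3)
    ph_clean = np.array(
        [ph_of_weak_base(c, config.amine.constants) for c in Cb]
    )

    v_s = np.array(
        [
            reacted_sebum_volume(
                reacted_sebum_mass(
                    reacted_acid_mass(
                        m, amine_molar_mass=M,
                        acid_molar_mass=config.sebum.stearic_molar_mass,
                    ),
                    config.sebum,
                ),
                config.sebum,
            )
            for m in m_zp
        ]
    )
    area = config.geometry.cross_section_mm2
    h_pen = v_s / area
    saturation = 1.0 - np.exp(-config.rate_k * t)
    h_inc = (config.water_binding_factor - 1.0) * h_pen + config.swell_mm * saturation

    label = _label(config.concentration_pct)
    ph_series = PHSeries(
        concentration_label=label,
        times_min=t,
        ph=np.clip(ph_clean + rng_ph.normal(0.0, config.noise_sd_ph, t.shape),
                   1e-6, 14 - 1e-6),
    )
    replicates = []
    for k in range(config.n_replicates):
        noise_p = rng_h.normal(0.0, config.noise_sd_height_mm, t.shape)
        noise_i = rng_h.normal(0.0, config.noise_sd_height_mm, t.shape)
        replicates.append(
            HeightSeries(
                times_min=t,
                penetration_mm=np.clip(h_pen + noise_p, 0.0, None),
                increase_mm=np.clip(h_inc + noise_i, 0.0, None),
                replicate_id=k,
            )
        )
    heights = HeightSeriesSet(concentration_label=label, replicates=replicates)

    t_h = np.arange(0.0, config.duration_min / 60.0 + 1e-9, 1.0)
    # amplitude inversely proportional to concentration, per the observed
    # pattern; 0.55 at 0.5% roughly matches the measured 4 h absorbance scale
    amp = 0.55 * 0.5 / config.concentration_pct
    turb = amp * (1.0 - np.exp(-0.7 * t_h))
    turb[0] = 0.0
    turbidity = TurbiditySeries(
        concentration_label=label,
        concentration_pct=config.concentration_pct,
        times_h=t_h,
        absorbance=turb,
    )

    truth = SimulationTruth(
        times_min=t,
        m_zp_g=m_zp,
        reacted_volume_mm3=v_s,
        penetration_mm=h_pen,
        increase_mm=h_inc,
        ph_clean=ph_clean,
        turbidity_times_h=t_h,
        turbidity=turb,
    )
    return SimulationResult(ph_series, heights, turbidity, truth)


# intensity levels of the three zones in rendered images
SOLUTION_LEVEL = 128
BAND_LEVEL = 220
SEBUM_LEVEL = 30


def render_tube_image(
    heights: LayerHeights,
    geometry: TubeGeometry,
    calibration: PixelCalibration,
    noise_sd: float = 5.0,
    seed: Optional[int] = None,
    margin_top_mm: float = 2.0,
    margin_bottom_mm: float = 2.0,
    width_px: int = 64,
    frame_height_mm: Optional[float] = None,
) -> TubeImage:
    """Render a three-band grayscale tube image for the given heights.

    Solution ~128, reacted band ~220, intact sebum ~30; band boundaries at
    baseline -/+ the (pixel-quantised) heights; seeded Gaussian pixel
    noise.  The frame auto-sizes unless ``frame_height_mm`` is given, in
    which case heights that do not fit raise ``ValueError``.
    """
    ppm = calibration.pixels_per_mm
    h_i_px = int(round(heights.increase_height_mm * ppm))
    h_p_px = int(round(heights.penetration_depth_mm * ppm))
    top_px = int(round(margin_top_mm * ppm))
    bot_px = int(round(margin_bottom_mm * ppm))
    rows = top_px + h_i_px + h_p_px + bot_px
    if frame_height_mm is not None:
        frame_px = int(round(frame_height_mm * ppm))
        if rows > frame_px:
            raise ValueError("layer heights exceed the requested frame height")
        rows = frame_px
    baseline = top_px + h_i_px

    img = np.full((rows, width_px), float(SOLUTION_LEVEL))
    img[baseline - h_i_px : baseline + h_p_px, :] = BAND_LEVEL
    img[baseline + h_p_px :, :] = SEBUM_LEVEL
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return TubeImage(pixels=img, baseline_row=baseline, calibration=calibration)


def synth_pycnometer(
    target_density: float, m1: float = 2.0, w: float = 25.0,
    seed: Optional[int] = None,
) -> PycnometerMeasurement:
    """Invert the pycnometer formula: solve for m2 at a target density.

    Deterministic (the ``seed`` argument is accepted for interface
    symmetry and ignored); the round trip through
    :func:`sebupen.density.pycnometer_density` returns ``target_density``
    to floating precision.
    """
    from .constants import AIR_BUOYANCY_CORRECTION, WATER_DENSITY_20C_G_PER_CM3

    if not target_density > AIR_BUOYANCY_CORRECTION:
        raise ValueError("target density must exceed the air correction")
    displaced = m1 * WATER_DENSITY_20C_G_PER_CM3 / (
        target_density - AIR_BUOYANCY_CORRECTION
    )
    if displaced > w:
        raise ValueError(
            "infeasible inversion: displaced water exceeds the pycnometer fill "
            "(negative top-up)"
        )
    m2 = w + m1 - displaced
    return PycnometerMeasurement(m1=m1, w=w, m2=m2)


# ---------------------------------------------------------------------------
# packaged measurement tables (transcribed fixtures)
# ---------------------------------------------------------------------------

def make_fixture_tables() -> Dict[str, pd.DataFrame]:
    """The three packaged measurement tables as DataFrames.

    ``alcoholamine_screen``: 4 h penetrated/increased volumes and pH for
    the four candidate alcoholamines (n = 1).  ``turbidity``: absorbance
    at 850 nm over 4 h for four concentrations (n = 1).
    ``method_comparison``: optical penetrated vs pH-derived reacted volume
    at 216 min for five concentrations, with the printed difference row.
    Note the printed 2.5% difference (121.77) does not equal the
    subtraction of its own rows (310.00 - 31.77 = 278.23); it is carried
    verbatim and flagged downstream.
    """
    screen = pd.DataFrame(
        {
            "AMPD": [397.0, 651.0, 10.468, 10.146],
            "TRIS": [332.0, 813.0, 10.444, 9.182],
            "DIPA": [357.0, 692.0, 10.708, 9.853],
            "TIPA": [427.0, 521.0, 10.063, 8.857],
        },
        index=["penetrated_mm3", "increased_mm3", "ph_initial", "ph_4h"],
    )
    turbidity = pd.DataFrame(
        {
            0.5: [0.291, 0.423, 0.476, 0.532],
            1.0: [0.200, 0.235, 0.269, 0.430],
            1.5: [0.146, 0.214, 0.294, 0.351],
            2.0: [0.036, 0.058, 0.114, 0.178],
        },
        index=pd.Index([1, 2, 3, 4], name="time_h"),
    )
    turbidity.columns.name = "concentration_pct"
    comparison = pd.DataFrame(
        {
            0.5: [226.67, 112.6, 115.10, 0.144, 111.57],
            1.0: [233.33, 61.91, 61.02, 0.869, 172.31],
            1.5: [285.00, 30.0, 76.46, 0.162, 208.54],
            2.0: [253.33, 34.16, 164.88, 0.408, 88.45],
            2.5: [310.00, 52.91, 31.77, 2.439, 121.77],
        },
        index=[
            "optical_penetrated_mm3",
            "optical_sd_mm3",
            "ph_reacted_mm3",
            "ph_sd_mm3",
            "printed_difference_mm3",
        ],
    )
    comparison.columns.name = "concentration_pct"
    return {
        "alcoholamine_screen": screen,
        "turbidity": turbidity,
        "method_comparison": comparison,
    }


def table2_turbidity_series() -> List[TurbiditySeries]:
    """Turbidity fixture as series, with the stated zero initial value
    prepended at t = 0."""
    table = make_fixture_tables()["turbidity"]
    out = []
    for conc in table.columns:
        out.append(
            TurbiditySeries(
                concentration_label=_label(conc),
                concentration_pct=float(conc),
                times_h=np.concatenate(([0.0], table.index.to_numpy(float))),
                absorbance=np.concatenate(([0.0], table[conc].to_numpy(float))),
            )
        )
    return out


def table3_volume_series(concentration_pct: float):
    """(optical, pH) single-point VolumeSeries at 216 min from the
    packaged method-comparison table."""
    from .pipeline import VolumeSeries, REFERENCE_TIME_MIN

    col = make_fixture_tables()["method_comparison"][concentration_pct]
    label = _label(concentration_pct)
    t = np.array([REFERENCE_TIME_MIN])
    optical = VolumeSeries(
        concentration_label=label,
        times_min=t,
        penetrated_mm3=np.array([col["optical_penetrated_mm3"]]),
        sd_mm3=np.array([col["optical_sd_mm3"]]),
    )
    ph = VolumeSeries(
        concentration_label=label,
        times_min=t,
        reacted_mm3=np.array([col["ph_reacted_mm3"]]),
        sd_mm3=np.array([col["ph_sd_mm3"]]),
    )
    return optical, ph
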