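"""End-to-end orchestration of the two volume-quantification methods.

The optical method turns replicate layer-height time series into penetrated
and increased cylinder volumes (mean and sample SD across replicates).  The
pH method turns a pH time series into a reacted-volume time series through
the weak-base equilibrium and the neutralisation stoichiometry, using the
pH at t0 as the unreacted baseline.  ``compare_methods`` reproduces the
per-concentration comparison at a reference time (default 216 min), where a
negative optical-minus-pH difference indicates a rigid product plug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import AlcoholamineSpec
from .optical import LayerHeights, TubeGeometry
from .stoichiometry import SebumComposition, ph_to_reacted_volume

logger = logging.getLogger(__name__)

__all__ = [
    "PHSeries",
    "HeightSeries",
    "HeightSeriesSet",
    "VolumeSeries",
    "MethodComparison",
    "TurbiditySeries",
    "ConcentrationSummary",
    "TrendReport",
    "run_ph_method",
    "run_optical_method",
    "compare_methods",
    "concentration_sweep_summary",
    "turbidity_trend_check",
]

#: default reference comparison time in minutes
REFERENCE_TIME_MIN = 216.0
#: default pH-meter accuracy propagated into the pH-method SD
PH_DEVICE_ACCURACY = 0.01


def _check_times(times: np.ndarray) -> None:
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")


@dataclass
class PHSeries:
    """pH above the sebum layer sampled over time (minutes)."""

    concentration_label: str
    times_min: np.ndarray
    ph: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        _check_times(self.times_min)
        if self.ph.shape != self.times_min.shape:
            raise ValueError("ph and times must have the same length")
        if np.any((self.ph <= 0) | (self.ph >= 14)):
            raise ValueError("pH values must lie in (0, 14)")


@dataclass
class HeightSeries:
    """One replicate of layer heights over time (mm)."""

    times_min: np.ndarray
    penetration_mm: np.ndarray
    increase_mm: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.penetration_mm = np.asarray(self.penetration_mm, dtype=float)
        self.increase_mm = np.asarray(self.increase_mm, dtype=float)
        _check_times(self.times_min)
        for name in ("penetration_mm", "increase_mm"):
            arr = getattr(self, name)
            if arr.shape != self.times_min.shape:
                raise ValueError(f"{name} length mismatch")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")

    def heights_at(self, i: int) -> LayerHeights:
        return LayerHeights(
            float(self.penetration_mm[i]), float(self.increase_mm[i])
        )


@dataclass
class HeightSeriesSet:
    """Replicate height series for one concentration (default n = 4)."""

    concentration_label: str
    replicates: List[HeightSeries]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("at least one replicate is required")
        t0 = self.replicates[0].times_min
        for rep in self.replicates[1:]:
            if rep.times_min.shape != t0.shape or np.any(rep.times_min != t0):
                raise ValueError("replicate time grids must be identical")

    @property
    def times_min(self) -> np.ndarray:
        return self.replicates[0].times_min


@dataclass
class VolumeSeries:
    """Per-time volumes in mm^3, the common output of both methods.

    Optical series carry ``penetrated_mm3`` and ``increased_mm3``; pH
    series carry ``reacted_mm3``.  ``sd_mm3`` is the replicate sample SD
    (optical) or device-accuracy propagation (pH) of the primary volume.
    """

    concentration_label: str
    times_min: np.ndarray
    penetrated_mm3: Optional[np.ndarray] = None
    increased_mm3: Optional[np.ndarray] = None
    reacted_mm3: Optional[np.ndarray] = None
    sd_mm3: Optional[np.ndarray] = None
    sd_increased_mm3: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        _check_times(self.times_min)
        for name in (
            "penetrated_mm3", "increased_mm3", "reacted_mm3",
            "sd_mm3", "sd_increased_mm3",
        ):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.times_min.shape:
                raise ValueError(f"{name} length mismatch")
            if name != "sd_mm3" and name != "sd_increased_mm3" and np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)

    @property
    def primary_mm3(self) -> np.ndarray:
        """Penetrated volume (optical) or reacted volume (pH method)."""
        if self.penetrated_mm3 is not None:
            return self.penetrated_mm3
        if self.reacted_mm3 is not None:
            return self.reacted_mm3
        raise ValueError("series carries neither penetrated nor reacted volumes")

    def value_at(self, t_min: float) -> float:
        idx = np.flatnonzero(np.isclose(self.times_min, t_min))
        if idx.size == 0:
            raise ValueError(f"time {t_min} min not covered by the series")
        return float(self.primary_mm3[idx[0]])


@dataclass(frozen=True)
class MethodComparison:
    """Optical vs pH-derived volume at one reference time."""

    concentration_label: str
    at_time_min: float
    optical_mm3: float
    ph_derived_mm3: float
    difference_mm3: float
    plug_flag: bool


@dataclass
class TurbiditySeries:
    """Apparent absorbance at 850 nm of the solution above the sebum."""

    concentration_label: str
    concentration_pct: float
    times_h: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        _check_times(self.times_h)
        if self.absorbance.shape != self.times_h.shape:
            raise ValueError("absorbance length mismatch")
        if np.any(self.absorbance < 0):
            raise ValueError("absorbance must be non-negative")
        if self.times_h[0] == 0 and self.absorbance[0] != 0:
            raise ValueError("turbidity at time 0 must be 0")


@dataclass(frozen=True)
class ConcentrationSummary:
    """Per-concentration outcome of the sweep."""

    concentration_label: str
    final_penetrated_mm3: float
    depleted: bool
    plug: bool
    rank: Optional[int]  # 1 = largest final volume among plug-free runs


@dataclass
class TrendReport:
    """Violations of the expected turbidity monotonicities."""

    time_violations: List[Tuple[str, float]] = field(default_factory=list)
    concentration_violations: List[Tuple[float, str, str]] = field(
        default_factory=list
    )

    @property
    def ok(self) -> bool:
        return not self.time_violations and not self.concentration_violations

    @property
    def n_violations(self) -> int:
        return len(self.time_violations) + len(self.concentration_violations)


def run_ph_method(
    series: PHSeries,
    amine: Optional[AlcoholamineSpec] = None,
    sebum: Optional[SebumComposition] = None,
    Vr_dm3: float = 3.0e-3,
    direction: str = "physical",
    policy: str = "clamp",
    ph_accuracy: float = PH_DEVICE_ACCURACY,
) -> VolumeSeries:
    """Reacted sebum volume over time from a pH series.

    The pH at t0 is the unreacted baseline; each later point gives a
    reacted volume through the equilibrium/stoichiometry chain.  The SD is
    propagated from the pH-meter accuracy (default +/-0.01 pH) by
    evaluating the chain at pH(tn) -/+ accuracy and halving the spread.
    """
    amine = amine or AlcoholamineSpec()
    sebum = sebum or SebumComposition()
    ph0 = float(series.ph[0])
    vols = np.empty_like(series.times_min)
    sds = np.empty_like(series.times_min)
    for i, phn in enumerate(series.ph):
        vols[i] = ph_to_reacted_volume(
            ph0, float(phn), amine, Vr_dm3, sebum,
            direction=direction, policy=policy,
        )
        # the perturbed evaluations use raw mode, clamped silently, so the
        # accuracy band near t0 does not trigger the pH-rise diagnostics
        lo = max(0.0, ph_to_reacted_volume(
            ph0, float(phn) + ph_accuracy, amine, Vr_dm3, sebum,
            direction=direction, policy="raw",
        ))
        hi = max(0.0, ph_to_reacted_volume(
            ph0, float(phn) - ph_accuracy, amine, Vr_dm3, sebum,
            direction=direction, policy="raw",
        ))
        sds[i] = 0.5 * abs(hi - lo)
    return VolumeSeries(
        concentration_label=series.concentration_label,
        times_min=series.times_min,
        reacted_mm3=vols,
        sd_mm3=sds,
    )


def run_optical_method(
    heights: HeightSeriesSet, geometry: Optional[TubeGeometry] = None
) -> VolumeSeries:
    """Mean and sample SD of penetrated/increased volumes across replicates."""
    geometry = geometry or TubeGeometry()
    pen = np.stack([r.penetration_mm for r in heights.replicates])
    inc = np.stack([r.increase_mm for r in heights.replicates])
    area = geometry.cross_section_mm2
    pen_v, inc_v = pen * area, inc * area
    ddof = 1 if pen_v.shape[0] > 1 else 0
    return VolumeSeries(
        concentration_label=heights.concentration_label,
        times_min=heights.times_min,
        penetrated_mm3=pen_v.mean(axis=0),
        increased_mm3=inc_v.mean(axis=0),
        sd_mm3=pen_v.std(axis=0, ddof=ddof),
        sd_increased_mm3=inc_v.std(axis=0, ddof=ddof),
    )


def compare_methods(
    optical: VolumeSeries,
    ph_based: VolumeSeries,
    at_time: float = REFERENCE_TIME_MIN,
) -> MethodComparison:
    """Optical penetrated minus pH-derived reacted volume at ``at_time``.

    A negative difference flags a rigid product plug: the stoichiometric
    estimate then exceeds what the optical etching front shows.
    """
    opt = optical.value_at(at_time)
    ph = ph_based.value_at(at_time)
    diff = opt - ph
    return MethodComparison(
        concentration_label=optical.concentration_label,
        at_time_min=at_time,
        optical_mm3=opt,
        ph_derived_mm3=ph,
        difference_mm3=diff,
        plug_flag=diff < 0,
    )


def concentration_sweep_summary(
    comparisons: Sequence[MethodComparison],
    volumes: Dict[str, VolumeSeries],
    plateau_window_frac: float = 0.1,
    plateau_tol: float = 0.02,
) -> List[ConcentrationSummary]:
    """Summarise a concentration sweep.

    For each concentration: the final penetrated volume, a depletion
    indicator (the volume has plateaued — relative growth over the last
    ``plateau_window_frac`` of the observation below ``plateau_tol``) and
    the plug flag from the method comparison.  Plug-free concentrations
    are ranked by final penetrated volume (rank 1 = largest); plugged ones
    carry no rank.
    """
    if len(comparisons) < 2:
        logger.warning("sweep summary over fewer than 2 concentrations")
    plug_by_label = {c.concentration_label: c.plug_flag for c in comparisons}
    rows = []
    for label, series in volumes.items():
        v = series.primary_mm3
        t = series.times_min
        final = float(v[-1])
        window_start = t[-1] - plateau_window_frac * (t[-1] - t[0])
        in_window = t >= window_start
        v_then = float(v[in_window][0])
        growth = (final - v_then) / final if final > 0 else 0.0
        rows.append(
            {
                "label": label,
                "final": final,
                "depleted": growth < plateau_tol,
                "plug": plug_by_label.get(label, False),
            }
        )
    unplugged = sorted(
        (r for r in rows if not r["plug"]), key=lambda r: -r["final"]
    )
    ranks = {r["label"]: i + 1 for i, r in enumerate(unplugged)}
    return [
        ConcentrationSummary(
            concentration_label=r["label"],
            final_penetrated_mm3=r["final"],
            depleted=r["depleted"],
            plug=r["plug"],
            rank=ranks.get(r["label"]),
        )
        for r in rows
    ]


def turbidity_trend_check(series: Sequence[TurbiditySeries]) -> TrendReport:
    """Check the expected turbidity monotonicities.

    Within each concentration the absorbance should be non-decreasing in
    time (particles accumulate); across concentrations, at each common
    time point, absorbance should be non-increasing in concentration (the
    denser product layer at high concentration holds particles back).
    Violations are reported, never raised.
    """
    report = TrendReport()
    for s in series:
        for i in range(1, len(s.times_h)):
            if s.absorbance[i] < s.absorbance[i - 1]:
                report.time_violations.append((s.concentration_label, float(s.times_h[i])))
    ordered = sorted(series, key=lambda s: s.concentration_pct)
    if len(ordered) >= 2:
        t0 = ordered[0].times_h
        for s in ordered[1:]:
            if s.times_h.shape != t0.shape or np.any(s.times_h != t0):
                raise ValueError("turbidity series must share a common time grid")
        for lo, hi in zip(ordered, ordered[1:]):
            worse = hi.absorbance > lo.absorbance
            for t in t0[worse]:
                report.concentration_violations.append(
                    (float(t), lo.concentration_label, hi.concentration_label)
                )
    return report
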